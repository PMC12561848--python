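"""AMMI: additive main effects and multiplicative interaction.

The model for the cell mean of genotype g in environment e is::

    y_ge = mu + rho_g + psi_e + sum_n theta_n * xi_gn * eta_en + eps_ge

Additive main effects come from a two-way ANOVA on the cell means (scaled
by the block count r); the doubly-centered interaction residual matrix is
then decomposed by SVD into interaction principal component axes (IPCA).
Axis n carries SS = r * theta_n**2 and Gollob degrees of freedom
g + e - 1 - 2n.  Every systematic row (treatment, genotype, environment,
interaction, each IPCA axis) is F-tested against the pooled error — total
SS minus treatment SS, i.e. blocks plus both split-plot error strata
pooled on g*e*(r-1) degrees of freedom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .data_model import aggregate_cell_means, grand_decomposition

AMMI_TABLE_COLUMNS = ["source", "df", "ss", "ms", "F", "p", "pct"]


def gollob_df(g: int, e: int, n: int) -> int:
    """Gollob degrees of freedom of the n-th interaction axis: g + e - 1 - 2n.

    Valid for 1 <= n <= min(g-1, e-1); the df of all min(g-1, e-1) axes sum
    to the interaction df (g-1)(e-1).
    """
    n_max = min(g - 1, e - 1)
    if not 1 <= n <= n_max:
        raise ValueError(f"axis index n={n} outside 1..{n_max} for g={g}, e={e}")
    return g + e - 1 - 2 * n


def orient_axes(xi: np.ndarray, eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix SVD sign indeterminacy: flip each axis so the environment-score
    entry of largest magnitude is positive (first such entry on ties)."""
    xi = xi.copy()
    eta = eta.copy()
    for n in range(eta.shape[1]):
        lead = int(np.argmax(np.abs(eta[:, n])))
        if eta[lead, n] < 0:
            eta[:, n] *= -1
            xi[:, n] *= -1
    return xi, eta


def add_percentages(table: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``pct`` column of an AMMI ANOVA table.

    Dual convention: the genotype, environment and interaction rows are
    expressed as percent of the *total* SS; each IPCA row as percent of the
    *interaction* SS.  Undefined (zero denominator) percentages are NaN.
    """
    table = table.copy()
    ss = dict(zip(table["source"], table["ss"]))
    total = ss.get("total", np.nan)
    inter = ss.get("interaction", np.nan)
    pct = []
    for source, s in zip(table["source"], table["ss"]):
        if source in ("genotype", "environment", "interaction"):
            pct.append(100.0 * s / total if total > 0 else np.nan)
        elif source.startswith("ipca_"):
            pct.append(100.0 * s / inter if inter > 0 else np.nan)
        else:
            pct.append(np.nan)
    table["pct"] = pct
    return table


pct_of_total = add_percentages


class AMMI(BaseEstimator):
    """AMMI estimator for balanced long-format activity tables.

    Parameters
    ----------
    n_axes : int or None, default 2
        Number of interaction principal component axes retained in the
        ANOVA table; the SS of the remaining axes is pooled into the
        ``residual`` row.  The default 2 matches the two-axis convention of
        biplot work; ``None`` retains every axis with positive Gollob df.

    Attributes
    ----------
    mu_ : float
        Grand mean of the cell means.
    genotype_effects_, environment_effects_ : Series
        Main-effect deviations rho_g and psi_e (each sums to zero).
    singular_values_ : ndarray
        All min(g-1, e-1) singular values of the interaction residual
        matrix, non-increasing.
    genotype_scores_, environment_scores_ : DataFrame
        Unit-norm axis scores xi and eta for the retained axes, columns
        ``ipca_1..``; oriented so each axis's largest-magnitude
        environment score is positive.
    axis_ss_, axis_df_ : ndarray
        Per-retained-axis SS (= r * theta_n**2) and Gollob df.
    residual_ss_, residual_df_ : float, int
        Interaction SS/df not captured by the retained axes.
    interaction_ss_ : float
    table_ : DataFrame
        ANOVA table with rows total, treatment, genotype, environment,
        interaction, ipca_1.., residual, error and columns
        ``source, df, ss, ms, F, p, pct``.
    r_ : int
        Block count.
    """

    def __init__(self, n_axes: int | None = 2):
        self.n_axes = n_axes

    def fit(self, X: pd.DataFrame, y=None) -> "AMMI":
        cell = aggregate_cell_means(X)
        g, e = cell.means.shape
        r = cell.r
        if g < 2 or e < 2:
            raise ValueError("need at least 2 genotypes and 2 environments")
        if r < 2:
            raise ValueError("need at least 2 blocks to estimate an error stratum")

        y_obs = pd.to_numeric(X["value"]).to_numpy(float)
        grand_obs = y_obs.mean()
        ss_total = float(((y_obs - grand_obs) ** 2).sum())

        dec = grand_decomposition(cell)
        rho = dec.genotype_effects.to_numpy()
        psi = dec.environment_effects.to_numpy()
        resid = dec.interaction_residuals.to_numpy()

        ss_gen = e * r * float((rho**2).sum())
        ss_env = g * r * float((psi**2).sum())
        ss_int = r * float((resid**2).sum())
        ss_treat = ss_gen + ss_env + ss_int
        ss_err = max(ss_total - ss_treat, 0.0)
        df_err = g * e * r - 1 - (g * e - 1)

        u, s, vt = np.linalg.svd(resid, full_matrices=False)
        k_full = min(g - 1, e - 1)
        s = s[:k_full]
        xi, eta = orient_axes(u[:, :k_full], vt[:k_full, :].T)

        m = k_full if self.n_axes is None else min(self.n_axes, k_full)
        if m < 1:
            raise ValueError("n_axes must retain at least one axis")
        axis_ss = r * s[:m] ** 2
        axis_df = np.array([gollob_df(g, e, n) for n in range(1, m + 1)])
        residual_ss = ss_int - float(axis_ss.sum())
        residual_df = (g - 1) * (e - 1) - int(axis_df.sum())

        names = [f"ipca_{n}" for n in range(1, m + 1)]
        rows = [
            ("total", g * e * r - 1, ss_total),
            ("treatment", g * e - 1, ss_treat),
            ("genotype", g - 1, ss_gen),
            ("environment", e - 1, ss_env),
            ("interaction", (g - 1) * (e - 1), ss_int),
            *zip(names, axis_df.tolist(), axis_ss.tolist()),
            ("residual", residual_df, max(residual_ss, 0.0)),
            ("error", df_err, ss_err),
        ]
        ms_err = ss_err / df_err
        tested = {"treatment", "genotype", "environment", "interaction", *names}
        table = []
        for source, df, ss in rows:
            ms = ss / df if df > 0 else np.nan
            f = p = np.nan
            if source in tested and df > 0:
                if ms_err > 0:
                    f = ms / ms_err
                    p = float(stats.f.sf(f, df, df_err))
                elif ms == 0:
                    f = 0.0
            table.append((source, df, ss, ms, f, p))
        table = pd.DataFrame(table, columns=AMMI_TABLE_COLUMNS[:-1])

        self.mu_ = dec.mu
        self.genotype_effects_ = dec.genotype_effects
        self.environment_effects_ = dec.environment_effects
        self.interaction_residuals_ = dec.interaction_residuals
        self.singular_values_ = s
        self.genotype_scores_ = pd.DataFrame(
            xi[:, :m], index=cell.means.index, columns=names
        )
        self.environment_scores_ = pd.DataFrame(
            eta[:, :m], index=cell.means.columns, columns=names
        )
        self.axis_ss_ = axis_ss
        self.axis_df_ = axis_df
        self.residual_ss_ = max(residual_ss, 0.0)
        self.residual_df_ = residual_df
        self.interaction_ss_ = ss_int
        self.r_ = r
        self.n_axes_ = m
        self.table_ = add_percentages(table)
        return self


def fit_ammi(table: pd.DataFrame, n_axes: int | None = 2) -> AMMI:
    """Fit an AMMI model to a balanced long-format table (thin wrapper)."""
    return AMMI(n_axes=n_axes).fit(table)
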