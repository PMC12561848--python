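"""Split-plot analysis of variance with two error strata.

The design: complete replicate blocks each contain one main plot per level
of the main-plot factor (here, water temperature); every main plot carries
all levels of the sub-plot factor (the enzyme assayed).  Because the two
factors are randomized at different levels, the main-plot factor is tested
against the main-plot error — the (main factor × block) stratum — while the
sub-plot factor and the interaction are tested against the residual
sub-plot error.

Model for observation y_{m,n,p} (main level m, sub level n, block p)::

    y = mu + a_p + g_{mn} + h_{mp} + eps_{mnp}

with block effects a_p, treatment effects g_{mn}, main-plot errors
h_{mp} ~ N(0, sigma_h^2) and sub-plot errors eps ~ N(0, sigma^2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .data_model import validate_activity_table

#: canonical row order of the split-plot ANOVA table
SPLITPLOT_SOURCES = (
    "blocks",
    "main_factor",
    "main_plot_error",
    "sub_factor",
    "interaction",
    "sub_plot_error",
    "total",
)


def splitplot_ss(y: np.ndarray) -> dict[str, float]:
    """Stratum sums of squares for a balanced array ``y[sub, main, block]``.

    Uses the standard balanced decomposition: each stratum SS is a scaled
    sum of squared deviations of the relevant marginal means; the sub-plot
    error is the remainder of the total.
    """
    y = np.asarray(y, float)
    s, m, r = y.shape
    grand = y.mean()
    block_means = y.mean(axis=(0, 1))
    main_means = y.mean(axis=(0, 2))
    sub_means = y.mean(axis=(1, 2))
    mainblock = y.mean(axis=0)          # (m, r) main-plot means
    cell = y.mean(axis=2)               # (s, m) treatment cell means

    ss_blocks = s * m * float(((block_means - grand) ** 2).sum())
    ss_main = s * r * float(((main_means - grand) ** 2).sum())
    ss_mpe = s * float(
        ((mainblock - main_means[:, None] - block_means[None, :] + grand) ** 2).sum()
    )
    ss_sub = m * r * float(((sub_means - grand) ** 2).sum())
    ss_int = r * float(
        ((cell - sub_means[:, None] - main_means[None, :] + grand) ** 2).sum()
    )
    ss_total = float(((y - grand) ** 2).sum())
    ss_spe = ss_total - ss_blocks - ss_main - ss_mpe - ss_sub - ss_int
    return {
        "blocks": ss_blocks,
        "main_factor": ss_main,
        "main_plot_error": ss_mpe,
        "sub_factor": ss_sub,
        "interaction": ss_int,
        "sub_plot_error": max(ss_spe, 0.0),
        "total": ss_total,
    }


def splitplot_table_from_ss(ss: dict[str, float], s: int, m: int, r: int) -> pd.DataFrame:
    """Assemble the ANOVA table (df, MS, F, p) from stratum SS.

    F(main) = MS(main)/MS(main-plot error); F(sub) and F(interaction) use
    MS(sub-plot error).  Blocks and error rows carry no F or p.
    """
    df = {
        "blocks": r - 1,
        "main_factor": m - 1,
        "main_plot_error": (m - 1) * (r - 1),
        "sub_factor": s - 1,
        "interaction": (m - 1) * (s - 1),
        "sub_plot_error": m * (r - 1) * (s - 1),
        "total": m * s * r - 1,
    }
    rows = []
    ms = {k: (ss[k] / df[k] if df[k] > 0 and k != "total" else np.nan)
          for k in SPLITPLOT_SOURCES}
    denom = {"main_factor": "main_plot_error",
             "sub_factor": "sub_plot_error",
             "interaction": "sub_plot_error"}
    for src in SPLITPLOT_SOURCES:
        f = p = np.nan
        if src in denom:
            ms_den = ms[denom[src]]
            if ms_den > 0:
                f = ms[src] / ms_den
                p = float(stats.f.sf(f, df[src], df[denom[src]]))
        rows.append((src, df[src], ss[src], ms[src], f, p))
    return pd.DataFrame(rows, columns=["source", "df", "ss", "ms", "F", "p"])


class SplitPlotAnova(BaseEstimator):
    """Split-plot ANOVA estimator for balanced long-format activity tables.

    Parameters
    ----------
    main_factor : {"environment", "genotype"}, default "environment"
        Column of the input table playing the main-plot role.
    sub_factor : {"genotype", "environment"}, default "genotype"
        Column playing the sub-plot role; must differ from ``main_factor``.

    Attributes
    ----------
    table_ : DataFrame
        ANOVA table with rows ``blocks, main_factor, main_plot_error,
        sub_factor, interaction, sub_plot_error, total`` and columns
        ``source, df, ss, ms, F, p``.
    n_main_levels_, n_sub_levels_, n_blocks_ : int
    grand_mean_ : float

    Examples
    --------
    >>> import pandas as pd
    >>> from gxekit import SplitPlotAnova
    >>> df = pd.DataFrame({
    ...     "genotype": ["A"] * 4 + ["B"] * 4,
    ...     "environment": ["E1", "E1", "E2", "E2"] * 2,
    ...     "block": ["b1", "b2"] * 4,
    ...     "value": [1, 3, 2, 4, 5, 7, 6, 8],
    ... })
    >>> SplitPlotAnova().fit(df).table_.loc[3, "ss"]   # sub-factor SS
    32.0
    """

    def __init__(self, main_factor: str = "environment", sub_factor: str = "genotype"):
        self.main_factor = main_factor
        self.sub_factor = sub_factor

    def fit(self, X: pd.DataFrame, y=None) -> "SplitPlotAnova":
        roles = {self.main_factor, self.sub_factor}
        if roles != {"genotype", "environment"}:
            raise ValueError(
                "main_factor and sub_factor must be 'genotype' and "
                f"'environment' in some order, got {self.main_factor!r}, "
                f"{self.sub_factor!r}"
            )
        orders = dict(zip(("genotype", "environment", "block"),
                          validate_activity_table(X)))
        sub_levels = orders[self.sub_factor]
        main_levels = orders[self.main_factor]
        blocks = orders["block"]
        s, m, r = len(sub_levels), len(main_levels), len(blocks)
        if s < 2 or m < 2:
            raise ValueError("need at least 2 levels of each factor")
        if r < 2:
            raise ValueError(
                "need at least 2 blocks: with r=1 the main-plot error "
                "stratum has zero degrees of freedom"
            )
        idx = {c: {lv: i for i, lv in enumerate(order)}
               for c, order in (("sub", sub_levels), ("main", main_levels),
                                ("block", blocks))}
        arr = np.empty((s, m, r))
        arr[
            [idx["sub"][v] for v in X[self.sub_factor]],
            [idx["main"][v] for v in X[self.main_factor]],
            [idx["block"][v] for v in X["block"]],
        ] = pd.to_numeric(X["value"]).to_numpy(float)

        ss = splitplot_ss(arr)
        self.table_ = splitplot_table_from_ss(ss, s, m, r)
        self.n_main_levels_ = m
        self.n_sub_levels_ = s
        self.n_blocks_ = r
        self.grand_mean_ = float(arr.mean())
        self.main_levels_ = main_levels
        self.sub_levels_ = sub_levels
        return self


def fit_split_plot(table: pd.DataFrame, main_factor: str = "environment",
                   sub_factor: str = "genotype") -> pd.DataFrame:
    """Fit a split-plot ANOVA and return its table (thin functional wrapper)."""
    return SplitPlotAnova(main_factor=main_factor, sub_factor=sub_factor).fit(table).table_


def ms_f_from_ss(rows, denominator_map: dict[str, str]) -> pd.DataFrame:
    """Recompute MS, F and p from (source, ss, df) triples.

    This is the validation path for already-summarized ANOVA tables: given
    only sums of squares and degrees of freedom, it fills in mean squares,
    F ratios (numerator source -> denominator source via
    ``denominator_map``) and upper-tail F-distribution p-values.

    Rows with df = 0 get undefined MS; a row with ss = 0 gets F = 0.
    Negative SS is an error.
    """
    out = []
    table = {}
    for source, ss, df in rows:
        if ss < 0:
            raise ValueError(f"negative sum of squares for {source!r}: {ss}")
        ms = ss / df if df > 0 else np.nan
        table[source] = (ss, df, ms)
        out.append([source, df, ss, ms, np.nan, np.nan])
    for row in out:
        source = row[0]
        den = denominator_map.get(source)
        if den is None:
            continue
        if den not in table:
            raise ValueError(f"denominator source {den!r} not present")
        ss_num, df_num, ms_num = table[source]
        ss_den, df_den, ms_den = table[den]
        if not np.isfinite(ms_num) or not np.isfinite(ms_den) or ms_den <= 0:
            continue
        f = 0.0 if ms_num == 0 else ms_num / ms_den
        row[4] = f
        row[5] = float(stats.f.sf(f, df_num, df_den))
    return pd.DataFrame(out, columns=["source", "df", "ss", "ms", "F", "p"])
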