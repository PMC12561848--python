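"""GGE biplot analysis: genotype main effect plus genotype × environment
interaction.

The two-way table of cell means is *environment-centered* — the environment
column means are subtracted, so genotype main effects (G) and interaction
(GE) are retained — and decomposed by SVD.  The first two axes give the
biplot; the singular value theta_n is partitioned between genotype and
environment markers by a scaling exponent f in [0, 1]::

    genotype coordinate  = theta_n**f     * xi_gn
    environment coordinate = theta_n**(1-f) * eta_en

so the inner product of a genotype and an environment marker reconstructs
the rank-2 approximation of the centered table regardless of f.

Four interpretive views are provided: environment relationships (angles
and vector lengths), which-won-where (convex hull + sector winners),
mean vs. stability (average-environment coordination), and the ideal-entry
ranking (concentric circles).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from sklearn.base import BaseEstimator

from .data_model import CellMeanMatrix, aggregate_cell_means
from .ammi import orient_axes

#: inner-product margin below which sector winners are reported as tied
WIN_TIE_TOL = 1e-9


def _as_cell_means(X) -> pd.DataFrame:
    if isinstance(X, CellMeanMatrix):
        return X.means
    if isinstance(X, pd.DataFrame) and {"genotype", "environment",
                                        "block", "value"} <= set(X.columns):
        return aggregate_cell_means(X).means
    if isinstance(X, pd.DataFrame):
        return X.astype(float)
    arr = np.asarray(X, float)
    return pd.DataFrame(
        arr,
        index=[f"G{i+1}" for i in range(arr.shape[0])],
        columns=[f"E{j+1}" for j in range(arr.shape[1])],
    )


class GGEBiplot(BaseEstimator):
    """Two-axis GGE model of a genotype × environment table.

    Parameters
    ----------
    scaling : float, default 0.5
        Singular-value partitioning exponent f: 0.5 is the symmetric
        biplot, 1.0 genotype-focused, 0.0 environment-focused.  Sector
        winners and all inner products are invariant to it.

    Attributes
    ----------
    centered_ : DataFrame
        Environment-centered table (column means removed).
    singular_values_ : ndarray
        All singular values of the centered table, non-increasing.
    var_explained_ : ndarray
        Fraction of total squared singular values captured per axis.
    genotype_coords_, environment_coords_ : DataFrame
        g × 2 and e × 2 marker coordinates (columns PC1, PC2).
    """

    def __init__(self, scaling: float = 0.5):
        self.scaling = scaling

    def fit(self, X, y=None) -> "GGEBiplot":
        if not 0.0 <= self.scaling <= 1.0:
            raise ValueError(f"scaling must lie in [0, 1], got {self.scaling}")
        means = _as_cell_means(X)
        if means.shape[1] < 2:
            raise ValueError("need at least 2 environments")
        arr = means.to_numpy(float)
        centered = arr - arr.mean(axis=0, keepdims=True)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        # zero out noise-level singular values: theta**f with f < 1 would
        # otherwise inflate numerical noise into visible coordinates
        if s.size and s[0] > 0:
            s = np.where(s > np.finfo(float).eps * max(centered.shape) * s[0],
                         s, 0.0)
        xi, eta = orient_axes(u, vt.T)

        total = float((s**2).sum())
        var = s**2 / total if total > 0 else np.zeros_like(s)

        f = self.scaling
        # theta**f is ill-defined at theta=0 for f=0; zero axes carry no
        # signal, so both markers get coordinate 0 there
        sf = np.where(s > 0, s, 1.0)
        gcoord = xi[:, :2] * np.where(s[:2] > 0, sf[:2] ** f, 0.0)
        ecoord = eta[:, :2] * np.where(s[:2] > 0, sf[:2] ** (1 - f), 0.0)

        self.centered_ = pd.DataFrame(centered, index=means.index,
                                      columns=means.columns)
        self.singular_values_ = s
        self.var_explained_ = var
        self.genotype_coords_ = pd.DataFrame(
            gcoord, index=means.index, columns=["PC1", "PC2"]
        )
        self.environment_coords_ = pd.DataFrame(
            ecoord, index=means.columns, columns=["PC1", "PC2"]
        )
        return self

    # -- views ---------------------------------------------------------

    def env_relationship(self) -> tuple[pd.DataFrame, pd.Series]:
        """Angles between environment vectors and their lengths.

        Small angles mean near-identical genotype rankings in the two
        environments; a long vector marks a discriminating environment.
        Angles involving a zero-length vector are NaN.
        """
        coords = self.environment_coords_.to_numpy()
        norms = np.linalg.norm(coords, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = (coords @ coords.T) / np.outer(norms, norms)
        angles = np.arccos(np.clip(cos, -1.0, 1.0))
        angles[norms == 0, :] = np.nan
        angles[:, norms == 0] = np.nan
        np.fill_diagonal(angles, np.where(norms == 0, np.nan, 0.0))
        envs = self.environment_coords_.index
        return (
            pd.DataFrame(angles, index=envs, columns=envs),
            pd.Series(norms, index=envs, name="vector_length"),
        )

    def which_won_where(self) -> tuple[list, dict]:
        """Convex hull of genotype markers and per-environment winners.

        Rays from the origin perpendicular to the hull edges partition the
        biplot into sectors; the vertex genotype of a sector wins in every
        environment falling inside it — equivalently, it maximizes the
        inner product with the environment vector among all genotypes.
        Winners within ``WIN_TIE_TOL`` of the maximum are all reported, in
        genotype order.
        """
        gc = self.genotype_coords_.to_numpy()
        genotypes = list(self.genotype_coords_.index)
        try:
            if len(genotypes) < 3:
                raise QhullError("fewer than 3 genotypes")
            hull = ConvexHull(gc)
            hull_vertices = [genotypes[i] for i in hull.vertices]
        except QhullError:
            warnings.warn(
                "genotype markers are collinear or too few for a convex "
                "hull; falling back to direct inner-product winners",
                stacklevel=2,
            )
            hull_vertices = []

        inner = gc @ self.environment_coords_.to_numpy().T  # g × e
        sectors = {}
        for j, env in enumerate(self.environment_coords_.index):
            col = inner[:, j]
            best = col.max()
            tied = [genotypes[i] for i in range(len(genotypes))
                    if best - col[i] <= WIN_TIE_TOL]
            sectors[env] = tied[0] if len(tied) == 1 else tuple(tied)
        return hull_vertices, sectors

    def mean_vs_stability(self) -> tuple[pd.Series, pd.Series]:
        """Average-environment-coordination (AEC) projections and distances.

        The AEC axis is the unit vector toward the mean of the environment
        markers.  A genotype's projection onto it proxies mean
        performance; the norm of the orthogonal component proxies
        instability (larger = less stable).
        """
        ecoords = self.environment_coords_.to_numpy()
        mean_env = ecoords.mean(axis=0)
        norm = np.linalg.norm(mean_env)
        scale = np.linalg.norm(ecoords, axis=1).max(initial=0.0)
        if norm <= 1e-9 * scale or scale == 0:
            raise ValueError(
                "average environment vector has zero length; the AEC axis "
                "is undefined"
            )
        axis = mean_env / norm
        gc = self.genotype_coords_.to_numpy()
        proj = gc @ axis
        ortho = gc - np.outer(proj, axis)
        dist = np.linalg.norm(ortho, axis=1)
        idx = self.genotype_coords_.index
        return (
            pd.Series(proj, index=idx, name="aec_projection"),
            pd.Series(dist, index=idx, name="aec_distance"),
        )

    def ideal_entry(self) -> tuple[pd.Series, list]:
        """Distance of each genotype to the ideal entry, and the ranking.

        The ideal entry sits on the positive AEC axis at the longest
        genotype projection: maximal mean performance with zero
        instability.  Smaller distance = better combined activity and
        stability; ties rank in genotype order.
        """
        proj, _ = self.mean_vs_stability()
        mean_env = self.environment_coords_.to_numpy().mean(axis=0)
        axis = mean_env / np.linalg.norm(mean_env)
        ideal = axis * proj.max()
        gc = self.genotype_coords_.to_numpy()
        dist = np.linalg.norm(gc - ideal, axis=1)
        idx = self.genotype_coords_.index
        series = pd.Series(dist, index=idx, name="ideal_distance")
        order = np.argsort(dist, kind="stable")
        return series, [idx[i] for i in order]

    def views(self) -> dict:
        """All four views in one JSON-serializable dictionary."""
        angles, lengths = self.env_relationship()
        hull, sectors = self.which_won_where()
        proj, dist = self.mean_vs_stability()
        ideal, ranking = self.ideal_entry()
        return {
            "var_explained": self.var_explained_[:2].tolist(),
            "env_angles_deg": np.degrees(angles).round(6).to_dict(),
            "env_vector_lengths": lengths.to_dict(),
            "hull_vertices": hull,
            "sector_winners": {
                str(k): (list(v) if isinstance(v, tuple) else v)
                for k, v in sectors.items()
            },
            "aec_projection": proj.to_dict(),
            "aec_distance": dist.to_dict(),
            "mean_performance_ranking": list(
                proj.sort_values(ascending=False, kind="stable").index
            ),
            "stability_ranking": list(
                dist.sort_values(kind="stable").index
            ),
            "ideal_distance": ideal.to_dict(),
            "ideal_entry_ranking": ranking,
        }


def fit_gge(matrix, scaling_f: float = 0.5) -> GGEBiplot:
    """Fit a GGE biplot model to a cell-mean matrix or long table."""
    return GGEBiplot(scaling=scaling_f).fit(matrix)
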