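"""Shared containers for balanced genotype × environment × block activity data.

The long-format container is a plain :class:`pandas.DataFrame` with columns
``genotype``, ``environment``, ``block`` and ``value`` — one row per
observation of one enzyme ("genotype" role) at one temperature
("environment" role) in one replicate block.  All analyses require a
*balanced* design: every (genotype, environment, block) combination present
exactly once.  Labels are opaque; numeric-looking environment labels
(temperatures) are never interpreted ordinally — only their ordering of
first appearance (or a caller-supplied ordering) is used, and only for
display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("genotype", "environment", "block", "value")


class UnbalancedDesignError(ValueError):
    """Raised when a (genotype, environment, block) combination is missing
    or duplicated."""


def _unique_in_order(values) -> list:
    seen: dict = {}
    for v in values:
        if v not in seen:
            seen[v] = None
    return list(seen)


def validate_activity_table(table: pd.DataFrame) -> tuple[list, list, list]:
    """Validate a long-format activity table and return its factor orders.

    Parameters
    ----------
    table : DataFrame
        Long-format data with columns ``genotype``, ``environment``,
        ``block``, ``value``.  Extra columns are ignored.

    Returns
    -------
    (genotype_order, environment_order, block_order) : lists
        Levels of each factor in order of first appearance.

    Raises
    ------
    UnbalancedDesignError
        If any combination is missing or duplicated; the message names the
        offending combination.
    ValueError
        For missing columns, empty labels or non-finite values.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    if len(table) == 0:
        raise ValueError("empty table")

    values = pd.to_numeric(table["value"], errors="coerce").to_numpy(float)
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise ValueError(
            f"non-finite or non-numeric value at row {bad[0]}: "
            f"{table['value'].iloc[bad[0]]!r}"
        )
    for col in ("genotype", "environment", "block"):
        labels = table[col].astype(str)
        if (labels.str.len() == 0).any():
            raise ValueError(f"empty label in column {col!r}")

    genotypes = _unique_in_order(table["genotype"])
    environments = _unique_in_order(table["environment"])
    blocks = _unique_in_order(table["block"])

    counts = table.groupby(
        ["genotype", "environment", "block"], sort=False, observed=True
    ).size()
    dup = counts[counts > 1]
    if len(dup):
        g, e, b = dup.index[0]
        raise UnbalancedDesignError(
            f"duplicated combination genotype={g!r}, environment={e!r}, "
            f"block={b!r} ({dup.iloc[0]} occurrences)"
        )
    expected = len(genotypes) * len(environments) * len(blocks)
    if len(counts) != expected:
        have = set(counts.index)
        for g in genotypes:
            for e in environments:
                for b in blocks:
                    if (g, e, b) not in have:
                        raise UnbalancedDesignError(
                            f"missing combination genotype={g!r}, "
                            f"environment={e!r}, block={b!r}"
                        )
    return genotypes, environments, blocks


@dataclass
class CellMeanMatrix:
    """Two-way table of cell means over blocks.

    Attributes
    ----------
    means : DataFrame
        g × e matrix; rows indexed by genotype, columns by environment, each
        entry the arithmetic mean of the r replicate values for that cell.
    r : int
        Number of complete blocks averaged over.
    """

    means: pd.DataFrame
    r: int

    @property
    def genotype_order(self) -> list:
        return list(self.means.index)

    @property
    def environment_order(self) -> list:
        return list(self.means.columns)

    def to_array(self) -> np.ndarray:
        return self.means.to_numpy(float)


@dataclass
class GrandDecomposition:
    """Additive decomposition of a cell-mean matrix.

    ``means = mu + genotype_effects[g] + environment_effects[e] + residuals``
    with both effect vectors summing to zero and the interaction residuals
    doubly centered (zero row and column sums).
    """

    mu: float
    genotype_effects: pd.Series
    environment_effects: pd.Series
    interaction_residuals: pd.DataFrame = field(repr=False)


def aggregate_cell_means(table: pd.DataFrame) -> CellMeanMatrix:
    """Average a balanced long-format table over blocks into a g × e matrix."""
    genotypes, environments, blocks = validate_activity_table(table)
    wide = (
        table.assign(value=pd.to_numeric(table["value"]))
        .pivot_table(index="genotype", columns="environment", values="value",
                     aggfunc="mean", observed=True)
        .reindex(index=genotypes, columns=environments)
    )
    wide.index.name = "genotype"
    wide.columns.name = "environment"
    return CellMeanMatrix(means=wide, r=len(blocks))


def grand_decomposition(matrix: CellMeanMatrix | pd.DataFrame) -> GrandDecomposition:
    """Split a two-way table into grand mean, main-effect deviations and
    doubly-centered interaction residuals."""
    means = matrix.means if isinstance(matrix, CellMeanMatrix) else matrix
    arr = means.to_numpy(float)
    mu = float(arr.mean())
    rho = arr.mean(axis=1) - mu
    psi = arr.mean(axis=0) - mu
    resid = arr - mu - rho[:, None] - psi[None, :]
    return GrandDecomposition(
        mu=mu,
        genotype_effects=pd.Series(rho, index=means.index, name="genotype_effect"),
        environment_effects=pd.Series(
            psi, index=means.columns, name="environment_effect"
        ),
        interaction_residuals=pd.DataFrame(
            resid, index=means.index, columns=means.columns
        ),
    )
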