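"""Reading and writing the package's file formats.

Long-format CSV in (``genotype,environment,block,value``, UTF-8, decimal
point, extra columns ignored); ANOVA tables and biplot coordinates out as
CSV at full precision.  Human-readable reports round to conventional table
precision and render tiny p-values as ``<0.001``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import REQUIRED_COLUMNS, validate_activity_table

P_DISPLAY_THRESHOLD = 1e-3


def read_long_csv(path) -> pd.DataFrame:
    """Read and validate a balanced long-format activity CSV."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(values.to_numpy(float)))
    if bad.size:
        # +2: header line and 1-based numbering
        raise ValueError(
            f"{path}: non-numeric value {df['value'].iloc[bad[0]]!r} "
            f"on line {bad[0] + 2}"
        )
    df = df.copy()
    df["value"] = values
    try:
        validate_activity_table(df)
    except ValueError as exc:
        raise type(exc)(f"{path}: {exc}") from None
    return df


def write_long_csv(table: pd.DataFrame, path) -> None:
    """Write a long-format activity table at 12 significant digits."""
    table.to_csv(path, index=False, float_format="%.12g")


def write_anova_csv(table: pd.DataFrame, path) -> None:
    """Write an ANOVA table at full precision."""
    table.to_csv(path, index=False, float_format="%.17g")


def format_p(p: float, threshold: float = P_DISPLAY_THRESHOLD,
             decimals: int = 4) -> str:
    """Render a p-value the way ANOVA tables conventionally print it."""
    if not np.isfinite(p):
        return ""
    if p < threshold:
        return f"<{threshold:g}"
    return f"{p:.{decimals}f}"


def format_anova_report(table: pd.DataFrame, title: str = "") -> str:
    """Human-readable ANOVA table: 4 decimals for SS/MS, 3 for F."""
    lines = []
    if title:
        lines += [title, "=" * len(title)]
    header = f"{'source':<18}{'df':>5}{'SS':>14}{'MS':>14}{'F':>10}{'p':>9}"
    has_pct = "pct" in table.columns
    if has_pct:
        header += f"{'%SS':>9}"
    lines.append(header)
    for _, row in table.iterrows():
        ms = f"{row['ms']:.4f}" if np.isfinite(row["ms"]) else ""
        f_ = f"{row['F']:.3f}" if np.isfinite(row["F"]) else ""
        p_ = format_p(row["p"]) if np.isfinite(row["p"]) else ""
        line = (f"{row['source']:<18}{int(row['df']):>5}"
                f"{row['ss']:>14.4f}{ms:>14}{f_:>10}{p_:>9}")
        if has_pct:
            pct = f"{row['pct']:.4f}" if np.isfinite(row["pct"]) else ""
            line += f"{pct:>9}"
        lines.append(line)
    return "\n".join(lines)
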