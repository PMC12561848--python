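"""Replay of reference ANOVA summaries as an arithmetic validation harness.

The tables below transcribe published split-plot and AMMI analysis-of-
variance summaries for enzyme activity of the large yellow croaker
(*Larimichthys crocea*) under winter water cooling: four antioxidant
factors (SOD, POD, CAT, T-AOC) assayed in liver and muscle, and six serum
enzymes (ALT, AST, ALP, LIP, ADA, GGT), each measured at five water
temperatures (20, 16, 12, 10, 8 degC) in six complete blocks.  Only the
sums of squares and degrees of freedom are inputs; the harness recomputes
every mean square, F ratio, p-value and percent-of-SS column and compares
it with the printed value at the printed number of decimals.

Printed values are kept as *strings* so the number of printed decimals is
known; a recomputed cell agrees when it differs from the printed value by
at most one unit in the last printed digit (the source tables round
intermediate mean squares, so half-ulp agreement is not always possible).
A printed p of ``<0.001`` is checked as an upper bound, and a printed
``0`` as p < 1e-4.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ammi import add_percentages
from .splitplot import ms_f_from_ss

# rows: (source, ss, df, printed_ms, printed_f, printed_p) — None if blank
SPLITPLOT_REFERENCE = {
    "liver_antioxidant": [
        ("blocks", 106.2773, 5, "21.2555", None, None),
        ("main_factor", 215.4319, 4, "53.858", "1.567", "0.2217"),
        ("main_plot_error", 687.4302, 20, "34.3715", None, None),
        ("sub_factor", 64644.578, 3, "21548.193", "690.332", "<0.001"),
        ("interaction", 717.6689, 12, "59.8057", "1.916", "0.0456"),
        ("sub_plot_error", 2341.067, 75, "31.2142", None, None),
        ("total", 68712.453, 119, None, None, None),
    ],
    "muscle_antioxidant": [
        ("blocks", 3.31, 5, "0.662", None, None),
        ("main_factor", 76.8437, 4, "19.2109", "65.546", "<0.001"),
        ("main_plot_error", 5.8618, 20, "0.2931", None, None),
        ("sub_factor", 1580.4493, 3, "526.8164", "1259.117", "<0.001"),
        ("interaction", 156.9203, 12, "13.0767", "31.254", "<0.001"),
        ("sub_plot_error", 31.3801, 75, "0.4184", None, None),
        ("total", 1854.7651, 119, None, None, None),
    ],
    "serum_enzyme": [
        ("blocks", 65.5821, 5, "13.1164", None, None),
        ("main_factor", 2258.2031, 4, "564.5508", "47.63", "<0.001"),
        ("main_plot_error", 237.0588, 20, "11.8529", None, None),
        ("sub_factor", 100879.87, 5, "20175.974", "1170.82", "<0.001"),
        ("interaction", 7044.8701, 20, "352.2435", "20.441", "<0.001"),
        ("sub_plot_error", 2154.0429, 125, "17.2323", None, None),
        ("total", 112639.63, 179, None, None, None),
    ],
}

# rows: (source, df, ss, printed_ms, printed_f, printed_p, printed_pct)
AMMI_REFERENCE = {
    "liver_antioxidant": [
        ("total", 119, 68712.453, "577.4156", None, None, None),
        ("treatment", 19, 65577.679, "3451.4568", "110.1022", "0", None),
        ("genotype", 3, 64644.578, "21548.193", "687.3921", "0", "94.0799"),
        ("environment", 4, 215.4319, "53.858", "1.7181", "0.1519", "0.3135"),
        ("interaction", 12, 717.6689, "59.8057", "1.9078", "0.0420", "1.0445"),
        ("ipca_1", 6, 713.59043, "118.93174", "3.79395", "0.0019", "99.4317"),
        ("ipca_2", 4, 2.89303, "0.72326", "0.02307", "0.9989", "0.4031"),
        ("residual", 2, 1.18546, "0.59273", None, None, None),
        ("error", 100, 3134.7745, "31.34774", None, None, None),
    ],
    "muscle_antioxidant": [
        ("total", 119, 1854.7651, "15.5863", None, None, None),
        ("treatment", 19, 1814.2133, "95.4849", "235.4638", "0", None),
        ("genotype", 3, 1580.4493, "526.8164", "1299.1182", "0", "85.2102"),
        ("environment", 4, 76.8437, "19.2109", "47.3737", "0", "4.1430"),
        ("interaction", 12, 156.9203, "13.0767", "32.2468", "0", "8.4604"),
        ("ipca_1", 6, 156.70159, "26.11693", "64.4038", "0", "99.8606"),
        ("ipca_2", 4, 0.17806, "0.04451", "0.1098", "0.9788", "0.1135"),
        ("residual", 2, 0.04063, "0.02031", None, None, None),
        ("error", 100, 40.55185, "0.40552", None, None, None),
    ],
    "serum_enzyme": [
        ("total", 179, 112639.63, "629.2717", None, None, None),
        ("treatment", 29, 110182.94, "3799.4118", "231.9842", "0", None),
        ("genotype", 5, 100879.87, "20175.974", "1231.903", "0", "89.5598"),
        ("environment", 4, 2258.2031, "564.5508", "34.4703", "0", "2.0048"),
        ("interaction", 20, 7044.8701, "352.2435", "21.5073", "0", "6.2543"),
        ("ipca_1", 8, 6894.0632, "861.75791", "52.6171", "0", "97.8593"),
        ("ipca_2", 6, 113.46768, "18.91128", "1.15468", "0.3338", "1.6106"),
        ("residual", 6, 37.33918, "6.2232", None, None, None),
        ("error", 150, 2456.6838, "16.37789", None, None, None),
    ],
}

#: (genotypes, environments) of each reference design
REFERENCE_DESIGNS = {
    "liver_antioxidant": (4, 5),
    "muscle_antioxidant": (4, 5),
    "serum_enzyme": (6, 5),
}

SPLITPLOT_DENOMINATORS = {
    "main_factor": "main_plot_error",
    "sub_factor": "sub_plot_error",
    "interaction": "sub_plot_error",
}


def _decimals(printed: str) -> int:
    return len(printed.split(".")[1]) if "." in printed else 0


def _agrees(computed: float, printed: str) -> bool:
    """Agreement at printed precision: within one unit in the last digit."""
    if printed.startswith("<"):
        return computed < float(printed[1:])
    if printed == "0":
        return computed < 1e-4
    tol = 10.0 ** (-_decimals(printed))
    return abs(computed - float(printed)) <= tol * (1 + 1e-6)


def _compare(records, table, name, source, quantity, computed, printed):
    if printed is None:
        return
    records.append({
        "table": table, "name": name, "source": source, "quantity": quantity,
        "computed": computed, "printed": printed,
        "ok": bool(np.isfinite(computed)) and _agrees(computed, printed),
    })


def validate_printed_tables() -> pd.DataFrame:
    """Recompute MS/F/p/%SS of every reference table from SS and df alone.

    Returns a tidy report with one row per printed cell and a boolean
    ``ok`` column marking agreement at printed precision.
    """
    records: list[dict] = []

    for name, rows in SPLITPLOT_REFERENCE.items():
        computed = ms_f_from_ss(
            [(s, ss, df) for s, ss, df, *_ in rows], SPLITPLOT_DENOMINATORS
        ).set_index("source")
        for source, ss, df, p_ms, p_f, p_p in rows:
            if source != "total":
                _compare(records, "splitplot", name, source, "ms",
                         computed.loc[source, "ms"], p_ms)
            _compare(records, "splitplot", name, source, "F",
                     computed.loc[source, "F"], p_f)
            _compare(records, "splitplot", name, source, "p",
                     computed.loc[source, "p"], p_p)

    for name, rows in AMMI_REFERENCE.items():
        d = {s: (df, ss) for s, df, ss, *_ in rows}
        df_err, ss_err = d["error"]
        ms_err = ss_err / df_err
        pct_table = add_percentages(
            pd.DataFrame(
                [(s, df, ss) for s, df, ss, *_ in rows],
                columns=["source", "df", "ss"],
            )
        ).set_index("source")
        for source, df, ss, p_ms, p_f, p_p, p_pct in rows:
            ms = ss / df if df > 0 else np.nan
            _compare(records, "ammi", name, source, "ms", ms, p_ms)
            if p_f is not None:
                f = ms / ms_err
                _compare(records, "ammi", name, source, "F", f, p_f)
                _compare(records, "ammi", name, source, "p",
                         float(stats.f.sf(f, df, df_err)), p_p)
            _compare(records, "ammi", name, source, "pct",
                     pct_table.loc[source, "pct"], p_pct)

    return pd.DataFrame.from_records(records)
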