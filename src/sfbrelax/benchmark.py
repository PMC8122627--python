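"""Bundled benchmark table of published oligosaccharide 13C relaxation data.

Six small sugars (32 experiment rows) with experimental T1/T2/NOE, the
corresponding reference-model calculated values at the per-system optimal
Reff, and the reference per-entry percentage deviations as printed in the
source tables. Used by the deviation-statistics acceptance checks.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .relaxation import DeviationReport, deviation_summary

__all__ = ["load_benchmark", "benchmark_deviation_report"]


def load_benchmark() -> pd.DataFrame:
    """The 32-row benchmark table as a DataFrame."""
    ref = importlib.resources.files("sfbrelax") / "data" / "oligosaccharide_benchmark.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def benchmark_deviation_report() -> DeviationReport:
    """Deviation statistics recomputed from the (exp, calc) pairs of the table."""
    df = load_benchmark()
    table = {
        "T1": list(zip(df["T1_exp_ms"], df["T1_calc_ms"])),
        "T2": list(zip(df["T2_exp_ms"], df["T2_calc_ms"])),
        "NOE": list(zip(df["NOE_exp"], df["NOE_calc"])),
    }
    return deviation_summary(table)
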