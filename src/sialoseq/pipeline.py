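"""End-to-end orchestration: simulate -> count -> test -> summarize.

Used for parameter-recovery studies: run the full analysis on a simulated
design with known truth and score how well the planted signal is recovered.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import expression, polymorphism, read_processing, synthetic_data
from .io_formats import CdsRecord, read_vcf_snps


def count_all_libraries(
    design: pd.DataFrame, index: read_processing.CdsIndex
) -> dict[str, read_processing.LibraryCounts]:
    """Run trim/filter/map counting for every library in a design table."""
    return {
        row.library_id: read_processing.count_library(
            row.fastq, index, library_id=row.library_id
        )
        for row in design.itertuples()
    }


def called_sets(
    tables: Mapping[str, pd.DataFrame]
) -> dict[str, dict[str, set]]:
    """Called CDS per contrast, split by direction."""
    out = {}
    for name, df in tables.items():
        out[name] = {
            "over_in_1": set(df.index[df["call"] == "over_in_1"]),
            "over_in_2": set(df.index[df["call"] == "over_in_2"]),
        }
    return out


def score_expression_recovery(
    truth: pd.DataFrame,
    tables: Mapping[str, pd.DataFrame],
    stages=("nymph", "adult"),
) -> dict:
    """Sensitivity and FDR of over-expression calls against planted effects.

    A planted CDS counts as recovered when any contrast calls it over in
    either direction; a called CDS with no planted effect is a false
    positive.
    """
    planted = set(truth.loc[truth["effect_type"] != "none", "cds_id"])
    called: set[str] = set()
    for sets in called_sets(tables).values():
        called |= sets["over_in_1"] | sets["over_in_2"]
    tp = len(called & planted)
    fp = len(called - planted)
    sensitivity = tp / len(planted) if planted else float("nan")
    fdr = fp / len(called) if called else 0.0
    return {
        "n_planted": len(planted),
        "n_called": len(called),
        "true_positives": tp,
        "false_positives": fp,
        "sensitivity": sensitivity,
        "fdr": fdr,
    }


def score_snp_recovery(
    class_table: pd.DataFrame, configured_rates: Mapping[str, tuple]
) -> pd.DataFrame:
    """Recovered vs configured class NS/S ratios (relative errors included)."""
    rows = []
    for row in class_table.itertuples():
        s_rate, ns_rate = configured_rates[row.class_label]
        expected = ns_rate / s_rate if s_rate else float("nan")
        rows.append(
            {
                "class_label": row.class_label,
                "configured_ns_s": expected,
                "recovered_ns_s": row.ns_over_s,
                "relative_error": abs(row.ns_over_s - expected) / expected
                if expected
                else float("nan"),
                "n_cds": row.n_cds,
            }
        )
    return pd.DataFrame(rows)


def run_parameter_recovery(
    config: synthetic_data.SimulationConfig,
    workdir,
    fold: float = 10.0,
    alpha: float = 0.05,
    mtc: str | None = "bonferroni",
) -> dict:
    """Simulate the full design, run the complete pipeline, score recovery.

    Returns a dict with the expression recovery scores, the NS/S recovery
    table, and the intermediate objects for inspection.
    """
    workdir = Path(workdir)
    cds_set, truth, design, truth_counts, truth_snps = synthetic_data.simulate_study(
        config, workdir
    )
    index = read_processing.build_index(cds_set)
    counts = count_all_libraries(design, index)
    contrasts = expression.build_contrasts(
        counts, design[["library_id", "stage", "region"]], cds_ids=list(cds_set)
    )
    tables = expression.call_overexpression(contrasts, fold=fold, alpha=alpha, mtc=mtc)
    de_scores = score_expression_recovery(truth, tables)

    calls = read_vcf_snps(workdir / "snps.vcf", cds_set)
    kept = polymorphism.filter_snps(calls)
    summaries = polymorphism.summaries_for_cds_set(kept, cds_set)
    class_of = dict(zip(truth["cds_id"], truth["class_label"]))
    class_table = polymorphism.rates_per_class(summaries.values(), class_of)
    snp_scores = score_snp_recovery(class_table, config.snp_rates)

    return {
        "expression": de_scores,
        "snp_recovery": snp_scores,
        "class_table": class_table,
        "de_tables": tables,
        "counts": counts,
        "truth": truth,
        "design": design,
    }
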