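"""Bundled published summary tables used as inputs to arithmetic checks.

These TSVs carry per-library sequencing totals, per-class CDS/read counts
and per-class polymorphism means as printed, together with the printed
derived columns so the package's arithmetic can be validated against them.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("sialoseq.data") / name
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_run_metadata() -> pd.DataFrame:
    """Per-library sequencing totals (sequences, residues) for the 10
    salivary-gland libraries, with the printed average lengths."""
    return _load("run_metadata.tsv")


def load_class_read_counts() -> pd.DataFrame:
    """Per-class CDS and mapped-read totals with the printed derived
    reads/CDS and percentage columns."""
    return _load("class_read_counts.tsv")


def load_polymorphism_class_means() -> pd.DataFrame:
    """Per-class mean S and NS polymorphism rates per 100 codons (with SEs),
    the printed NS/S ratios and polymorphic-CDS counts."""
    return _load("polymorphism_class_means.tsv")
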