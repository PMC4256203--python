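"""rDNA haplotype collapsing and alignment-column classification.

Operates on multiple sequence alignments of marker sequences (typically the
ITS-1 / 5.8S / ITS-2 rDNA intergenic region).  Identical aligned sequences
are collapsed into haplotypes; alignment columns are classified as variable
vs invariant, and variable columns are split into mutually exclusive
substitution vs gapped categories, with substitutions further divided into
parsimony-informative and singleton sites.

Gap accounting: any variable column containing a gap character counts as
"gapped" and is excluded from the substitution categories, so that
``n_variable == n_substitution + n_gapped`` holds exactly.  Ambiguity codes
(N, Y, R, ...) are treated as missing data: they neither create variability
nor contribute to distinct-state counts.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import GAP

_BASES = frozenset("ACGT")


@dataclass
class AlignmentSummary:
    """Column-classification counts for one alignment, with percentages.

    Percentages are ``100 * count / n_columns`` rounded to 2 decimals.
    """

    n_columns: int
    n_variable: int
    n_substitution: int
    n_parsimony_informative: int
    n_singleton: int
    n_gapped: int

    def __post_init__(self) -> None:
        if self.n_columns <= 0:
            raise ValueError("empty alignment")
        if self.n_variable != self.n_substitution + self.n_gapped:
            raise ValueError("variable sites must split into substitution + gapped")
        if self.n_substitution != self.n_parsimony_informative + self.n_singleton:
            raise ValueError(
                "substitution sites must split into parsimony-informative + singleton"
            )
        for v in (self.n_variable, self.n_substitution, self.n_gapped,
                  self.n_parsimony_informative, self.n_singleton):
            if not 0 <= v <= self.n_columns:
                raise ValueError("counts must lie within [0, n_columns]")

    def _pct(self, count: int) -> float:
        return round(100.0 * count / self.n_columns, 2)

    @property
    def pct_variable(self) -> float:
        return self._pct(self.n_variable)

    @property
    def pct_substitution(self) -> float:
        return self._pct(self.n_substitution)

    @property
    def pct_parsimony_informative(self) -> float:
        return self._pct(self.n_parsimony_informative)

    @property
    def pct_singleton(self) -> float:
        return self._pct(self.n_singleton)

    @property
    def pct_gapped(self) -> float:
        return self._pct(self.n_gapped)


def _check_aligned(sequences: Sequence[str]) -> int:
    lengths = {len(s) for s in sequences}
    if len(lengths) > 1:
        raise ValueError(f"sequences are not aligned: lengths {sorted(lengths)}")
    if not sequences or not lengths:
        raise ValueError("empty alignment")
    return lengths.pop()


def classify_column(column: Sequence[str]) -> str:
    """Classify one alignment column.

    Returns one of ``invariant``, ``gapped``, ``parsimony_informative``,
    ``singleton``.  Symbols outside {A,C,G,T,-} are ignored as missing.
    """
    symbols = [c for c in (s.upper() for s in column) if c in _BASES or c == GAP]
    distinct = set(symbols)
    if len(distinct) <= 1:
        return "invariant"
    if GAP in distinct:
        return "gapped"
    counts = {b: symbols.count(b) for b in distinct}
    if sum(1 for v in counts.values() if v >= 2) >= 2:
        return "parsimony_informative"
    return "singleton"


def column_classify(
    sequences: Sequence[str] | Mapping[str, str],
) -> tuple[AlignmentSummary, list[str]]:
    """Classify every column of an alignment.

    Accepts a list of aligned sequences or an ``{id: sequence}`` mapping with
    at least two members.  Returns the summary and the per-column states.
    """
    if isinstance(sequences, Mapping):
        sequences = list(sequences.values())
    if len(sequences) < 2:
        raise ValueError("column classification needs at least 2 sequences")
    n_cols = _check_aligned(sequences)
    states = [
        classify_column([s[i] for s in sequences]) for i in range(n_cols)
    ]
    gapped = states.count("gapped")
    pinfo = states.count("parsimony_informative")
    singleton = states.count("singleton")
    summary = AlignmentSummary(
        n_columns=n_cols,
        n_variable=gapped + pinfo + singleton,
        n_substitution=pinfo + singleton,
        n_parsimony_informative=pinfo,
        n_singleton=singleton,
        n_gapped=gapped,
    )
    return summary, states


# ---------------------------------------------------------------------------
# Haplotype collapsing

@dataclass
class Haplotype:
    label: str
    sequence: str
    member_ids: list[str] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.member_ids)


@dataclass
class HaplotypeTable:
    """Identical-sequence groups with labels and per-category counts."""

    haplotypes: list[Haplotype]
    crosstab: pd.DataFrame | None = None  # rows: labels, columns: categories

    def __len__(self) -> int:
        return len(self.haplotypes)

    def by_label(self) -> dict[str, Haplotype]:
        return {h.label: h for h in self.haplotypes}


def _labels(style: str):
    if style == "number":
        i = 1
        while True:
            yield str(i)
            i += 1
    elif style == "letter":
        letters = string.ascii_uppercase
        i = 0
        while True:
            # A..Z, then AA, AB, ...
            label, j = "", i
            while True:
                label = letters[j % 26] + label
                j = j // 26 - 1
                if j < 0:
                    break
            yield label
            i += 1
    else:
        raise ValueError(f"unknown label style {style!r}")


def collapse_haplotypes(
    records: Sequence[tuple[str, str]],
    categories: Mapping[str, str] | None = None,
    label_style: str = "number",
    rename: Mapping[str, str] | None = None,
) -> HaplotypeTable:
    """Group identical aligned sequences into haplotypes.

    Labels are assigned in order of first appearance: numbers for the
    ITS-2 convention (``label_style='number'``) or capital letters for ITS-1
    (``'letter'``).  ``rename`` maps the automatic labels onto biological
    names.  ``categories`` (id -> origin/ecotope category) yields a
    haplotype-by-category count table.
    """
    _check_aligned([seq for _, seq in records])
    gen = _labels(label_style)
    table: dict[str, Haplotype] = {}
    for name, seq in records:
        seq = seq.upper()
        if seq not in table:
            table[seq] = Haplotype(label=next(gen), sequence=seq)
        table[seq].member_ids.append(name)
    haps = list(table.values())
    if rename:
        for h in haps:
            h.label = rename.get(h.label, h.label)
    crosstab = None
    if categories is not None:
        rows = [
            {"haplotype": h.label, "category": categories[m]}
            for h in haps
            for m in h.member_ids
        ]
        crosstab = (
            pd.crosstab(
                pd.Series([r["haplotype"] for r in rows], name="haplotype"),
                pd.Series([r["category"] for r in rows], name="category"),
            )
            .reindex([h.label for h in haps])
        )
    return HaplotypeTable(haplotypes=haps, crosstab=crosstab)


def composite_label(its2_label: str, its1_label: str, prefix: str = "CH") -> str:
    """Join an ITS-2 (numeric) and ITS-1 (alphabetic) haplotype label."""
    return f"{prefix}{its2_label}{its1_label}"


# ---------------------------------------------------------------------------
# Composition and site tables

def composition_stats(sequence: str) -> tuple[int, float, float]:
    """(length bp, AT%, GC%) of a sequence; gaps are stripped first.

    AT% = 100*(A+T)/(A+C+G+T) rounded to 2 decimals; GC% = 100 - AT%.
    """
    seq = sequence.upper().replace(GAP, "")
    counted = sum(seq.count(b) for b in "ACGT")
    if counted == 0:
        raise ValueError("zero-length sequence (after gap stripping)")
    at = round(100.0 * (seq.count("A") + seq.count("T")) / counted, 2)
    return len(seq), at, round(100.0 - at, 2)


def polymorphic_site_table(
    records: Sequence[tuple[str, str]], reference_id: str
) -> pd.DataFrame:
    """Variable-site matrix: rows = sequences, columns = 1-based variable
    alignment positions; cells show '.' when identical to the reference,
    the base when substituted, '-' for a gap.
    """
    ids = [name for name, _ in records]
    if reference_id not in ids:
        raise ValueError(f"reference {reference_id!r} not in alignment")
    seqs = {name: seq.upper() for name, seq in records}
    _check_aligned(list(seqs.values()))
    _, states = column_classify(list(seqs.values()))
    var_pos = [i for i, st in enumerate(states) if st != "invariant"]
    ref = seqs[reference_id]
    data = {}
    for pos0 in var_pos:
        col = []
        for name in ids:
            c = seqs[name][pos0]
            col.append("." if c == ref[pos0] else c)
        data[pos0 + 1] = col
    return pd.DataFrame(data, index=ids)
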