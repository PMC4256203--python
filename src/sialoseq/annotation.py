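"""ORF extraction and keyword-vocabulary functional classification.

Transcripts are binned into five functional classes — Secreted,
Housekeeping, Transposable element, Viral, Unknown — by scanning their hit
descriptions against an ordered keyword vocabulary (first match wins).  Two
pieces of external evidence enter as pre-supplied flags rather than being
computed here: the presence of a signal peptide in the translated ORF
(decides Secreted when no keyword matches) and transposable-element evidence
(a significant profile hit against a repeat database; required before a TE
keyword is allowed to fire, mirroring an e-value <= 1e-15 call).
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import FUNCTIONAL_CLASSES, CdsRecord

STOP_CODONS = ("TAA", "TAG", "TGA")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class VocabularyEntry:
    keyword: str  # lower-case; matched as case-insensitive substring
    class_label: str
    subfamily: str | None = None

    def __post_init__(self):
        if not self.keyword:
            raise ValueError("empty vocabulary keyword")
        if self.class_label not in FUNCTIONAL_CLASSES:
            raise ValueError(f"unknown class label {self.class_label!r}")


class Vocabulary:
    """An ordered keyword list; earlier entries take precedence."""

    def __init__(self, entries: Iterable[VocabularyEntry]):
        self.entries = list(entries)

    @classmethod
    def from_tsv(cls, path) -> "Vocabulary":
        df = pd.read_csv(path, sep="\t")
        entries = [
            VocabularyEntry(
                keyword=str(row.keyword).lower(),
                class_label=row.class_label,
                subfamily=None if pd.isna(row.subfamily) or not row.subfamily else row.subfamily,
            )
            for row in df.itertuples()
        ]
        return cls(entries)

    @classmethod
    def default(cls) -> "Vocabulary":
        ref = importlib.resources.files("sialoseq.data") / "vocabulary.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path)

    def __len__(self) -> int:
        return len(self.entries)


_DEFAULT_VOCABULARY: Vocabulary | None = None


def default_vocabulary() -> Vocabulary:
    global _DEFAULT_VOCABULARY
    if _DEFAULT_VOCABULARY is None:
        _DEFAULT_VOCABULARY = Vocabulary.default()
    return _DEFAULT_VOCABULARY


# ---------------------------------------------------------------------------
# ORF finding

@dataclass(frozen=True)
class Orf:
    """An open reading frame ATG..stop.

    ``start``/``end`` are 1-based inclusive positions on the *input* strand;
    for ``strand == '-'`` the ORF reads from ``end`` down to ``start`` on the
    reverse complement.  ``frame`` is 1..3 on the strand the ORF lies on.
    """

    start: int
    end: int
    frame: int
    strand: str  # '+' or '-'

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


_ORF_RE = re.compile(r"ATG(?:(?!TAA|TAG|TGA)[ACGTN]{3})*(?:TAA|TAG|TGA)")


def find_orfs(sequence: str) -> list[Orf]:
    """All ATG..stop ORFs in the six reading frames, longest first.

    ORFs are maximal per start: for nested starts sharing a stop, every ATG
    opens its own ORF.  Ties in length break deterministically by
    (start, strand).
    """
    seq = sequence.upper()
    n = len(seq)
    orfs: list[Orf] = []
    for strand, s in (("+", seq), ("-", _revcomp(seq))):
        for frame0 in range(3):
            codons = [s[i : i + 3] for i in range(frame0, n - 2, 3)]
            start_idx = None
            open_starts: list[int] = []
            for ci, codon in enumerate(codons):
                if codon == "ATG":
                    open_starts.append(ci)
                elif codon in STOP_CODONS and open_starts:
                    for sc in open_starts:
                        a = frame0 + 3 * sc  # 0-based on strand s
                        b = frame0 + 3 * ci + 2
                        if strand == "+":
                            orfs.append(Orf(a + 1, b + 1, frame0 + 1, "+"))
                        else:
                            # map back to input-strand coordinates
                            orfs.append(Orf(n - b, n - a, frame0 + 1, "-"))
                    open_starts = []
    orfs.sort(key=lambda o: (-o.length_nt, o.start, o.strand))
    return orfs


# ---------------------------------------------------------------------------
# Classification

def classify_cds(
    description: str,
    has_signal_peptide: bool,
    vocabulary: Vocabulary | None = None,
    te_evidence: bool = False,
) -> tuple[str, str | None]:
    """Assign a functional class (and optional subfamily) from a description.

    The first vocabulary keyword found as a case-insensitive substring of the
    description decides; Transposable-element keywords only fire when
    ``te_evidence`` is set.  With no keyword hit, a signal peptide implies
    Secreted (unknown subfamily), otherwise Unknown.
    """
    vocab = vocabulary or default_vocabulary()
    text = (description or "").lower()
    if text:
        for entry in vocab.entries:
            if entry.keyword in text:
                if entry.class_label == "Transposable element" and not te_evidence:
                    continue
                return entry.class_label, entry.subfamily
    if has_signal_peptide:
        return "Secreted", None
    return "Unknown", None


def classify_cds_set(
    cds_set: Mapping[str, CdsRecord], vocabulary: Vocabulary | None = None
) -> dict[str, CdsRecord]:
    """Classify every CDS in place (fills class_label/subfamily); returns the map."""
    for cds in cds_set.values():
        cds.class_label, cds.subfamily = classify_cds(
            cds.description, cds.has_signal_peptide, vocabulary, cds.te_evidence
        )
    return cds_set


# ---------------------------------------------------------------------------
# Class-level metrics

def class_metrics_from_totals(per_class: pd.DataFrame) -> pd.DataFrame:
    """Derive the class-metrics table from per-class CDS and read totals.

    ``per_class`` needs columns class_label, n_cds, n_reads.  Adds
    reads_per_cds (integer-rounded), pct_total_cds and pct_total_reads
    (2 decimals), plus a Total row.
    """
    df = per_class.copy()
    total_cds = int(df["n_cds"].sum())
    total_reads = int(df["n_reads"].sum())
    if total_cds == 0:
        raise ValueError("no CDS to summarize")
    df["reads_per_cds"] = [
        int(round(r / n)) if n else 0 for r, n in zip(df["n_reads"], df["n_cds"])
    ]
    df["pct_total_cds"] = (100.0 * df["n_cds"] / total_cds).round(2)
    df["pct_total_reads"] = (
        (100.0 * df["n_reads"] / total_reads).round(2) if total_reads else 0.0
    )
    total = pd.DataFrame(
        [
            {
                "class_label": "Total",
                "n_cds": total_cds,
                "n_reads": total_reads,
                "reads_per_cds": "",
                "pct_total_cds": round(100.0 * (total_cds > 0), 2),
                "pct_total_reads": round(100.0 * (total_reads > 0), 2),
            }
        ]
    )
    return pd.concat([df, total], ignore_index=True)


def class_metrics(
    cds_set: Mapping[str, CdsRecord], counts: Mapping[str, int]
) -> pd.DataFrame:
    """Per-class CDS and mapped-read totals with derived percentages.

    ``counts`` maps cds_id to reads summed over all libraries.  Classes with
    no members appear with zeros so the table shape is stable.
    """
    rows = []
    for label in FUNCTIONAL_CLASSES:
        members = [c for c in cds_set.values() if c.class_label == label]
        n_reads = sum(int(counts.get(c.id, 0)) for c in members)
        rows.append(
            {"class_label": label, "n_cds": len(members), "n_reads": n_reads}
        )
    return class_metrics_from_totals(pd.DataFrame(rows))
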