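"""Readers and writers for the pipeline's on-disk formats.

Handles FASTA (plain and aligned), FASTQ (Phred+33), the SNP subset of VCF,
and the TSV annotation table.  All on-disk coordinates are 1-based inclusive
(VCF convention); internal arithmetic is 0-based half-open.  The conversion
between the two lives only in this module, via :func:`to_zero_based` and
:func:`to_one_based`.

CDS records are sense-strand by construction (they are coding sequences), so
no reverse-complement handling is applied when mapping VCF positions onto
them.  Sequencing reads, in contrast, may come from either strand; strand
handling for reads lives in :mod:`sialoseq.read_processing`.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

CDS_ALPHABET = frozenset("ACGTN")
GAP = "-"

#: the five functional classes used throughout the pipeline
FUNCTIONAL_CLASSES = (
    "Secreted",
    "Housekeeping",
    "Transposable element",
    "Viral",
    "Unknown",
)


class FormatError(ValueError):
    """A malformed input file; the message names the offending line."""


def to_zero_based(pos_1based: int) -> int:
    """Convert a 1-based inclusive position to a 0-based index."""
    return pos_1based - 1


def to_one_based(index: int) -> int:
    """Convert a 0-based index to a 1-based inclusive position."""
    return index + 1


@dataclass
class CdsRecord:
    """One coding sequence: a complete ORF from start to stop codon.

    The signal-peptide flag is an input (produced upstream by a dedicated
    predictor), never computed here.
    """

    id: str
    sequence: str
    description: str = ""
    class_label: str | None = None
    subfamily: str | None = None
    has_signal_peptide: bool = False
    te_evidence: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 3:
            raise ValueError(f"CDS {self.id!r}: length {len(self.sequence)} < 3")
        bad = set(self.sequence) - CDS_ALPHABET
        if bad:
            raise ValueError(
                f"CDS {self.id!r}: invalid characters {sorted(bad)!r}"
            )

    @property
    def length_nt(self) -> int:
        return len(self.sequence)


@dataclass
class ReadRecord:
    """A sequencing read with per-base Phred quality scores (0-60)."""

    id: str
    sequence: str
    qualities: np.ndarray  # integer Phred scores, same length as sequence

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: {len(self.sequence)} bases but "
                f"{len(self.qualities)} quality scores"
            )


@dataclass
class SnpCall:
    """A single-nucleotide variant located on a CDS (1-based position)."""

    cds_id: str
    pos_1based: int
    ref: str
    alt: str
    depth: int
    quality: float
    effect: str = "unset"  # synonymous | nonsynonymous | unset

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(
                f"SNP {self.cds_id}:{self.pos_1based}: ref == alt ({self.ref})"
            )


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, aligned: bool = False) -> list[tuple[str, str]]:
    """Read a FASTA file into a list of ``(id, sequence)`` tuples.

    Sequences are upper-cased; input order is preserved; ids must be unique.
    With ``aligned=True`` the gap character ``-`` is permitted (for the
    haplotype module's aligned FASTA input).

    Raises :class:`FormatError` naming the line number for malformed headers,
    empty sequences, or duplicate ids.
    """
    records: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    allowed = CDS_ALPHABET | ({GAP} if aligned else set())
    # ambiguity codes are tolerated on read; downstream modules decide
    allowed = allowed | set("RYSWKMBDHV")
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def _flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"line {header_line}: record {header!r} has an empty sequence")
        if header in seen:
            raise FormatError(
                f"line {header_line}: duplicate id {header!r} "
                f"(first seen at line {seen[header]})"
            )
        seen[header] = header_line
        records.append((header, seq))
        header, chunks = None, []

    with _open_text(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(line_no)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"line {line_no}: empty FASTA header")
                header = name
                header_line = line_no
            else:
                if header is None:
                    raise FormatError(
                        f"line {line_no}: sequence data before any '>' header"
                    )
                seq = line.upper()
                bad = set(seq) - allowed
                if bad:
                    raise FormatError(
                        f"line {line_no}: invalid characters {sorted(bad)!r}"
                    )
                chunks.append(seq)
        _flush(line_no if records or header else 0)
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    """Write ``(id, sequence)`` tuples as FASTA, wrapping at ``width``."""
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignment(path) -> list[tuple[str, str]]:
    """Read an aligned FASTA (gaps permitted) as ``(id, sequence)`` tuples."""
    return read_fasta(path, aligned=True)


def read_cds_fasta(path, annotations: pd.DataFrame | None = None) -> dict[str, CdsRecord]:
    """Read a CDS FASTA into an ordered ``{id: CdsRecord}`` map.

    ``annotations`` is the optional TSV table from :func:`read_annotation_tsv`
    supplying descriptions, signal-peptide and TE-evidence flags.
    """
    ann = {}
    if annotations is not None:
        ann = annotations.set_index("cds_id").to_dict("index")
    out: dict[str, CdsRecord] = {}
    for name, seq in read_fasta(path):
        meta = ann.get(name, {})
        out[name] = CdsRecord(
            id=name,
            sequence=seq,
            description=str(meta.get("description", "") or ""),
            has_signal_peptide=bool(meta.get("has_signal_peptide", False)),
            te_evidence=bool(meta.get("te_evidence", False)),
            class_label=meta.get("class_label") or None,
        )
    return out


# ---------------------------------------------------------------------------
# FASTQ (Phred+33)

def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream a Phred+33 FASTQ file as :class:`ReadRecord` objects.

    Truncated records and sequence/quality length mismatches raise
    :class:`FormatError`.
    """
    with _open_text(path) as fh:
        try:
            for name, seq, qual in FastqGeneralIterator(fh):
                quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
                yield ReadRecord(id=name.split()[0], sequence=seq.upper(), qualities=quals)
        except ValueError as exc:  # Biopython's parse errors
            raise FormatError(str(exc)) from exc


def write_fastq(path, records: Iterable[ReadRecord]) -> None:
    """Write reads as Phred+33 FASTQ."""
    with _open_text(path, "wt") as fh:
        for rec in records:
            qual = (rec.qualities + 33).astype(np.uint8).tobytes().decode("ascii")
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# VCF (SNP subset)

def read_vcf_snps(path, cds_set: dict[str, CdsRecord]) -> list[SnpCall]:
    """Read the SNP lines of a VCF whose CHROM values are CDS ids.

    Non-SNP lines (indels, multi-base alleles) are skipped; the skipped count
    is logged.  Multi-allelic ALTs are expanded to one :class:`SnpCall` per
    alternate base.  Depth is taken from INFO/DP, quality from QUAL.

    Raises ``KeyError`` listing CHROM values absent from ``cds_set`` and
    ``ValueError`` when REF does not match the CDS base at POS.
    """
    from cyvcf2 import VCF

    calls: list[SnpCall] = []
    skipped = 0
    missing: set[str] = set()
    vcf = VCF(str(path))
    try:
        for var in vcf:
            chrom = var.CHROM
            cds = cds_set.get(chrom)
            if cds is None:
                missing.add(chrom)
                continue
            ref = var.REF.upper()
            pos = var.POS
            snp_alts = [a.upper() for a in var.ALT]
            # any indel or multi-base allele disqualifies the whole line
            if len(ref) != 1 or not snp_alts or any(
                len(a) != 1 or a not in "ACGT" for a in snp_alts
            ):
                skipped += 1
                continue
            if pos < 1 or pos > cds.length_nt:
                raise ValueError(
                    f"{chrom}:{pos}: position outside CDS of length {cds.length_nt}"
                )
            cds_base = cds.sequence[to_zero_based(pos)]
            if cds_base != ref:
                raise ValueError(
                    f"{chrom}:{pos}: VCF REF {ref} does not match CDS base {cds_base}"
                )
            depth = var.INFO.get("DP", 0) or 0
            qual = float(var.QUAL) if var.QUAL is not None else 0.0
            for alt in snp_alts:
                calls.append(
                    SnpCall(
                        cds_id=chrom,
                        pos_1based=pos,
                        ref=ref,
                        alt=alt,
                        depth=int(depth),
                        quality=qual,
                    )
                )
    finally:
        vcf.close()
    if missing:
        raise KeyError(
            "VCF CHROM values not present in the CDS set: "
            + ", ".join(sorted(missing))
        )
    if skipped:
        logger.info("read_vcf_snps: skipped %d non-SNP lines", skipped)
    return calls


def write_vcf(path, snps: Sequence[SnpCall], cds_set: dict[str, CdsRecord]) -> None:
    """Write SNP calls as a minimal VCF 4.2 file (CHROM/POS/REF/ALT/QUAL, INFO DP)."""
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">\n')
        for cds in cds_set.values():
            fh.write(f"##contig=<ID={cds.id},length={cds.length_nt}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for snp in snps:
            fh.write(
                f"{snp.cds_id}\t{snp.pos_1based}\t.\t{snp.ref}\t{snp.alt}\t"
                f"{snp.quality:g}\t.\tDP={snp.depth}\n"
            )


# ---------------------------------------------------------------------------
# TSV tables

def read_annotation_tsv(path) -> pd.DataFrame:
    """Read the annotation table: cds_id, description, has_signal_peptide
    (optional columns: te_evidence, class_label, subfamily)."""
    df = pd.read_csv(path, sep="\t", dtype={"cds_id": str})
    required = {"cds_id", "description", "has_signal_peptide"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"annotation table missing columns: {sorted(missing)}")
    df["description"] = df["description"].fillna("")
    df["has_signal_peptide"] = df["has_signal_peptide"].astype(bool)
    if "te_evidence" in df.columns:
        df["te_evidence"] = df["te_evidence"].astype(bool)
    return df


def write_annotation_tsv(path, cds_set: dict[str, CdsRecord]) -> None:
    rows = [
        {
            "cds_id": c.id,
            "description": c.description,
            "has_signal_peptide": c.has_signal_peptide,
            "te_evidence": c.te_evidence,
            "class_label": c.class_label or "",
        }
        for c in cds_set.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> tuple[dict[str, int], dict[str, int]]:
    """Read a per-library counts TSV written by the ``count`` command.

    Returns ``(counts, tallies)`` where tallies holds the summary fields
    (reads_in, reads_rejected_qc, reads_unmapped, total_mapped, ...).
    """
    counts: dict[str, int] = {}
    tallies: dict[str, int] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("cds_id\t"):
                continue
            key, value = line.split("\t")
            if key.startswith("#"):
                tallies[key[1:]] = int(value)
            else:
                counts[key] = int(value)
    return counts, tallies


def write_counts_tsv(path, library_counts) -> None:
    """Write LibraryCounts as a TSV with a trailing summary block."""
    with _open_text(path, "wt") as fh:
        fh.write("cds_id\tcount\n")
        for cds_id in sorted(library_counts.counts):
            fh.write(f"{cds_id}\t{library_counts.counts[cds_id]}\n")
        fh.write(f"#total_mapped\t{library_counts.total_mapped}\n")
        fh.write(f"#distinct_mapped\t{library_counts.distinct_mapped}\n")
        fh.write(f"#reads_in\t{library_counts.reads_in}\n")
        fh.write(f"#reads_rejected_qc\t{library_counts.reads_rejected_qc}\n")
        fh.write(f"#reads_unmapped\t{library_counts.reads_unmapped}\n")
        fh.write(f"#reads_ambiguous\t{library_counts.reads_ambiguous}\n")


def read_design_tsv(path) -> pd.DataFrame:
    """Read the library design table: library_id, stage {nymph,adult}, region."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"library_id", "stage", "region"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"design table missing columns: {sorted(missing)}")
    bad = set(df["stage"]) - {"nymph", "adult"}
    if bad:
        raise FormatError(f"design table has unknown stages: {sorted(bad)}")
    return df
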