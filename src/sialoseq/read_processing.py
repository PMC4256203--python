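"""Quality trimming and read-to-CDS counting.

Reads are end-trimmed (bases below Q10 removed from both ends), rejected if
the trimmed mean quality falls below Q20 or the remainder is shorter than
the 25-base seed, then assigned to coding sequences by exact-25-mer seeding
followed by banded extension allowing at most one gap opening.  Alignments
must reach 96% identity (matches / read length); all CDS tying at the best
alignment score are counted, up to five — a read tying across more than
five CDS is discarded rather than arbitrarily resolved, which keeps counts
independent of input order.

This is a seed-and-extend contract, not a BLAST reimplementation: at >=96%
identity over reads of a few hundred bases, a true alignment almost surely
contains an exact 25-mer, so seeding finds it.  Scoring is +1 per match,
-2 per mismatch, -3 per gap opening and -1 per additional gap base, with at
most one gap opening per alignment; reads must align fully within a CDS
(no overhangs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import CdsRecord, ReadRecord, read_fastq

DEFAULT_WORD_SIZE = 25
DEFAULT_MIN_IDENTITY = 0.96
DEFAULT_MAX_TIES = 5
DEFAULT_MAX_GAP_LEN = 3

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Trimming

def trim_ends(read: ReadRecord, end_q: int = 10) -> ReadRecord:
    """Strip bases with quality < ``end_q`` from the 5' and 3' ends."""
    good = read.qualities >= end_q
    if not good.any():
        return ReadRecord(id=read.id, sequence="", qualities=np.empty(0, dtype=np.int16))
    lo = int(np.argmax(good))
    hi = len(good) - int(np.argmax(good[::-1]))
    return ReadRecord(
        id=read.id,
        sequence=read.sequence[lo:hi],
        qualities=read.qualities[lo:hi],
    )


def trim_and_filter(
    read: ReadRecord,
    end_q: int = 10,
    mean_q: int = 20,
    min_length: int = DEFAULT_WORD_SIZE,
) -> ReadRecord | None:
    """End-trim then accept or reject a read.

    Rejection (returning ``None``) is a normal outcome, not an error: the
    read is dropped when the trimmed remainder is shorter than the seed
    length or its mean quality is below ``mean_q``.
    """
    trimmed = trim_ends(read, end_q=end_q)
    if len(trimmed.sequence) < min_length:
        return None
    if trimmed.qualities.mean() < mean_q:
        return None
    return trimmed


# ---------------------------------------------------------------------------
# Index

class CdsIndex:
    """Exact k-mer index over both strands of a CDS set.

    Maps every k-mer to ``(cds_idx, offset, strand)`` postings; ``strand``
    is +1 for the sense strand and -1 for the reverse complement.  CDS are
    held in lexicographic id order so tie-breaking is deterministic.
    """

    def __init__(self, cds_set: Iterable[CdsRecord] | Mapping[str, CdsRecord], k: int = DEFAULT_WORD_SIZE):
        if isinstance(cds_set, Mapping):
            records = list(cds_set.values())
        else:
            records = list(cds_set)
        if not records:
            raise ValueError("empty CDS set")
        records.sort(key=lambda c: c.id)
        short = [c.id for c in records if c.length_nt < k]
        if short:
            raise ValueError(f"CDS shorter than word size {k}: {short[:5]}")
        self.k = k
        self.cds_ids = [c.id for c in records]
        self.lengths = [c.length_nt for c in records]
        # strand sequences the alignments run against
        self.fwd = [c.sequence for c in records]
        self.rev = [_revcomp(c.sequence) for c in records]
        index: dict[str, list[tuple[int, int, int]]] = {}
        for idx, cds in enumerate(records):
            for strand, seq in ((1, self.fwd[idx]), (-1, self.rev[idx])):
                for off in range(cds.length_nt - k + 1):
                    index.setdefault(seq[off : off + k], []).append((idx, off, strand))
        self.index = index
        self.n_postings = sum(len(v) for v in index.values())

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.index

    def lookup(self, kmer: str) -> list[tuple[int, int, int]]:
        return self.index.get(kmer, [])


def build_index(cds_set, k: int = DEFAULT_WORD_SIZE) -> CdsIndex:
    return CdsIndex(cds_set, k=k)


# ---------------------------------------------------------------------------
# Alignment scoring

MATCH = 1
MISMATCH = -2
GAP_OPEN = -3
GAP_EXTEND = -1


def _mismatches(a: str, b: str) -> int:
    if a == b:
        return 0
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    return int((x != y).sum())


def _gap_penalty(length: int) -> int:
    return -(GAP_OPEN + GAP_EXTEND * (length - 1)) if length > 0 else 0


def score_at_diagonal(
    read: str, ref: str, diag: int, max_gap_len: int = DEFAULT_MAX_GAP_LEN
) -> tuple[float, int] | None:
    """Best (score, matches) for ``read`` against ``ref`` anchored near one
    diagonal, allowing at most one gap (in read or reference) of up to
    ``max_gap_len`` bases.  Returns ``None`` when the read cannot lie fully
    inside the reference around this diagonal."""
    L = len(read)
    M = len(ref)
    best: tuple[float, int] | None = None

    def consider(score: float, matches: int) -> None:
        nonlocal best
        if best is None or score > best[0]:
            best = (score, matches)

    # ungapped
    if 0 <= diag and diag + L <= M:
        mm = _mismatches(read, ref[diag : diag + L])
        consider(L - mm + MISMATCH * mm, L - mm)
        if mm <= 1:
            # the best gapped score is L + GAP_OPEN = L - 3, which cannot
            # beat an ungapped hit with <= 1 mismatch (score >= L - 3)
            return best

    rd = np.frombuffer(read.encode(), dtype=np.uint8)
    rf = np.frombuffer(ref.encode(), dtype=np.uint8)
    for gap in range(1, max_gap_len + 1):
        pen = GAP_OPEN + GAP_EXTEND * (gap - 1)  # negative
        for d in (diag, diag - gap):
            # deletion in read: read spans L+gap reference bases from d
            if 0 <= d and d + L + gap <= M:
                pre = rd != rf[d : d + L]
                suf = rd != rf[d + gap : d + gap + L]
                # split i: read[:i] on diagonal d, read[i:] on diagonal d+gap
                pre_cum = np.concatenate([[0], np.cumsum(pre)])
                suf_cum = np.concatenate([[0], np.cumsum(suf[::-1])])[::-1]
                mm_total = int((pre_cum[:-1] + suf_cum[1:]).min()) if L > 0 else 0
                matches = L - mm_total
                consider(matches + MISMATCH * mm_total + pen, matches)
        for d in (diag, diag + gap):
            # insertion in read: gap bases of the read are unaligned
            if L > gap and 0 <= d and d + L - gap <= M:
                seg = rf[d : d + L - gap]
                pre = rd[: L - gap] != seg
                suf = rd[gap:] != seg
                pre_cum = np.concatenate([[0], np.cumsum(pre)])
                suf_cum = np.concatenate([[0], np.cumsum(suf[::-1])])[::-1]
                mm_total = int((pre_cum[:-1] + suf_cum[1:]).min())
                matches = L - gap - mm_total
                consider(matches + MISMATCH * mm_total + pen, matches)
    return best


# ---------------------------------------------------------------------------
# Mapping

def best_hits(
    seq: str,
    index: CdsIndex,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_gaps: int = 1,
    max_gap_len: int = DEFAULT_MAX_GAP_LEN,
) -> list[str]:
    """All CDS ids achieving the maximum acceptable alignment score for a
    read, in lexicographic order (no tie cap applied).

    ``max_gaps`` only supports the contract's 0 or 1 gap openings.
    """
    if max_gaps not in (0, 1):
        raise ValueError("only 0 or 1 gap openings are supported")
    k = index.k
    L = len(seq)
    if L < k:
        return []
    offsets = list(range(0, L - k + 1, k))
    if offsets[-1] != L - k:
        offsets.append(L - k)
    candidates: set[tuple[int, int, int]] = set()
    for off in offsets:
        for cds_idx, pos, strand in index.lookup(seq[off : off + k]):
            candidates.add((cds_idx, strand, pos - off))
    if not candidates:
        return []
    gap_len = max_gap_len if max_gaps == 1 else 0
    best_by_cds: dict[int, float] = {}
    for cds_idx, strand, diag in candidates:
        ref = index.fwd[cds_idx] if strand == 1 else index.rev[cds_idx]
        result = score_at_diagonal(seq, ref, diag, max_gap_len=gap_len)
        if result is None:
            continue
        score, matches = result
        if matches / L < min_identity:
            continue
        if score > best_by_cds.get(cds_idx, -np.inf):
            best_by_cds[cds_idx] = score
    if not best_by_cds:
        return []
    top = max(best_by_cds.values())
    return sorted(index.cds_ids[i] for i, s in best_by_cds.items() if s == top)


def map_read(
    read: ReadRecord | str,
    index: CdsIndex,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_gaps: int = 1,
    max_ties: int = DEFAULT_MAX_TIES,
    max_gap_len: int = DEFAULT_MAX_GAP_LEN,
) -> list[str]:
    """CDS assignment for one trimmed read.

    Returns every CDS tying at the maximum alignment score, capped at
    ``max_ties``; a read tied across more than ``max_ties`` CDS is discarded
    (empty list), as is a read with no acceptable alignment.
    """
    seq = read.sequence if isinstance(read, ReadRecord) else read
    hits = best_hits(seq, index, min_identity=min_identity, max_gaps=max_gaps, max_gap_len=max_gap_len)
    if len(hits) > max_ties:
        return []
    return hits


# ---------------------------------------------------------------------------
# Counting

@dataclass
class LibraryCounts:
    """Per-CDS mapped-read counts for one library.

    A read tied across k <= max_ties CDS adds 1 to each tied CDS, so
    ``total_mapped`` (R, the sum over per-CDS counts) can exceed
    ``distinct_mapped`` (the number of reads that mapped anywhere).
    """

    library_id: str
    counts: dict[str, int] = field(default_factory=dict)
    reads_in: int = 0
    reads_rejected_qc: int = 0
    reads_unmapped: int = 0  # includes over-tied (ambiguous) reads
    reads_ambiguous: int = 0
    distinct_mapped: int = 0

    @property
    def total_mapped(self) -> int:
        return sum(self.counts.values())

    def check_conservation(self) -> None:
        """Every input read is exactly one of rejected / unmapped / mapped."""
        if self.reads_in != (
            self.reads_rejected_qc + self.reads_unmapped + self.distinct_mapped
        ):
            raise AssertionError("read conservation violated")


def count_library(
    fastq_path,
    index: CdsIndex,
    library_id: str | None = None,
    end_q: int = 10,
    mean_q: int = 20,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_gaps: int = 1,
    max_ties: int = DEFAULT_MAX_TIES,
    tie_mode: str = "each",
) -> LibraryCounts:
    """Trim, filter and map every read of one FASTQ library.

    ``tie_mode='each'`` adds 1 to every tied CDS (the default accrual);
    ``'fractional'`` splits the read as 1/k across the k tied CDS.
    Deterministic for fixed inputs: candidate order is fixed by cds_id sort.
    """
    if tie_mode not in ("each", "fractional"):
        raise ValueError(f"unknown tie_mode {tie_mode!r}")
    lc = LibraryCounts(library_id=library_id or str(fastq_path))
    counts: dict[str, float] = {}
    for read in read_fastq(fastq_path):
        lc.reads_in += 1
        trimmed = trim_and_filter(read, end_q=end_q, mean_q=mean_q, min_length=index.k)
        if trimmed is None:
            lc.reads_rejected_qc += 1
            continue
        hits = best_hits(trimmed.sequence, index, min_identity=min_identity, max_gaps=max_gaps)
        if not hits:
            lc.reads_unmapped += 1
            continue
        if len(hits) > max_ties:
            lc.reads_ambiguous += 1
            lc.reads_unmapped += 1
            continue
        lc.distinct_mapped += 1
        w = 1.0 / len(hits) if tie_mode == "fractional" else 1
        for h in hits:
            counts[h] = counts.get(h, 0) + w
    lc.counts = {
        k: (int(round(v)) if tie_mode == "each" else v) for k, v in sorted(counts.items())
    }
    lc.check_conservation()
    return lc
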