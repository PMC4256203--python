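import numpy as np
import pytest

from sialoseq import read_processing as rp
from sialoseq.io_formats import CdsRecord, ReadRecord, write_fastq
from sialoseq.read_processing import (
    CdsIndex,
    LibraryCounts,
    best_hits,
    build_index,
    count_library,
    map_read,
    trim_and_filter,
    trim_ends,
)

from conftest import make_read, random_cds

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(_COMPLEMENT)[::-1]


class TestTrimming:
    def test_low_quality_ends_removed(self):
        read = ReadRecord(id="r", sequence="AACGTA", qualities=np.array([5, 5, 30, 30, 30, 5]))
        trimmed = trim_ends(read, end_q=10)
        assert trimmed.sequence == "CGT"
        assert trimmed.qualities.tolist() == [30, 30, 30]

    def test_mean_quality_below_20_rejected(self):
        read = make_read("A" * 30, q=19)
        assert trim_and_filter(read) is None

    def test_trimmed_mean_recovers_read(self):
        quals = np.array([9] * 10 + [40] * 30)
        read = ReadRecord(id="r", sequence="A" * 40, qualities=quals)
        kept = trim_and_filter(read)
        assert kept is not None
        assert len(kept.sequence) == 30
        assert kept.qualities.mean() == 40

    def test_short_remainder_rejected(self):
        quals = np.array([5] * 10 + [40] * 10 + [5] * 10)
        read = ReadRecord(id="r", sequence="A" * 30, qualities=quals)
        assert trim_and_filter(read) is None  # 10 < 25-base seed

    def test_all_bases_bad(self):
        read = make_read("ACGT" * 10, q=3)
        assert trim_and_filter(read) is None


class TestIndex:
    def test_single_25mer_cds_has_two_postings(self):
        cds = CdsRecord(id="c", sequence="ATGAAACCCGGGTTTACGTACGTAA")
        assert len(cds.sequence) == 25
        index = build_index({"c": cds})
        assert index.n_postings == 2  # forward + reverse complement

    def test_duplicate_cds_index_both(self, rng):
        cds = random_cds(rng, 20, "a")
        twin = CdsRecord(id="b", sequence=cds.sequence)
        index = build_index({"a": cds, "b": twin})
        kmer = cds.sequence[:25]
        hit_ids = {index.cds_ids[i] for i, _, _ in index.lookup(kmer)}
        assert hit_ids == {"a", "b"}

    def test_membership_matches_brute_force(self, rng):
        cds_set = {f"c{i}": random_cds(rng, 30, f"c{i}") for i in range(100)}
        index = build_index(cds_set)
        haystack = [
            s for c in cds_set.values() for s in (c.sequence, revcomp(c.sequence))
        ]
        for _ in range(300):
            if rng.random() < 0.5:
                donor = list(cds_set.values())[rng.integers(len(cds_set))]
                start = rng.integers(donor.length_nt - 25 + 1)
                kmer = donor.sequence[start : start + 25]
            else:
                kmer = "".join("ACGT"[b] for b in rng.integers(4, size=25))
            brute = any(kmer in h for h in haystack)
            assert (kmer in index) == brute

    def test_too_short_cds_rejected(self):
        with pytest.raises(ValueError, match="shorter than word size"):
            build_index({"c": CdsRecord(id="c", sequence="ATGTAA")})


def oracle_best_hits(read, cds_set, min_identity=0.96, max_gap_len=3):
    """Exhaustive all-pairs banded-alignment oracle (independent of seeding).

    For every CDS and strand, scores every diagonal ungapped and every
    (diagonal, gap length, side, split) combination with <=1 gap opening,
    then returns all CDS tying at the global best acceptable score.
    """
    L = len(read)
    rd = np.frombuffer(read.encode(), dtype=np.uint8)

    def split_min_mm(pre_neq, suf_neq):
        # best total mismatches over all prefix/suffix split points
        pre = np.concatenate([[0], np.cumsum(pre_neq)])
        suf = np.concatenate([[0], np.cumsum(suf_neq[::-1])])[::-1]
        return int((pre + suf).min())

    per_cds = {}
    for cds_id, cds in cds_set.items():
        best = None
        for ref in (cds.sequence, revcomp(cds.sequence)):
            M = len(ref)
            rf = np.frombuffer(ref.encode(), dtype=np.uint8)
            for diag in range(0, M - L + 1):
                mm = int((rd != rf[diag : diag + L]).sum())
                score, matches = L - 3 * mm, L - mm
                if best is None or score > best[0]:
                    best = (score, matches)
            for gap in range(1, max_gap_len + 1):
                pen = 3 + (gap - 1)
                # deletion in read: read[:i] at diag, read[i:] at diag+gap
                for diag in range(0, M - L - gap + 1):
                    mm = split_min_mm(
                        rd != rf[diag : diag + L],
                        rd != rf[diag + gap : diag + gap + L],
                    )
                    matches = L - mm
                    score = matches - 2 * mm - pen
                    if best is None or score > best[0]:
                        best = (score, matches)
                # insertion in read: gap read bases unaligned
                if L > gap:
                    for diag in range(0, M - (L - gap) + 1):
                        seg = rf[diag : diag + L - gap]
                        mm = split_min_mm(rd[: L - gap] != seg, rd[gap:] != seg)
                        matches = L - gap - mm
                        score = matches - 2 * mm - pen
                        if best is None or score > best[0]:
                            best = (score, matches)
        if best and best[1] / L >= min_identity:
            per_cds[cds_id] = best[0]
    if not per_cds:
        return []
    top = max(per_cds.values())
    return sorted(k for k, v in per_cds.items() if v == top)


class TestMapRead:
    def test_exact_substring_maps_to_its_cds(self, small_cds_set):
        cds = small_cds_set["cds3"]
        index = build_index(small_cds_set)
        read = cds.sequence[10:60]
        assert map_read(read, index) == ["cds3"]
        assert map_read(revcomp(read), index) == ["cds3"]

    def test_below_identity_threshold_discarded(self, rng):
        cds = random_cds(rng, 40, "a")
        index = build_index({"a": cds})
        read = list(cds.sequence[:50])
        for pos in (30, 40, 48):  # 3 mismatches in 50 bases -> 94% identity
            read[pos] = next(b for b in "ACGT" if b != read[pos])
        assert map_read("".join(read), index) == []

    def test_paralogs_tie_and_both_count(self, rng):
        cds = random_cds(rng, 60, "a")
        twin = CdsRecord(id="b", sequence=cds.sequence)
        index = build_index({"a": cds, "b": twin})
        assert map_read(cds.sequence[5:105], index) == ["a", "b"]

    def test_over_five_way_tie_discards_read(self, rng):
        cds = random_cds(rng, 60, "a")
        clones = {
            f"c{i}": CdsRecord(id=f"c{i}", sequence=cds.sequence) for i in range(6)
        }
        index = build_index(clones)
        read = cds.sequence[0:80]
        assert best_hits(read, index) == [f"c{i}" for i in range(6)]
        assert map_read(read, index, max_ties=5) == []

    def test_single_gap_tolerated(self, rng):
        cds = random_cds(rng, 60, "a")
        index = build_index({"a": cds})
        # delete 2 bases from the middle of a 120-base window
        window = cds.sequence[10:130]
        read = window[:60] + window[62:]
        assert map_read(read, index) == ["a"]

    def test_raising_identity_never_adds_hits(self, rng):
        cds_set = {f"c{i}": random_cds(rng, 50, f"c{i}") for i in range(10)}
        index = build_index(cds_set)
        for _ in range(50):
            donor = list(cds_set.values())[rng.integers(10)]
            start = rng.integers(donor.length_nt - 100)
            read = list(donor.sequence[start : start + 100])
            for pos in rng.choice(100, size=rng.integers(0, 5), replace=False):
                read[pos] = "ACGT"[rng.integers(4)]
            read = "".join(read)
            loose = best_hits(read, index, min_identity=0.90)
            tight = best_hits(read, index, min_identity=0.96)
            assert set(tight) <= set(loose)

    def test_agrees_with_exhaustive_oracle(self, rng):
        """Top-score sets match an all-pairs banded-alignment oracle."""
        cds_set = {f"c{i:02d}": random_cds(rng, 45, f"c{i:02d}") for i in range(15)}
        # two exact paralogs to force ties
        src = cds_set["c00"]
        cds_set["c90"] = CdsRecord(id="c90", sequence=src.sequence)
        index = build_index(cds_set)
        n_checked = 0
        for _ in range(120):
            donor = list(cds_set.values())[rng.integers(len(cds_set))]
            start = int(rng.integers(donor.length_nt - 120 + 1))
            read = donor.sequence[start : start + 120]
            kind = rng.integers(3)
            if kind == 1:  # up to 2 substitutions
                chars = list(read)
                for pos in rng.choice(120, size=2, replace=False):
                    chars[pos] = "ACGT"[rng.integers(4)]
                read = "".join(chars)
            elif kind == 2:  # one deletion of 1-2 bases
                g = int(rng.integers(1, 3))
                cut = int(rng.integers(30, 90))
                read = read[:cut] + read[cut + g :]
            if rng.random() < 0.5:
                read = revcomp(read)
            assert best_hits(read, index) == oracle_best_hits(read, cds_set)
            n_checked += 1
        assert n_checked == 120


class TestCountLibrary:
    def test_counts_equal_truth_on_clean_simulation(self, tmp_path, rng):
        from sialoseq.synthetic_data import SimulationConfig, simulate_cds, simulate_reads

        cfg = SimulationConfig(
            n_cds=30, reads_per_library=400, error_rate=0.0, qc_fail_fraction=0.0,
            seed=7, stages=("nymph", "adult"), regions=("R1",),
        )
        cds_set, truth = simulate_cds(cfg)
        design, truth_counts = simulate_reads(cds_set, truth, cfg, tmp_path)
        index = build_index(cds_set)
        for row in design.itertuples():
            lc = count_library(row.fastq, index, row.library_id)
            expected = truth_counts[row.library_id]
            assert lc.reads_rejected_qc == 0
            for cds_id, n in expected.items():
                assert lc.counts.get(cds_id, 0) == n

    def test_empty_fastq(self, tmp_path, small_cds_set):
        p = tmp_path / "empty.fastq"
        p.write_text("")
        index = build_index(small_cds_set)
        lc = count_library(p, index, "L")
        assert lc.reads_in == 0 and lc.total_mapped == 0

    def test_read_conservation(self, tmp_path, rng, small_cds_set):
        index = build_index(small_cds_set)
        reads = []
        cds_list = list(small_cds_set.values())
        for i in range(60):
            kind = rng.integers(3)
            if kind == 0:  # mappable
                donor = cds_list[rng.integers(len(cds_list))]
                reads.append(make_read(donor.sequence[5:85], q=40, read_id=f"r{i}"))
            elif kind == 1:  # unmappable (random)
                seq = "".join("ACGT"[b] for b in rng.integers(4, size=80))
                reads.append(make_read(seq, q=40, read_id=f"r{i}"))
            else:  # low quality
                donor = cds_list[rng.integers(len(cds_list))]
                reads.append(make_read(donor.sequence[5:85], q=10, read_id=f"r{i}"))
        p = tmp_path / "mix.fastq"
        write_fastq(p, reads)
        lc = count_library(p, index, "L")
        assert lc.reads_in == 60
        lc.check_conservation()
        assert lc.reads_rejected_qc > 0 and lc.reads_unmapped > 0

    def test_fractional_tie_mode_conserves_mass(self, tmp_path, rng):
        cds = random_cds(rng, 60, "a")
        twin = CdsRecord(id="b", sequence=cds.sequence)
        index = build_index({"a": cds, "b": twin})
        reads = [make_read(cds.sequence[i : i + 80], read_id=f"r{i}") for i in range(10)]
        p = tmp_path / "ties.fastq"
        write_fastq(p, reads)
        each = count_library(p, index, "L", tie_mode="each")
        frac = count_library(p, index, "L", tie_mode="fractional")
        assert each.total_mapped == 20  # 10 reads x 2 tied CDS
        assert each.distinct_mapped == 10
        assert sum(frac.counts.values()) == pytest.approx(10.0)
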