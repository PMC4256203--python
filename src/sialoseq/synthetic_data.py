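"""Ground-truth simulator for the 10-library salivary-gland study design.

Generates a CDS population with functional classes in realistic proportions
(roughly 20% secreted, 65% housekeeping, 5% transposable element, 0.4%
viral, 10% unknown), stage-by-region structured read libraries (2
developmental stages x 5 geographic regions by default), and per-CDS SNPs
with class-dependent synonymous/non-synonymous rates, together with truth
tables that let every downstream stage be checked against what was planted.

Model choices
-------------
* CDS lengths are log-normal (median ~1.17 kb), each sequence a valid ORF:
  ATG start, single stop at the end, no in-frame internal stop.
* Per-CDS expression is a log-normal baseline; stage or region effects are
  multiplicative folds on that baseline, matching a ratio-based analysis.
* Reads are uniform substrings of their CDS on either strand with
  independent per-base substitution errors.  Qualities follow a
  two-component model: good reads draw Q35-40 with short (<10) tails at the
  ends so end-trimming has work to do, and a configurable fraction of reads
  draws Q2-12 throughout and must fail the mean-Q20 filter.
* SNP counts per CDS are the configured per-100-codon rate times the codon
  count, stochastically rounded (floor plus Bernoulli remainder); positions
  and alternate bases are chosen so the substitution provably has the
  intended effect, verified against the genetic code at generation time.
  A configurable fraction of calls is pushed below the depth-20/quality-13
  acceptance thresholds to exercise filtering.

Everything is deterministic under a fixed seed: per-stage child generators
are derived from ``(seed, stage-tag)`` so each generator's byte output does
not depend on whether the other stages ran.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation
from .io_formats import (
    CdsRecord,
    ReadRecord,
    SnpCall,
    write_annotation_tsv,
    write_fasta,
    write_fastq,
    write_vcf,
)
from .polymorphism import translate_codon

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    c
    for c in ("".join(p) for p in itertools.product(_BASES, repeat=3))
    if c not in STOP_CODONS
)

#: default class mix (fractions of the CDS population)
DEFAULT_CLASS_PROPORTIONS = {
    "Secreted": 0.20,
    "Housekeeping": 0.65,
    "Transposable element": 0.05,
    "Viral": 0.004,
    "Unknown": 0.096,
}

#: default per-class (synonymous, non-synonymous) rates per 100 codons
DEFAULT_SNP_RATES = {
    "Secreted": (0.938, 1.942),
    "Housekeeping": (0.669, 0.666),
    "Transposable element": (1.385, 2.206),
    "Viral": (1.66, 2.044),
    "Unknown": (1.223, 2.229),
}

DEFAULT_REGIONS = ("Arg", "BolCol", "BolNat", "Chile", "Peru")
DEFAULT_STAGES = ("nymph", "adult")

_DESCRIPTION_TEMPLATES = (
    "putative {} precursor",
    "salivary {}",
    "{} homolog",
    "{}-like protein",
)


@dataclass
class SimulationConfig:
    """All knobs of the simulated study, with the study-design defaults."""

    n_cds: int = 2000
    class_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    stages: tuple = DEFAULT_STAGES
    regions: tuple = DEFAULT_REGIONS
    reads_per_library: int = 50_000
    read_length: int = 300
    fold_overexpressed_fraction: float = 0.05
    fold_range: tuple = (10.0, 1000.0)  # log-uniform planted folds
    baseline_sigma: float = 1.0  # sd of log baseline expression
    length_median_nt: float = 1170.0
    length_sigma: float = 0.35  # sd of log length
    min_length_nt: int = 450
    max_length_nt: int = 9000
    error_rate: float = 0.001  # per-base substitution error
    qc_fail_fraction: float = 0.05  # reads drawn entirely low-quality
    snp_rates: dict = field(default_factory=lambda: dict(DEFAULT_SNP_RATES))
    snp_low_quality_fraction: float = 0.1  # calls below the 20/13 thresholds
    paralog_families: int = 0
    paralog_identity: float = 0.97
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cds < 1:
            raise ValueError("n_cds must be >= 1")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValueError("class proportions must be >= 0")
        for label, (s, ns) in self.snp_rates.items():
            if s < 0 or ns < 0:
                raise ValueError(f"negative SNP rate for class {label!r}")
        for frac in (
            self.fold_overexpressed_fraction,
            self.qc_fail_fraction,
            self.snp_low_quality_fraction,
        ):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.error_rate < 0 or self.error_rate > 1:
            raise ValueError("error_rate must lie in [0, 1]")
        if self.min_length_nt < 6:
            raise ValueError("min_length_nt must cover at least start + stop")

    @property
    def n_libraries(self) -> int:
        return len(self.stages) * len(self.regions)

    def library_design(self) -> pd.DataFrame:
        suffix = {"nymph": "N", "adult": "A"}
        rows = [
            {
                "library_id": f"{region}-{suffix.get(stage, stage[:1].upper())}",
                "stage": stage,
                "region": region,
            }
            for region in self.regions
            for stage in self.stages
        ]
        return pd.DataFrame(rows)

    def _rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), tag])


def load_config(path) -> SimulationConfig:
    """Read a SimulationConfig from a YAML key: value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("stages", "regions", "fold_range"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    if "snp_rates" in raw:
        raw["snp_rates"] = {k: tuple(v) for k, v in raw["snp_rates"].items()}
    return SimulationConfig(**raw)


def save_config(config: SimulationConfig, path) -> None:
    raw = dataclasses.asdict(config)
    raw["stages"] = list(config.stages)
    raw["regions"] = list(config.regions)
    raw["fold_range"] = list(config.fold_range)
    raw["snp_rates"] = {k: list(v) for k, v in config.snp_rates.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# CDS simulation

def _class_counts(proportions: dict, n: int) -> dict[str, int]:
    """Largest-remainder apportionment so counts hit the proportions exactly."""
    items = list(proportions.items())
    raw = [p * n for _, p in items]
    counts = [int(np.floor(x)) for x in raw]
    short = n - sum(counts)
    order = np.argsort([c - x for x, c in zip(raw, counts)])  # most negative first
    for i in order[:short]:
        counts[i] += 1
    return {label: c for (label, _), c in zip(items, counts)}


def _draw_description(rng, label: str, vocab) -> str:
    entries = [e for e in vocab.entries if e.class_label == label]
    entry = entries[rng.integers(len(entries))]
    template = _DESCRIPTION_TEMPLATES[rng.integers(len(_DESCRIPTION_TEMPLATES))]
    return template.format(entry.keyword)


def simulate_cds(config: SimulationConfig):
    """Generate the CDS population and its truth table.

    Returns ``(cds_set, truth)``: an ordered ``{id: CdsRecord}`` map and a
    DataFrame with the planted class, expression design (baseline weight,
    stage/region effect and fold) for every CDS.
    """
    rng = config._rng(1)
    vocab = annotation.default_vocabulary()
    counts = _class_counts(config.class_proportions, config.n_cds)
    labels = [l for l, c in counts.items() for _ in range(c)]
    rng.shuffle(labels)

    # lengths in codons (incl. start and stop), log-normal in nt
    lengths_nt = rng.lognormal(
        mean=np.log(config.length_median_nt), sigma=config.length_sigma, size=config.n_cds
    )
    lengths_nt = np.clip(lengths_nt, config.min_length_nt, config.max_length_nt)
    n_codons = np.maximum((lengths_nt / 3).round().astype(int), 4)

    # expression design
    baseline = rng.lognormal(mean=0.0, sigma=config.baseline_sigma, size=config.n_cds)
    n_eff = int(round(config.fold_overexpressed_fraction * config.n_cds))
    eff_idx = rng.choice(config.n_cds, size=n_eff, replace=False) if n_eff else np.array([], dtype=int)
    conditions = [("stage", s) for s in config.stages] + [
        ("region", r) for r in config.regions
    ]
    lo, hi = config.fold_range
    folds = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_eff))

    effect_type = np.array(["none"] * config.n_cds, dtype=object)
    effect_value = np.array([""] * config.n_cds, dtype=object)
    fold_col = np.ones(config.n_cds)
    for j, idx in enumerate(eff_idx):
        kind, value = conditions[rng.integers(len(conditions))]
        effect_type[idx] = kind
        effect_value[idx] = value
        fold_col[idx] = folds[j]

    cds_set: dict[str, CdsRecord] = {}
    rows = []
    width = len(str(config.n_cds))
    codon_arr = np.array(SENSE_CODONS)
    stop_arr = np.array(STOP_CODONS)
    for i in range(config.n_cds):
        label = labels[i]
        nc = int(n_codons[i])
        body = codon_arr[rng.integers(len(codon_arr), size=nc - 2)]
        seq = "ATG" + "".join(body) + str(stop_arr[rng.integers(3)])
        has_sp = label == "Secreted"
        te = label == "Transposable element"
        if label == "Unknown":
            desc = ""
        elif label == "Secreted" and rng.random() < 0.2:
            desc = ""  # exercises the signal-peptide fallback
        else:
            desc = _draw_description(rng, label, vocab)
        cds_id = f"cds{i + 1:0{width}d}"
        cds_set[cds_id] = CdsRecord(
            id=cds_id,
            sequence=seq,
            description=desc,
            class_label=None,
            has_signal_peptide=has_sp,
            te_evidence=te,
        )
        rows.append(
            {
                "cds_id": cds_id,
                "class_label": label,
                "length_nt": 3 * nc,
                "n_codons": nc,
                "baseline": baseline[i],
                "effect_type": effect_type[i],
                "effect_value": effect_value[i],
                "fold": fold_col[i],
                "paralog_of": "",
            }
        )

    if config.paralog_families:
        _add_paralogs(config, rng, cds_set, rows)
    truth = pd.DataFrame(rows)
    return cds_set, truth


def _add_paralogs(config, rng, cds_set, rows) -> None:
    """Duplicate CDS at ~paralog_identity to exercise the tied-match rule."""
    base_rows = [r for r in rows if r["effect_type"] == "none"]
    picks = rng.choice(len(base_rows), size=min(config.paralog_families, len(base_rows)), replace=False)
    for p in picks:
        src = base_rows[int(p)]
        parent = cds_set[src["cds_id"]]
        seq = list(parent.sequence)
        # mutate interior bases only, keeping start/stop intact
        n_mut = int(round((1 - config.paralog_identity) * len(seq)))
        sites = rng.choice(np.arange(3, len(seq) - 3), size=n_mut, replace=False)
        for s in sites:
            choices = [b for b in _BASES if b != seq[s]]
            seq[s] = choices[rng.integers(3)]
        pid = src["cds_id"] + "p"
        cds_set[pid] = CdsRecord(
            id=pid,
            sequence="".join(seq),
            description=parent.description,
            has_signal_peptide=parent.has_signal_peptide,
            te_evidence=parent.te_evidence,
        )
        row = dict(src)
        row.update(cds_id=pid, paralog_of=src["cds_id"])
        rows.append(row)


# ---------------------------------------------------------------------------
# Read simulation

def _library_weights(truth: pd.DataFrame, stage: str, region: str) -> np.ndarray:
    """Expected read share per CDS: baseline x length x any matching effect."""
    w = truth["baseline"].to_numpy() * truth["length_nt"].to_numpy().astype(float)
    effect = np.ones(len(truth))
    is_stage = (truth["effect_type"] == "stage") & (truth["effect_value"] == stage)
    is_region = (truth["effect_type"] == "region") & (truth["effect_value"] == region)
    effect[is_stage | is_region] = truth.loc[is_stage | is_region, "fold"]
    return w * effect


def simulate_reads(
    cds_set: dict[str, CdsRecord],
    truth: pd.DataFrame,
    config: SimulationConfig,
    out_dir,
):
    """Write one FASTQ per library; return ``(design, truth_counts)``.

    ``design`` lists library_id, stage, region and the FASTQ path;
    ``truth_counts`` is the CDS x library matrix of reads actually drawn.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    L = config.read_length
    min_len = min(c.length_nt for c in cds_set.values())
    if L > min_len:
        raise ValueError(
            f"read_length {L} exceeds the shortest CDS ({min_len} nt)"
        )
    rng = config._rng(2)
    design = config.library_design()
    seqs = [cds_set[c].sequence for c in truth["cds_id"]]
    lengths = np.array([len(s) for s in seqs])
    truth_counts = pd.DataFrame(
        0, index=pd.Index(truth["cds_id"], name="cds_id"), columns=design["library_id"]
    )
    paths = []
    for row in design.itertuples():
        w = _library_weights(truth, row.stage, row.region)
        p = w / w.sum()
        counts = rng.multinomial(config.reads_per_library, p)
        truth_counts[row.library_id] = counts
        path = out_dir / f"{row.library_id}.fastq"
        _write_library_fastq(rng, row.library_id, seqs, lengths, counts, config, path)
        paths.append(str(path))
    design = design.assign(fastq=paths)
    return design, truth_counts


def _write_library_fastq(rng, lib_id, seqs, lengths, counts, config, path) -> None:
    L = config.read_length
    n = int(counts.sum())
    cds_of = np.repeat(np.arange(len(seqs)), counts)
    pos = (rng.random(n) * (lengths[cds_of] - L + 1)).astype(int)
    strand = rng.random(n) < 0.5
    n_err = (
        rng.binomial(L, config.error_rate, size=n)
        if config.error_rate > 0
        else np.zeros(n, dtype=int)
    )
    qc_fail = rng.random(n) < config.qc_fail_fraction

    # two-component quality model, built in one block per library
    Q = rng.integers(35, 41, size=(n, L), dtype=np.int8)
    low = rng.integers(2, 10, size=(n, L), dtype=np.int8)
    t5 = rng.integers(0, 7, size=n)
    t3 = rng.integers(0, 7, size=n)
    cols = np.arange(L)
    tail_mask = (cols[None, :] < t5[:, None]) | (cols[None, :] >= (L - t3)[:, None])
    Q = np.where(tail_mask, low, Q)
    bad = rng.integers(2, 13, size=(n, L), dtype=np.int8)
    Q[qc_fail] = bad[qc_fail]
    Q33 = (Q + 33).astype(np.uint8)

    with open(path, "wb") as fh:
        for i in range(n):
            s = seqs[cds_of[i]][pos[i] : pos[i] + L]
            if n_err[i]:
                chars = list(s)
                for e in rng.integers(0, L, size=n_err[i]):
                    cur = chars[e]
                    alt = _BASES[rng.integers(4)]
                    while alt == cur:
                        alt = _BASES[rng.integers(4)]
                    chars[e] = alt
                s = "".join(chars)
            if strand[i]:
                s = s.translate(_COMPLEMENT)[::-1]
            fh.write(b"@" + f"{lib_id}:{i:07d}".encode() + b"\n")
            fh.write(s.encode() + b"\n+\n")
            fh.write(Q33[i].tobytes() + b"\n")


# ---------------------------------------------------------------------------
# SNP simulation

def _codon_options():
    """For every codon: single-base changes that are provably synonymous or
    non-synonymous, verified against the genetic code at import time."""
    syn: dict[str, list[tuple[int, str]]] = {}
    nonsyn: dict[str, list[tuple[int, str]]] = {}
    for codon in ("".join(p) for p in itertools.product(_BASES, repeat=3)):
        aa = translate_codon(codon)
        for off in range(3):
            for alt in _BASES:
                if alt == codon[off]:
                    continue
                alt_codon = codon[:off] + alt + codon[off + 1 :]
                target = syn if translate_codon(alt_codon) == aa else nonsyn
                target.setdefault(codon, []).append((off, alt))
    return syn, nonsyn


_SYN_OPTIONS, _NONSYN_OPTIONS = _codon_options()


def _stochastic_round(rng, x: float) -> int:
    base = int(np.floor(x))
    return base + int(rng.random() < (x - base))


def simulate_snps(
    cds_set: dict[str, CdsRecord],
    truth: pd.DataFrame,
    config: SimulationConfig,
    out_path,
) -> pd.DataFrame:
    """Plant class-dependent S/NS SNPs; write a VCF; return the truth table.

    Counts per CDS are rate x n_codons / 100, stochastically rounded.  At
    most one SNP is planted per codon.  A ``snp_low_quality_fraction`` of
    calls draws depth or quality below the 20/13 acceptance thresholds
    (``passes_filter`` False in the truth table).
    """
    rng = config._rng(3)
    class_of = dict(zip(truth["cds_id"], truth["class_label"]))
    records = []
    calls: list[SnpCall] = []
    for cds_id, cds in cds_set.items():
        label = class_of[cds_id]
        if label not in config.snp_rates:
            raise ValueError(f"no SNP rates configured for class {label!r}")
        s_rate, ns_rate = config.snp_rates[label]
        codons = [cds.sequence[i : i + 3] for i in range(0, cds.length_nt, 3)]
        nc = len(codons)
        n_s = _stochastic_round(rng, s_rate * nc / 100.0)
        n_ns = _stochastic_round(rng, ns_rate * nc / 100.0)
        syn_capable = [i for i, c in enumerate(codons) if c in _SYN_OPTIONS]
        nonsyn_capable = [i for i, c in enumerate(codons) if c in _NONSYN_OPTIONS]
        n_s = min(n_s, len(syn_capable))
        chosen_s = rng.choice(syn_capable, size=n_s, replace=False) if n_s else []
        used = set(int(i) for i in chosen_s)
        nonsyn_free = [i for i in nonsyn_capable if i not in used]
        n_ns = min(n_ns, len(nonsyn_free))
        chosen_ns = rng.choice(nonsyn_free, size=n_ns, replace=False) if n_ns else []
        for codon_idx, effect, options in (
            *((int(i), "synonymous", _SYN_OPTIONS) for i in chosen_s),
            *((int(i), "nonsynonymous", _NONSYN_OPTIONS) for i in chosen_ns),
        ):
            codon = codons[codon_idx]
            opts = options[codon]
            off, alt = opts[rng.integers(len(opts))]
            pos = 3 * codon_idx + off + 1
            fails = rng.random() < config.snp_low_quality_fraction
            if fails:
                if rng.random() < 0.5:
                    depth, qual = int(rng.integers(1, 20)), float(rng.uniform(13, 60))
                else:
                    # stay strictly below the inclusive quality-13 boundary
                    depth, qual = int(rng.integers(20, 200)), float(rng.uniform(0, 12.9))
            else:
                depth, qual = int(rng.integers(20, 200)), float(rng.uniform(13, 60))
            qual = round(qual, 1)
            calls.append(
                SnpCall(
                    cds_id=cds_id,
                    pos_1based=pos,
                    ref=codon[off],
                    alt=alt,
                    depth=depth,
                    quality=qual,
                )
            )
            records.append(
                {
                    "cds_id": cds_id,
                    "pos_1based": pos,
                    "ref": codon[off],
                    "alt": alt,
                    "effect": effect,
                    "depth": depth,
                    "quality": qual,
                    "passes_filter": not fails,
                }
            )
    calls.sort(key=lambda c: (c.cds_id, c.pos_1based))
    write_vcf(out_path, calls, cds_set)
    df = pd.DataFrame(records)
    if not df.empty:
        df = df.sort_values(["cds_id", "pos_1based"], ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# One-call convenience

def simulate_study(config: SimulationConfig, out_dir):
    """Run all three generators into ``out_dir``.

    Writes cds.fasta, annotation.tsv, design.tsv, one FASTQ per library,
    snps.vcf, truth_cds.tsv, truth_counts.tsv and truth_snps.tsv.  Returns
    ``(cds_set, truth, design, truth_counts, truth_snps)``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cds_set, truth = simulate_cds(config)
    write_fasta(out_dir / "cds.fasta", [(c.id, c.sequence) for c in cds_set.values()])
    write_annotation_tsv(out_dir / "annotation.tsv", cds_set)
    design, truth_counts = simulate_reads(cds_set, truth, config, out_dir)
    truth_snps = simulate_snps(cds_set, truth, config, out_dir / "snps.vcf")
    truth.to_csv(out_dir / "truth_cds.tsv", sep="\t", index=False)
    truth_counts.to_csv(out_dir / "truth_counts.tsv", sep="\t")
    truth_snps.to_csv(out_dir / "truth_snps.tsv", sep="\t", index=False)
    design.to_csv(out_dir / "design.tsv", sep="\t", index=False)
    return cds_set, truth, design, truth_counts, truth_snps
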