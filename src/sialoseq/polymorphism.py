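"""SNP filtering, synonymous/non-synonymous classification and rate tables.

Variants are accepted when coverage depth is at least 20 and call quality at
least 13 (both boundaries inclusive).  Each accepted SNP is classified
against the standard genetic code (translation table 1, appropriate for
insect nuclear genes) by substituting the alternate base into the reference
codon: the change is synonymous when both codons translate to the same
amino acid, non-synonymous otherwise; any change into or out of a stop
codon that alters the product is non-synonymous.  Multiple SNPs within one
codon are classified independently against the reference codon — the same
per-SNP convention used by per-site callers — not haplotype-aware.

Rates are expressed per 100 codons.  Codons containing N are excluded from
both the codon denominator and the classified counts (SNPs in such codons
are left "unset").  Class-level NS/S is the ratio of class mean rates
(mean NS rate / mean S rate over member CDS), not the mean of per-CDS
ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io_formats import CdsRecord, SnpCall, to_zero_based

DEFAULT_MIN_DEPTH = 20
DEFAULT_MIN_QUAL = 13.0

_TABLE = CodonTable.unambiguous_dna_by_id[1]


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon, '*' for stop (standard code)."""
    codon = codon.upper()
    if codon in _TABLE.stop_codons:
        return "*"
    return _TABLE.forward_table[codon]


def filter_snps(
    calls: Iterable[SnpCall],
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_qual: float = DEFAULT_MIN_QUAL,
) -> list[SnpCall]:
    """Keep SNPs with depth >= min_depth and quality >= min_qual (inclusive)."""
    return [c for c in calls if c.depth >= min_depth and c.quality >= min_qual]


def classify_effect(snp: SnpCall, cds: CdsRecord) -> str:
    """'synonymous' / 'nonsynonymous' against the reference codon; 'unset'
    when the codon contains N.  The classification is stored on the call."""
    if cds.length_nt % 3 != 0:
        raise ValueError(
            f"CDS {cds.id!r}: length {cds.length_nt} not divisible by 3"
        )
    pos0 = to_zero_based(snp.pos_1based)
    if not 0 <= pos0 < cds.length_nt:
        raise ValueError(
            f"SNP {snp.cds_id}:{snp.pos_1based} beyond CDS length {cds.length_nt}"
        )
    codon_idx = pos0 // 3
    offset = pos0 % 3
    codon = cds.sequence[3 * codon_idx : 3 * codon_idx + 3]
    if "N" in codon:
        snp.effect = "unset"
        return snp.effect
    if codon[offset] != snp.ref:
        raise ValueError(
            f"SNP {snp.cds_id}:{snp.pos_1based}: ref {snp.ref} does not match "
            f"CDS base {codon[offset]}"
        )
    alt_codon = codon[:offset] + snp.alt + codon[offset + 1 :]
    snp.effect = (
        "synonymous"
        if translate_codon(codon) == translate_codon(alt_codon)
        else "nonsynonymous"
    )
    return snp.effect


def countable_codons(cds: CdsRecord) -> int:
    """Number of codons in frame 0, excluding codons containing N."""
    if cds.length_nt % 3 != 0:
        raise ValueError(
            f"CDS {cds.id!r}: length {cds.length_nt} not divisible by 3"
        )
    n = 0
    seq = cds.sequence
    for i in range(0, len(seq) - 2, 3):
        if "N" not in seq[i : i + 3]:
            n += 1
    return n


@dataclass
class PolymorphismSummary:
    """Per-scope S/NS counts and per-100-codon rates.

    ``scope`` names a CDS, a functional class or a library.  ``ns_over_s``
    is NaN when the synonymous rate is zero.
    """

    scope: str
    n_codons: int
    s_count: int
    ns_count: int
    n_cds: int = 1
    se_s: float = float("nan")
    se_ns: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_codons <= 0:
            raise ValueError(f"{self.scope!r}: no countable codons")
        if self.s_count < 0 or self.ns_count < 0:
            raise ValueError("negative polymorphism counts")

    @property
    def s_per_100(self) -> float:
        return 100.0 * self.s_count / self.n_codons

    @property
    def ns_per_100(self) -> float:
        return 100.0 * self.ns_count / self.n_codons

    @property
    def ns_over_s(self) -> float:
        return ratio_of_means(self.ns_per_100, self.s_per_100)

    @property
    def is_polymorphic(self) -> bool:
        return self.s_count + self.ns_count > 0


def ratio_of_means(mean_ns: float, mean_s: float) -> float:
    """NS/S as a ratio of (class) means; NaN when the S mean is zero."""
    if mean_s == 0:
        return float("nan")
    return mean_ns / mean_s


def rates_per_cds(
    snps: Sequence[SnpCall], cds: CdsRecord, classify: bool = True
) -> PolymorphismSummary:
    """S/NS counts and per-100-codon rates for one CDS.

    Conservation: s_count + ns_count + unset equals the number of input SNPs.
    ``classify=False`` trusts effects already present on the calls.
    """
    s = ns = 0
    for snp in snps:
        if snp.cds_id != cds.id:
            raise ValueError(f"SNP on {snp.cds_id!r} passed with CDS {cds.id!r}")
        effect = classify_effect(snp, cds) if classify else snp.effect
        if effect == "synonymous":
            s += 1
        elif effect == "nonsynonymous":
            ns += 1
    return PolymorphismSummary(
        scope=cds.id, n_codons=countable_codons(cds), s_count=s, ns_count=ns
    )


def summaries_for_cds_set(
    calls: Sequence[SnpCall], cds_set: Mapping[str, CdsRecord]
) -> dict[str, PolymorphismSummary]:
    """Per-CDS summaries over a whole call set (every CDS gets a summary,
    polymorphic or not)."""
    by_cds: dict[str, list[SnpCall]] = {}
    for c in calls:
        by_cds.setdefault(c.cds_id, []).append(c)
    return {
        cds_id: rates_per_cds(by_cds.get(cds_id, []), cds)
        for cds_id, cds in cds_set.items()
    }


def rates_per_class(
    summaries: Iterable[PolymorphismSummary],
    class_of: Mapping[str, str],
    polymorphic_only: bool = True,
) -> pd.DataFrame:
    """Class-level polymorphism table.

    Per class: mean and SE (sd/sqrt(n)) of the member-CDS per-100-codon S
    and NS rates, NS/S as the ratio of the class means, and N = number of
    (by default polymorphic) member CDS.  Rows are sorted by NS/S.
    """
    rows: dict[str, list[PolymorphismSummary]] = {}
    for s in summaries:
        if polymorphic_only and not s.is_polymorphic:
            continue
        label = class_of.get(s.scope)
        if label is None:
            continue
        rows.setdefault(label, []).append(s)
    out = []
    for label, members in rows.items():
        s_rates = np.array([m.s_per_100 for m in members])
        ns_rates = np.array([m.ns_per_100 for m in members])
        n = len(members)
        out.append(
            {
                "class_label": label,
                "mean_s_per_100": s_rates.mean(),
                "se_s": s_rates.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "mean_ns_per_100": ns_rates.mean(),
                "se_ns": ns_rates.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "ns_over_s": ratio_of_means(ns_rates.mean(), s_rates.mean()),
                "n_cds": n,
            }
        )
    df = pd.DataFrame(out)
    if not df.empty:
        df = df.sort_values("ns_over_s", ignore_index=True)
    return df


def per_library_polymorphism(
    calls_by_library: Mapping[str, Sequence[SnpCall]],
    cds_set: Mapping[str, CdsRecord],
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_qual: float = DEFAULT_MIN_QUAL,
) -> pd.DataFrame:
    """Mean +/- SE of per-CDS S and NS rates for each library.

    Rates are averaged over the shared polymorphic CDS set — the union of
    CDS polymorphic in at least one library after filtering — so every bar
    is computed on the same denominator; a CDS with no surviving SNP in a
    given library contributes zero rates there.
    """
    filtered = {
        lib: filter_snps(calls, min_depth=min_depth, min_qual=min_qual)
        for lib, calls in calls_by_library.items()
    }
    per_lib_summaries = {
        lib: summaries_for_cds_set(calls, cds_set) for lib, calls in filtered.items()
    }
    shared: set[str] = set()
    for summaries in per_lib_summaries.values():
        shared.update(s.scope for s in summaries.values() if s.is_polymorphic)
    shared_ids = sorted(shared)
    rows = []
    for lib, summaries in per_lib_summaries.items():
        s_rates = np.array([summaries[c].s_per_100 for c in shared_ids])
        ns_rates = np.array([summaries[c].ns_per_100 for c in shared_ids])
        n = len(shared_ids)
        rows.append(
            {
                "library_id": lib,
                "mean_s_per_100": s_rates.mean() if n else 0.0,
                "se_s": s_rates.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "mean_ns_per_100": ns_rates.mean() if n else 0.0,
                "se_ns": ns_rates.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "n_cds": n,
            }
        )
    return pd.DataFrame(rows)
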