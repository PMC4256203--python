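"""Expression quantification and differential-expression calls.

Core statistics
---------------
* RPKM = reads * 1e9 / (CDS length in nt * total mapped reads).  For a
  multi-library ("overall") RPKM, counts and totals are pooled before the
  formula is applied.
* The normalized fold-change ratio between two groups with per-CDS reads
  r1, r2 and group totals R1, R2:

      ratio_1over2 = r1 * R2 / (R1 * (r2 + 1))
      ratio_2over1 = r2 * R1 / (R2 * (r1 + 1))

  The +1 pseudocount in the denominator keeps both ratios finite.
* A Pearson chi-squared test (1 df, no continuity correction) on the 2x2
  table [[r1, R1-r1], [r2, R2-r2]] flags CDS whose read share differs
  between the groups.  Degenerate tables (any zero expected cell) return
  chi2 = 0, p = 1.
* A CDS is called over-expressed in a group when its normalized ratio
  reaches the fold threshold (default 10) AND its (optionally
  multiple-testing adjusted) p-value clears alpha.  Bonferroni over the CDS
  tested in a contrast is the default adjustment; pass ``mtc=None`` to test
  uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .read_processing import LibraryCounts


def rpkm(count: int, cds_length_nt: int, total_mapped: int) -> float:
    """Reads per kilobase of CDS per million mapped reads."""
    if cds_length_nt < 3:
        raise ValueError(f"CDS length {cds_length_nt} < 3")
    if total_mapped < 1:
        raise ValueError("total_mapped must be >= 1")
    return count * 1e9 / (cds_length_nt * total_mapped)


def rpkm_matrix(
    counts_by_library: Mapping[str, LibraryCounts],
    lengths: Mapping[str, int],
) -> pd.DataFrame:
    """CDS x library RPKM matrix (rows: every CDS in ``lengths``)."""
    cds_ids = list(lengths)
    data = {}
    for lib_id, lc in counts_by_library.items():
        total = max(lc.total_mapped, 1)
        data[lib_id] = [
            rpkm(lc.counts.get(c, 0), lengths[c], total) for c in cds_ids
        ]
    return pd.DataFrame(data, index=pd.Index(cds_ids, name="cds_id"))


def pooled_rpkm(
    counts_by_library: Mapping[str, LibraryCounts],
    lengths: Mapping[str, int],
    libraries: Sequence[str] | None = None,
) -> pd.Series:
    """Multi-library RPKM: counts and totals pooled before the formula."""
    libs = list(libraries) if libraries is not None else list(counts_by_library)
    total = sum(counts_by_library[l].total_mapped for l in libs)
    total = max(total, 1)
    return pd.Series(
        {
            c: rpkm(
                sum(counts_by_library[l].counts.get(c, 0) for l in libs),
                lengths[c],
                total,
            )
            for c in lengths
        },
        name="rpkm",
    )


# ---------------------------------------------------------------------------
# Ratio and test

def normalized_ratio(r1: int, R1: int, r2: int, R2: int) -> tuple[float, float]:
    """Library-size-normalized fold change in both directions."""
    if R1 < 1 or R2 < 1:
        raise ValueError("group totals must be >= 1")
    if r1 < 0 or r2 < 0 or r1 > R1 or r2 > R2:
        raise ValueError("reads must satisfy 0 <= r <= R")
    return r1 * R2 / (R1 * (r2 + 1)), r2 * R1 / (R2 * (r1 + 1))


def chi2_test(r1: int, R1: int, r2: int, R2: int) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) on the 2x2 table
    [[r1, R1-r1], [r2, R2-r2]].  Degenerate tables give (0.0, 1.0)."""
    if R1 < 1 or R2 < 1:
        raise ValueError("group totals must be >= 1")
    if r1 < 0 or r2 < 0 or r1 > R1 or r2 > R2:
        raise ValueError("reads must satisfy 0 <= r <= R")
    table = np.array([[r1, R1 - r1], [r2, R2 - r2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


@dataclass
class Contrast:
    """A two-group comparison with per-CDS reads and group totals."""

    name: str
    group1_libraries: list[str]
    group2_libraries: list[str]
    r1: pd.Series  # per-CDS reads in group 1
    r2: pd.Series
    R1: int
    R2: int


def build_contrasts(
    counts_by_library: Mapping[str, LibraryCounts],
    design: pd.DataFrame,
    cds_ids: Sequence[str] | None = None,
    regions: Sequence[str] | None = None,
) -> list[Contrast]:
    """The study's contrasts from a library design table.

    One stage contrast (all nymphal vs all adult libraries, reads summed
    within each group) plus one contrast per region (that region's libraries
    vs all the others).  ``design`` needs columns library_id, stage, region.
    ``regions`` defaults to the regions present in the design; requesting a
    region with no libraries is an error, and a region covering every
    library has no complement and yields no contrast.
    """
    design = design.set_index("library_id") if "library_id" in design.columns else design
    missing = set(design.index) - set(counts_by_library)
    if missing:
        raise ValueError(f"design lists libraries without counts: {sorted(missing)}")
    if cds_ids is None:
        ids: set[str] = set()
        for lc in counts_by_library.values():
            ids.update(lc.counts)
        cds_ids = sorted(ids)
    cds_index = pd.Index(cds_ids, name="cds_id")

    def _group(libs: list[str]) -> tuple[pd.Series, int]:
        r = pd.Series(0, index=cds_index, dtype=np.int64)
        R = 0
        for l in libs:
            lc = counts_by_library[l]
            r = r.add(pd.Series(lc.counts, dtype=np.int64), fill_value=0)
            R += lc.total_mapped
        return r.reindex(cds_index, fill_value=0).astype(np.int64), int(R)

    contrasts: list[Contrast] = []
    nymph = sorted(design.index[design["stage"] == "nymph"])
    adult = sorted(design.index[design["stage"] == "adult"])
    if nymph and adult:
        r1, R1 = _group(nymph)
        r2, R2 = _group(adult)
        contrasts.append(
            Contrast("nymph_vs_adult", nymph, adult, r1, r2, R1, R2)
        )
    region_list = sorted(design["region"].unique()) if regions is None else list(regions)
    for region in region_list:
        libs = sorted(design.index[design["region"] == region])
        rest = sorted(design.index[design["region"] != region])
        if not libs:
            raise ValueError(f"region {region!r} has no libraries")
        if not rest:
            continue  # a region covering every library has no complement
        r1, R1 = _group(libs)
        r2, R2 = _group(rest)
        contrasts.append(
            Contrast(f"{region}_vs_rest", libs, rest, r1, r2, R1, R2)
        )
    return contrasts


def de_table(
    contrast: Contrast,
    fold: float = 10.0,
    alpha: float = 0.05,
    mtc: str | None = "bonferroni",
) -> pd.DataFrame:
    """Per-CDS differential-expression table for one contrast.

    Columns: r1, r2, R1, R2, ratio_1over2, ratio_2over1, chi2, p, p_adj,
    call in {over_in_1, over_in_2, ns}.  CDS with r1 = r2 = 0 are not
    tested (p_adj = 1, call = ns) and do not count toward the Bonferroni
    family size.
    """
    if mtc not in (None, "none", "bonferroni"):
        raise ValueError(f"unknown multiple-testing mode {mtc!r}")
    r1 = contrast.r1.to_numpy(dtype=np.int64)
    r2 = contrast.r2.to_numpy(dtype=np.int64)
    R1, R2 = contrast.R1, contrast.R2
    n = len(r1)
    ratio12 = np.empty(n)
    ratio21 = np.empty(n)
    chi2 = np.empty(n)
    p = np.empty(n)
    tested = (r1 + r2) > 0
    # vectorized ratio
    ratio12 = r1 * R2 / (R1 * (r2 + 1.0))
    ratio21 = r2 * R1 / (R2 * (r1 + 1.0))
    # vectorized Pearson chi2 on [[r1, R1-r1],[r2, R2-r2]]
    a, b, c, d = r1.astype(float), (R1 - r1).astype(float), r2.astype(float), (R2 - r2).astype(float)
    N = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, N * (a * d - b * c) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(denom > 0, p, 1.0)
    m = int(tested.sum())
    if mtc == "bonferroni" and m > 0:
        p_adj = np.minimum(p * m, 1.0)
    else:
        p_adj = p.copy()
    p_adj = np.where(tested, p_adj, 1.0)
    call = np.full(n, "ns", dtype=object)
    call[(ratio12 >= fold) & (p_adj < alpha) & tested] = "over_in_1"
    call[(ratio21 >= fold) & (p_adj < alpha) & tested] = "over_in_2"
    return pd.DataFrame(
        {
            "r1": r1,
            "r2": r2,
            "R1": R1,
            "R2": R2,
            "ratio_1over2": ratio12,
            "ratio_2over1": ratio21,
            "chi2": chi2,
            "p": p,
            "p_adj": p_adj,
            "call": call,
        },
        index=contrast.r1.index,
    )


def call_overexpression(
    contrasts: Iterable[Contrast],
    fold: float = 10.0,
    alpha: float = 0.05,
    mtc: str | None = "bonferroni",
) -> dict[str, pd.DataFrame]:
    """DE tables for a set of contrasts, keyed by contrast name."""
    return {c.name: de_table(c, fold=fold, alpha=alpha, mtc=mtc) for c in contrasts}


# ---------------------------------------------------------------------------
# Class summaries and normalization

def class_summary(
    called_cds: Sequence[str],
    rpkm_group1: Mapping[str, float],
    rpkm_group2: Mapping[str, float],
    classes: Mapping[str, str],
) -> pd.DataFrame:
    """Per-class mean +/- SE of per-CDS group RPKM among called CDS.

    SE = sample sd / sqrt(n); blank (NaN) when a class has a single CDS.
    """
    rows = []
    by_class: dict[str, list[str]] = {}
    for cds_id in called_cds:
        by_class.setdefault(classes.get(cds_id, "Unknown"), []).append(cds_id)
    for label, members in sorted(by_class.items()):
        g1 = np.array([rpkm_group1[c] for c in members], dtype=float)
        g2 = np.array([rpkm_group2[c] for c in members], dtype=float)
        n = len(members)
        rows.append(
            {
                "class_label": label,
                "mean_rpkm_group1": g1.mean(),
                "se_rpkm_group1": g1.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "mean_rpkm_group2": g2.mean(),
                "se_rpkm_group2": g2.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "n_cds": n,
            }
        )
    return pd.DataFrame(rows)


def row_average_normalize(
    matrix: pd.DataFrame,
    overall_rpkm: pd.Series | None = None,
    min_overall: float = 20.0,
) -> pd.DataFrame:
    """Divide each row of an RPKM matrix by its own mean.

    Rows whose overall RPKM (pooled across libraries; defaults to the row
    mean when not supplied) falls below ``min_overall`` are dropped before
    normalization, as are all-zero rows.  Every surviving row has mean 1.
    """
    if matrix.shape[1] < 1:
        raise ValueError("matrix needs at least one column")
    overall = overall_rpkm.reindex(matrix.index) if overall_rpkm is not None else matrix.mean(axis=1)
    keep = (overall >= min_overall) & (matrix.mean(axis=1) > 0)
    sub = matrix.loc[keep]
    return sub.div(sub.mean(axis=1), axis=0)


def zscore_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row Z-scores (alternative display normalization); constant rows drop."""
    sd = matrix.std(axis=1, ddof=0)
    sub = matrix.loc[sd > 0]
    return sub.sub(sub.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)


def clustered_heatmap(matrix: pd.DataFrame, path, log_scale: bool = True):
    """Basic hierarchically clustered heat map of a normalized matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import leaves_list, linkage

    data = np.log2(matrix + 1.0) if log_scale else matrix
    if len(data) > 2:
        order = leaves_list(linkage(data.to_numpy(), method="average"))
        data = data.iloc[order]
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r", interpolation="nearest")
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels(data.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
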