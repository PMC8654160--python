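"""Duo-SGS: Fisher combination of two pedigrees' profiles, fixed-pedigree
optimization over partners, region extraction, and post-hoc filters.

The duo statistic at a SNP combines the two pedigrees' best single-pedigree
empirical p-values with Fisher's method, X = -2(ln p1 + ln p2) ~ chi-square
with 4 df under the null, whose upper tail has the closed form
exp(-X/2)(1 + X/2).  For a fixed pedigree the duo profile is the per-SNP
minimum of the combined p over all partner pedigrees.  Regions are maximal
runs of positions beyond a threshold; each reports both contributing
segments and their bp intersection — only positional overlap is required,
so the method is robust to allelic heterogeneity between pedigrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sgs_core import OptimalProfile, SharedSegment


def fisher_combine(p1: float, p2: float) -> float:
    """Fisher's combined probability for two p-values (chi-square, 4 df).

    Closed form: with q = p1*p2 and X = -2 ln q, the upper-tail probability
    is exp(-X/2)(1 + X/2) = q(1 - ln q).
    """
    return float(_fisher_vec(np.asarray(p1, float), np.asarray(p2, float)))


def _fisher_vec(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    if np.any(p1 <= 0) or np.any(p2 <= 0):
        raise ValueError("p-values must be in (0, 1]; floor empirical zeroes upstream")
    if np.any(p1 > 1) or np.any(p2 > 1):
        raise ValueError("p-values must be in (0, 1]")
    q = p1 * p2
    return q * (1.0 - np.log(q))


def duo_profile(fixed: OptimalProfile, partner: OptimalProfile) -> np.ndarray:
    """Position-wise Fisher combination of two profiles' best p-values."""
    if fixed.n_snps != partner.n_snps:
        raise ValueError(
            f"profiles on different SNP grids ({fixed.n_snps} vs {partner.n_snps}); "
            "harmonize upstream"
        )
    return _fisher_vec(fixed.p, partner.p)


@dataclass
class DuoProfile:
    """Optimized duo evidence for one fixed pedigree.

    ``combined_p[i]`` is the minimum Fisher-combined p over all partners at
    SNP i; ``partner_index[i]`` indexes ``partner_ids`` for the winner.
    """

    fixed_id: str
    partner_ids: list[str]
    combined_p: np.ndarray
    partner_index: np.ndarray

    def winning_partner(self, pos: int) -> str:
        return self.partner_ids[int(self.partner_index[pos])]


def optimize_duo(fixed_id: str, profiles: dict[str, OptimalProfile]) -> DuoProfile:
    """Per-SNP minimum combined p over all partner pedigrees.

    Ties go to the partner earliest in sorted id order (deterministic).
    """
    if fixed_id not in profiles:
        raise KeyError(f"no profile for fixed pedigree {fixed_id!r}")
    partners = sorted(p for p in profiles if p != fixed_id)
    if not partners:
        raise ValueError("duo optimization requires at least 2 pedigrees")
    fixed = profiles[fixed_id]
    best = None
    best_idx = None
    for k, pid in enumerate(partners):
        comb = duo_profile(fixed, profiles[pid])
        if best is None:
            best = comb
            best_idx = np.zeros(len(comb), dtype=np.int64)
        else:
            better = comb < best
            best = np.where(better, comb, best)
            best_idx[better] = k
    return DuoProfile(
        fixed_id=fixed_id,
        partner_ids=partners,
        combined_p=best,
        partner_index=best_idx,
    )


def intersect_segments(
    a: tuple[str, int, int], b: tuple[str, int, int]
) -> tuple[str, int, int] | None:
    """Intersection of two (chrom, start_bp, end_bp) intervals, or None."""
    ca, sa, ea = a
    cb, sb, eb = b
    if ca != cb:
        raise ValueError(f"intervals on different chromosomes ({ca} vs {cb})")
    start, end = max(sa, sb), min(ea, eb)
    return (ca, start, end) if start <= end else None


@dataclass
class DuoRegion:
    """A duo-SGS region: both contributing segments and their overlap."""

    locus: str
    fixed_id: str
    partner_id: str
    chrom: str
    start_bp: int            # extent of the thresholded duo run
    end_bp: int
    combined_p: float
    fixed_segment: SharedSegment
    partner_segment: SharedSegment
    overlap_start: int
    overlap_end: int
    expected_rate: float | None = None   # genome-wide rate mu(t) at this p
    significant: bool = False
    genes: list[str] = field(default_factory=list)

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.fixed_id, self.partner_id)))

    @property
    def overlap_span_bp(self) -> int:
        return self.overlap_end - self.overlap_start


def extract_regions(
    duo: DuoProfile,
    threshold: float,
    profiles: dict[str, OptimalProfile],
    snps: pd.DataFrame,
) -> list[DuoRegion]:
    """Maximal SNP runs with combined p <= threshold, as DuoRegions.

    Each region is summarised at its most significant SNP: the winning
    partner there, the two pedigrees' optimal segments, and the bp
    intersection of the two segments (non-empty because both cover the SNP).
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    chroms = snps["chrom"].to_numpy()
    bp = snps["bp"].to_numpy()
    below = duo.combined_p <= threshold
    regions: list[DuoRegion] = []
    start = 0
    n = len(chroms)
    blocks: list[tuple[int, int]] = []
    for i in range(1, n + 1):
        if i == n or chroms[i] != chroms[start]:
            blocks.append((start, i))
            start = i
    for lo, hi in blocks:
        block = below[lo:hi]
        padded = np.concatenate([[False], block, [False]]).astype(np.int8)
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1) + lo
        ends = np.flatnonzero(d == -1) - 1 + lo
        for a, b in zip(starts, ends):
            rep = a + int(np.argmin(duo.combined_p[a : b + 1]))
            partner = duo.winning_partner(rep)
            fseg = profiles[duo.fixed_id].segment_at(rep)
            pseg = profiles[partner].segment_at(rep)
            if fseg is None or pseg is None:  # p=1 sentinel cannot pass threshold
                continue
            ov = intersect_segments(
                (fseg.chrom, fseg.start_bp, fseg.end_bp),
                (pseg.chrom, pseg.start_bp, pseg.end_bp),
            )
            assert ov is not None  # both segments cover SNP rep
            regions.append(
                DuoRegion(
                    locus=f"{chroms[a]}:{bp[a]}-{bp[b]}",
                    fixed_id=duo.fixed_id,
                    partner_id=partner,
                    chrom=str(chroms[a]),
                    start_bp=int(bp[a]),
                    end_bp=int(bp[b]),
                    combined_p=float(duo.combined_p[rep]),
                    fixed_segment=fseg,
                    partner_segment=pseg,
                    overlap_start=ov[1],
                    overlap_end=ov[2],
                )
            )
    return regions


def posthoc_filter(
    regions: list[DuoRegion],
    centromeres: pd.DataFrame | None = None,
    memberships: dict[str, str] | None = None,
    thresholds: dict[str, float] | None = None,
) -> list[DuoRegion]:
    """Post-hoc region filters, applied in order:

    1. duplicates — the same unordered pedigree pair reporting overlapping
       intervals from both fixed-pedigree analyses: keep the most
       significant (smallest p relative to its fixed pedigree's significant
       threshold when ``thresholds`` is given, since thresholds differ by
       fixed pedigree; raw p otherwise);
    2. overlap individuals — a person (after optional ``memberships`` id
       aliasing) appearing in the sharing subsets of both pedigrees;
    3. centromere-spanning regions (``centromeres``: BED-like chrom/start/end).
    """
    def rank(r: DuoRegion) -> float:
        if thresholds and r.fixed_id in thresholds:
            return r.combined_p / thresholds[r.fixed_id]
        return r.combined_p

    keep = list(regions)
    # 1. duplicates within the same unordered pair at overlapping positions
    removed: set[int] = set()
    for i in range(len(keep)):
        for j in range(i + 1, len(keep)):
            a, b = keep[i], keep[j]
            if i in removed or j in removed:
                continue
            if a.pair != b.pair or a.chrom != b.chrom:
                continue
            if max(a.start_bp, b.start_bp) <= min(a.end_bp, b.end_bp):
                removed.add(j if rank(a) <= rank(b) else i)
    keep = [r for k, r in enumerate(keep) if k not in removed]

    # 2. same individual sharing the region in both pedigrees
    def person(i: str) -> str:
        return memberships.get(i, i) if memberships else i

    keep = [
        r
        for r in keep
        if not (
            {person(i) for i in r.fixed_segment.subset}
            & {person(i) for i in r.partner_segment.subset}
        )
    ]

    # 3. centromere-spanning
    if centromeres is not None and len(centromeres):
        cen = {
            str(row.chrom): (int(row.start), int(row.end))
            for row in centromeres.itertuples()
        }
        def spans(r: DuoRegion) -> bool:
            if r.chrom not in cen:
                return False
            s, e = cen[r.chrom]
            return r.start_bp <= e and r.end_bp >= s
        keep = [r for r in keep if not spans(r)]
    return keep


def annotate_regions(regions: list[DuoRegion], genes: pd.DataFrame) -> list[DuoRegion]:
    """Attach genes overlapping each region's overlap interval.

    ``genes`` is BED-like with columns chrom, start, end, name; any overlap
    counts.
    """
    for r in regions:
        hits = []
        for row in genes.itertuples():
            if (
                str(row.chrom) == r.chrom
                and int(row.start) <= r.overlap_end
                and int(row.end) >= r.overlap_start
            ):
                hits.append(str(row.name))
        r.genes = hits
    return regions


_REGION_COLUMNS = [
    "locus", "chrom", "duo_p", "mu_t", "significant",
    "fixed_pedigree", "fixed_p", "fixed_start_bp", "fixed_end_bp",
    "fixed_n_cases", "partner_pedigree", "partner_p", "partner_start_bp",
    "partner_end_bp", "partner_n_cases", "overlap_start_bp",
    "overlap_end_bp", "genes",
]


def regions_table(regions: list[DuoRegion]) -> pd.DataFrame:
    """Report mirroring the published region-table layout."""
    rows = []
    for r in regions:
        rows.append(
            {
                "locus": r.locus,
                "chrom": r.chrom,
                "duo_p": r.combined_p,
                "mu_t": r.expected_rate,
                "significant": r.significant,
                "fixed_pedigree": r.fixed_id,
                "fixed_p": r.fixed_segment.empirical_p,
                "fixed_start_bp": r.fixed_segment.start_bp,
                "fixed_end_bp": r.fixed_segment.end_bp,
                "fixed_n_cases": len(r.fixed_segment.subset),
                "partner_pedigree": r.partner_id,
                "partner_p": r.partner_segment.empirical_p,
                "partner_start_bp": r.partner_segment.start_bp,
                "partner_end_bp": r.partner_segment.end_bp,
                "partner_n_cases": len(r.partner_segment.subset),
                "overlap_start_bp": r.overlap_start,
                "overlap_end_bp": r.overlap_end,
                "genes": ";".join(r.genes),
            }
        )
    return pd.DataFrame(rows, columns=_REGION_COLUMNS)
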