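"""Shared Genomic Segment core: IBS sharing runs and optimized profiles.

A case subset shares a SNP identity-by-state when some allele is carried by
every member, i.e. the non-missing calls do not include both homozygote
classes.  Maximal runs of shared SNPs are the observed segments; after each
segment receives an empirical p-value the per-SNP minimum over covering
segments yields the pedigree's optimized profile (the best evidence for
excess sharing at each position, optimized over all case subsets).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np

from .pedio import GenotypeMatrix, MISSING


@dataclass(frozen=True)
class SharedSegment:
    """A maximal IBS run for one case subset (bp coordinates inclusive)."""

    pedigree_id: str
    subset: tuple[str, ...]
    chrom: str
    first_snp: int          # global SNP index, inclusive
    last_snp: int
    start_bp: int
    end_bp: int
    empirical_p: float | None = None

    def __post_init__(self) -> None:
        if len(self.subset) < 2:
            raise ValueError("segment subset must contain at least 2 cases")
        if self.start_bp > self.end_bp or self.first_snp > self.last_snp:
            raise ValueError("segment end precedes start")

    @property
    def n_snps(self) -> int:
        return self.last_snp - self.first_snp + 1

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp

    def with_p(self, p: float) -> "SharedSegment":
        return replace(self, empirical_p=float(p))


def sharing_indicator(
    genotypes: GenotypeMatrix,
    subset: tuple[str, ...] | list[str],
    missing_breaks: bool = False,
) -> np.ndarray:
    """Per-SNP boolean: does some allele exist carried by every subset member?

    Equivalent to: the subset's non-missing calls do not contain both
    homozygote classes.  Missing calls are treated as compatible with
    sharing unless ``missing_breaks`` is set.
    """
    if len(subset) < 2:
        raise ValueError("subset must contain at least 2 cases")
    cols = [genotypes.sample_index(s) for s in subset]
    sub = genotypes.calls[:, cols]
    has_hom_ref = (sub == 0).any(axis=1)
    has_hom_alt = (sub == 2).any(axis=1)
    ind = ~(has_hom_ref & has_hom_alt)
    if missing_breaks:
        ind &= ~(sub == MISSING).any(axis=1)
    return ind


def detect_runs(
    indicator: np.ndarray,
    genotypes: GenotypeMatrix,
    subset: tuple[str, ...],
    pedigree_id: str = "",
) -> list[SharedSegment]:
    """Maximal true-runs of the indicator as SharedSegments.

    Runs never cross chromosome boundaries; bp span is from the first to
    the last SNP of the run.  Single-SNP runs are retained (downstream
    assessment renders them non-significant).
    """
    indicator = np.asarray(indicator, dtype=bool)
    if indicator.shape[0] != genotypes.n_snps:
        raise ValueError("indicator not aligned to SNP metadata")
    bp = genotypes.snps["bp"].to_numpy()
    segments: list[SharedSegment] = []
    for chrom, lo, hi in genotypes.chrom_slices():
        block = indicator[lo:hi]
        padded = np.concatenate([[False], block, [False]]).astype(np.int8)
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1) - 1
        for a, b in zip(starts, ends):
            segments.append(
                SharedSegment(
                    pedigree_id=pedigree_id,
                    subset=tuple(sorted(subset)),
                    chrom=chrom,
                    first_snp=lo + int(a),
                    last_snp=lo + int(b),
                    start_bp=int(bp[lo + a]),
                    end_bp=int(bp[lo + b]),
                )
            )
    return segments


def segments_to_bed(segments: list[SharedSegment], path) -> None:
    """Dump segments as BED (0-based half-open) with subset and p columns."""
    with open(path, "w") as fh:
        for s in segments:
            name = ",".join(s.subset)
            p = "" if s.empirical_p is None else f"\t{s.empirical_p:g}"
            fh.write(f"{s.chrom}\t{s.start_bp - 1}\t{s.end_bp}\t{name}{p}\n")


def enumerate_subsets(
    cases: tuple[str, ...] | list[str], min_size: int = 2
) -> list[tuple[str, ...]]:
    """All case subsets of size >= min_size, largest first then lexicographic."""
    cases = sorted(cases)
    if len(cases) < min_size:
        raise ValueError(f"need at least {min_size} cases, got {len(cases)}")
    out: list[tuple[str, ...]] = []
    for size in range(len(cases), min_size - 1, -1):
        out.extend(combinations(cases, size))
    return out


@dataclass
class OptimalProfile:
    """Per-SNP best (lowest) empirical p over all segments of one pedigree.

    ``p`` is 1.0 at positions covered by no segment; ``seg_index`` points
    into ``segments`` (-1 where uncovered).
    """

    pedigree_id: str
    p: np.ndarray
    seg_index: np.ndarray
    segments: list[SharedSegment]

    @property
    def n_snps(self) -> int:
        return len(self.p)

    def segment_at(self, pos: int) -> SharedSegment | None:
        k = int(self.seg_index[pos])
        return self.segments[k] if k >= 0 else None


def optimize_profile(
    segments: list[SharedSegment], n_snps: int, pedigree_id: str | None = None
) -> OptimalProfile:
    """Minimum empirical p per SNP over covering segments.

    Ties broken by larger subset, then longer bp span, then lexicographic
    subset order; uncovered positions carry the p = 1 sentinel.
    """
    for seg in segments:
        if seg.empirical_p is None:
            raise ValueError("every segment must carry an empirical_p")
    if pedigree_id is None:
        pedigree_id = segments[0].pedigree_id if segments else ""
    p = np.ones(n_snps)
    idx = np.full(n_snps, -1, dtype=np.int64)
    order = sorted(
        range(len(segments)),
        key=lambda k: (
            segments[k].empirical_p,
            -len(segments[k].subset),
            -segments[k].span_bp,
            segments[k].subset,
        ),
    )
    for k in reversed(order):  # best segment overwrites last
        seg = segments[k]
        sl = slice(seg.first_snp, seg.last_snp + 1)
        p[sl] = seg.empirical_p
        idx[sl] = k
    return OptimalProfile(pedigree_id=pedigree_id, p=p, seg_index=idx, segments=list(segments))
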