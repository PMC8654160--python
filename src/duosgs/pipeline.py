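"""End-to-end orchestration: single-pedigree SGS and multi-pedigree duo-SGS.

All randomness flows from one master seed through named numpy SeedSequence
substreams (gene-drop assessment, threshold perturbation), so each stage is
independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .duo import (
    DuoProfile,
    DuoRegion,
    annotate_regions,
    extract_regions,
    optimize_duo,
    posthoc_filter,
    regions_table,
)
from .genedrop import assess_segments, build_context
from .ldmap import GeneticMap, LDModel, fit_ld_model
from .pedio import GenotypeMatrix, Pedigree
from .sgs_core import (
    OptimalProfile,
    SharedSegment,
    detect_runs,
    enumerate_subsets,
    optimize_profile,
    sharing_indicator,
)
from .thresholds import ThresholdFit, thresholds_for_pedigree


def _substream(master_seed: int, *tags: object) -> int:
    """Deterministic 31-bit child seed for a named stage (stable across runs)."""
    h = np.random.SeedSequence(
        [int(master_seed)] + [zlib.crc32(str(t).encode()) for t in tags]
    )
    return int(h.generate_state(1)[0] % (2**31))


@dataclass
class SingleResult:
    """Observed segments with empirical p-values plus the optimized profile."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    model: LDModel
    segments: list[SharedSegment]
    profile: OptimalProfile
    n_sims: int

    def segments_table(self) -> pd.DataFrame:
        rows = [
            {
                "pedigree": s.pedigree_id,
                "subset": ",".join(s.subset),
                "chrom": s.chrom,
                "start_bp": s.start_bp,
                "end_bp": s.end_bp,
                "n_snps": s.n_snps,
                "empirical_p": s.empirical_p,
            }
            for s in self.segments
        ]
        return pd.DataFrame(rows)


def run_single(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    n_sims: int,
    seed: int,
    model: LDModel | None = None,
    min_subset: int = 2,
    missing_breaks: bool = False,
) -> SingleResult:
    """Single-pedigree SGS: observed runs for every case subset, gene-drop
    empirical p-values, and the per-SNP optimized profile."""
    cases = [c for c in pedigree.genotyped_cases if c in genotypes.sample_ids]
    if len(cases) < 2:
        raise ValueError(
            f"pedigree {pedigree.pedigree_id}: fewer than 2 genotyped cases present"
        )
    if model is None:
        model = fit_ld_model(genotypes=genotypes)
    segments: list[SharedSegment] = []
    for subset in enumerate_subsets(cases, min_subset):
        ind = sharing_indicator(genotypes, subset, missing_breaks=missing_breaks)
        segments.extend(detect_runs(ind, genotypes, subset, pedigree.pedigree_id))
    segments = assess_segments(
        pedigree, segments, model, gmap, n_sims,
        _substream(seed, "genedrop", pedigree.pedigree_id),
    )
    profile = optimize_profile(segments, genotypes.n_snps, pedigree.pedigree_id)
    return SingleResult(
        pedigree=pedigree,
        genotypes=genotypes,
        model=model,
        segments=segments,
        profile=profile,
        n_sims=n_sims,
    )


@dataclass
class DuoResult:
    """Duo-SGS output across all fixed pedigrees."""

    fits: dict[str, ThresholdFit]
    duo_profiles: dict[str, DuoProfile]
    regions: list[DuoRegion]
    snps: pd.DataFrame

    def thresholds_table(self) -> pd.DataFrame:
        rows = [
            {
                "pedigree": f.fixed_id,
                "significant": f.T_sig,
                "suggestive": f.T_sugg,
                "k": f.k,
                "sigma": f.sigma,
                "C": f.C,
                "G": f.G,
                "n_sims": f.n_sims,
            }
            for f in self.fits.values()
        ]
        return pd.DataFrame(rows)

    def regions_table(self) -> pd.DataFrame:
        return regions_table(self.regions)


def run_duo(
    singles: dict[str, SingleResult],
    gmap: GeneticMap,
    seed: int,
    C: int | None = None,
    centromeres: pd.DataFrame | None = None,
    genes: pd.DataFrame | None = None,
    memberships: dict[str, str] | None = None,
) -> DuoResult:
    """Fixed-pedigree duo optimization, thresholds, regions, post-hoc filters.

    For every pedigree in turn: derive its genome-wide thresholds by
    perturbation + gamma fit + Large Deviations, optimize the duo evidence
    over all partners, and extract regions at the suggestive level (flagged
    significant where the combined p clears the significant threshold).
    """
    if len(singles) < 2:
        raise ValueError("duo analysis requires at least 2 pedigrees")
    first = next(iter(singles.values()))
    snps = first.genotypes.snps
    n_sims = first.n_sims
    profiles = {pid: s.profile for pid, s in singles.items()}
    fits: dict[str, ThresholdFit] = {}
    duos: dict[str, DuoProfile] = {}
    regions: list[DuoRegion] = []
    for fixed_id in sorted(singles):
        fit = thresholds_for_pedigree(
            fixed_id, profiles, n_sims,
            _substream(seed, "perturb", fixed_id), gmap, C=C,
        )
        duo = optimize_duo(fixed_id, profiles)
        regs = extract_regions(duo, fit.T_sugg, profiles, snps)
        for r in regs:
            r.significant = r.combined_p <= fit.T_sig
            r.expected_rate = fit.mu_of_p(r.combined_p)
        fits[fixed_id] = fit
        duos[fixed_id] = duo
        regions.extend(regs)
    regions = posthoc_filter(
        regions,
        centromeres=centromeres,
        memberships=memberships,
        thresholds={pid: f.T_sig for pid, f in fits.items()},
    )
    if genes is not None:
        regions = annotate_regions(regions, genes)
    return DuoResult(fits=fits, duo_profiles=duos, regions=regions, snps=snps)
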