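"""Synthetic pedigrees, LD-structured genotypes, and planted IBD segments.

Emulates the study design the analysis targets: multi-generation high-risk
pedigrees with a handful of genotyped cases separated by 8-23 meioses,
dense biallelic SNP data with adjacent-marker LD, and optionally a planted
identity-by-descent segment shared by a chosen case subset.  The generator
returns the true simulation model alongside the data so every downstream
stage can be checked against a known truth.

Defaults are the package's desk-scale study conditions: 4 genotyped cases
at 12 meioses, 4 chromosomes of 2,000 SNPs each (160 cM / 100 Mb per
chromosome), marginal alternate-allele frequencies U(0.1, 0.9), and
adjacent-haplotype LD correlation 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels
from .genedrop import build_context
from .ldmap import GeneticMap, LDModel, write_genetic_map
from .pedio import GenotypeMatrix, Pedigree, Person, write_genotypes, write_pedigree


@dataclass
class PlantedSegment:
    """A segment to copy IBD into a chosen carrier subset."""

    chrom: str
    start_bp: int
    end_bp: int
    carriers: tuple[str, ...]


@dataclass
class SynthConfig:
    pedigree_id: str = "SYN1"
    n_cases: int = 4
    meiosis_band: tuple[int, int] = (8, 23)
    case_depths: tuple[int, ...] | None = None
    sibship_size: int = 2
    n_chromosomes: int = 4
    n_snps_per_chrom: int = 2000
    chrom_length_cm: float = 160.0
    chrom_length_bp: int = 100_000_000
    maf_range: tuple[float, float] = (0.1, 0.9)
    ld: float = 0.5
    planted: PlantedSegment | None = None
    seed: int = 0

    @property
    def n_generations(self) -> int:
        depths = self.case_depths or _choose_depths(
            self.n_cases, self.meiosis_band, max_depth=8
        )
        return max(depths) + 1


def _choose_depths(
    n_cases: int, band: tuple[int, int], max_depth: int
) -> tuple[int, ...]:
    """Case generation depths whose sum (total meioses, disjoint branches)
    falls inside the requested band, as balanced as possible."""
    lo, hi = band
    if n_cases < 2:
        raise ValueError("need at least 2 cases")
    target = (lo + hi) // 2
    base = max(1, round(target / n_cases))
    depths = [min(base, max_depth)] * n_cases
    # nudge individual depths until the total lands in the band
    for _ in range(10 * n_cases * max_depth):
        total = sum(depths)
        if lo <= total <= hi:
            return tuple(depths)
        i = int(np.argmin(depths)) if total < lo else int(np.argmax(depths))
        if total < lo:
            if depths[i] >= max_depth:
                raise ValueError(f"meiosis band {band} infeasible at depth {max_depth}")
            depths[i] += 1
        else:
            if depths[i] <= 1:
                raise ValueError(f"meiosis band {band} infeasible")
            depths[i] -= 1
    raise ValueError(f"meiosis band {band} infeasible")


def make_pedigree(config: SynthConfig, rng: np.random.Generator) -> Pedigree:
    """Founder couple expanded into distinct case branches.

    Each genotyped case sits at the bottom of its own descent chain from the
    top founder couple; descendants marry spawned-in founders (outbred
    pedigree), so the meiosis count between the cases is the sum of branch
    depths and lands in the requested band by construction.  Extra sibs
    (``sibship_size``) pad each internal couple for realism.
    """
    depths = config.case_depths or _choose_depths(
        config.n_cases, config.meiosis_band, max_depth=8
    )
    if len(depths) != config.n_cases:
        raise ValueError("case_depths length must equal n_cases")
    pid = config.pedigree_id
    persons: dict[str, Person] = {}
    top_f, top_m = f"{pid}_F0", f"{pid}_M0"
    persons[top_f] = Person(top_f, None, None, sex=1)
    persons[top_m] = Person(top_m, None, None, sex=2)
    cases: list[str] = []
    for b, depth in enumerate(depths):
        fa, mo = top_f, top_m
        for g in range(1, depth + 1):
            is_last = g == depth
            child = f"{pid}_b{b}_g{g}"
            sex = 1 if rng.random() < 0.5 else 2
            persons[child] = Person(
                child, fa, mo, sex=sex, affected=is_last, sampled=is_last
            )
            for k in range(1, config.sibship_size):
                sib = f"{pid}_b{b}_g{g}s{k}"
                persons[sib] = Person(sib, fa, mo, sex=1 if rng.random() < 0.5 else 2)
            if is_last:
                cases.append(child)
            else:
                spouse = f"{pid}_b{b}_g{g}sp"
                persons[spouse] = Person(spouse, None, None, sex=3 - sex)
                fa, mo = (child, spouse) if sex == 1 else (spouse, child)
    return Pedigree(pedigree_id=pid, persons=persons, genotyped_cases=tuple(cases))


def _build_truth_model(config: SynthConfig, rng: np.random.Generator) -> tuple[
    pd.DataFrame, LDModel, GeneticMap
]:
    n, C = config.n_snps_per_chrom, config.n_chromosomes
    spacing_bp = config.chrom_length_bp // n
    rows = []
    t0d, t1d = {}, {}
    anchors = {}
    for c in range(1, C + 1):
        chrom = str(c)
        bp = 1 + spacing_bp * np.arange(n, dtype=np.int64)
        cm = config.chrom_length_cm * np.arange(n) / max(n - 1, 1)
        f = rng.uniform(*config.maf_range, size=n)
        t0 = np.empty(n)
        t1 = np.empty(n)
        t0[0] = t1[0] = f[0]
        rho = config.ld
        for i in range(1, n):
            sd = np.sqrt(f[i - 1] * (1 - f[i - 1]) * f[i] * (1 - f[i]))
            h11 = f[i - 1] * f[i] + rho * sd
            h11 = min(max(h11, 0.0), min(f[i - 1], f[i]))
            t1[i] = h11 / f[i - 1]
            t0[i] = (f[i] - h11) / (1 - f[i - 1])
        np.clip(t0, 1e-6, 1 - 1e-6, out=t0)
        np.clip(t1, 1e-6, 1 - 1e-6, out=t1)
        t0d[chrom], t1d[chrom] = t0, t1
        anchors[chrom] = (np.array([bp[0], bp[-1]]), np.array([0.0, config.chrom_length_cm]))
        for i in range(n):
            rows.append((chrom, f"snp{c}_{i}", cm[i], bp[i]))
    snps = pd.DataFrame(rows, columns=["chrom", "snp_id", "cm", "bp"])
    snps["a1"] = "A"
    snps["a2"] = "B"
    model = LDModel(snps=snps, t0=t0d, t1=t1d)
    gmap = GeneticMap(anchors)
    return snps, model, gmap


@dataclass
class SynthDataset:
    """A generated dataset plus the truth used to generate it."""

    config: SynthConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix          # genotyped cases only
    gmap: GeneticMap
    model: LDModel                     # the true simulation chain
    case_haplotypes: np.ndarray        # int8 (2*n_cases, n_snps)
    planted: PlantedSegment | None = None

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "pedigree": outdir / "pedigree.txt",
            "ped": outdir / "genotypes.ped",
            "map": outdir / "genotypes.map",
            "genetic_map": outdir / "genetic.map",
            "truth": outdir / "truth.json",
        }
        write_pedigree(self.pedigree, paths["pedigree"])
        write_genotypes(self.genotypes, paths["ped"], paths["map"], self.pedigree)
        write_genetic_map(self.gmap, paths["genetic_map"])
        truth = {
            "seed": self.config.seed,
            "pedigree_id": self.pedigree.pedigree_id,
            "cases": list(self.pedigree.genotyped_cases),
            "planted": None
            if self.planted is None
            else {
                "chrom": self.planted.chrom,
                "start_bp": self.planted.start_bp,
                "end_bp": self.planted.end_bp,
                "carriers": list(self.planted.carriers),
            },
        }
        paths["truth"].write_text(json.dumps(truth, indent=2))
        return paths


def generate_genotypes(
    pedigree: Pedigree, config: SynthConfig, rng: np.random.Generator
) -> SynthDataset:
    """Drop the truth chain through the pedigree; return data + truth model."""
    snps, model, gmap = _build_truth_model(config, rng)
    ctx = build_context(pedigree, model, gmap)
    seed = np.uint64(rng.integers(0, 2**63, dtype=np.int64))
    haps = np.empty((2 * ctx.n_ind, ctx.n_snps), np.int8)
    _kernels.drop_haplotypes(
        seed, ctx.father, ctx.mother, ctx.chrom_off, ctx.cm, ctx.thr, haps
    )
    case_haps = np.empty((2 * len(ctx.case_rows), ctx.n_snps), np.int8)
    for j, row in enumerate(ctx.case_rows):
        case_haps[2 * j] = haps[2 * row]
        case_haps[2 * j + 1] = haps[2 * row + 1]
    geno = (case_haps[0::2] + case_haps[1::2]).astype(np.int8)
    gm = GenotypeMatrix(snps.copy(), list(ctx.case_ids), geno.T.copy())
    return SynthDataset(
        config=config,
        pedigree=pedigree,
        genotypes=gm,
        gmap=gmap,
        model=model,
        case_haplotypes=case_haps,
    )


def plant_shared_segment(
    dataset: SynthDataset,
    planted: PlantedSegment,
    rng: np.random.Generator,
) -> SynthDataset:
    """Copy one founder haplotype over the interval into every carrier.

    A fresh chain haplotype (a founder haplotype the carriers inherit IBD)
    is written into one haplotype of each carrier across the interval; all
    other positions are untouched, so IBS sharing emerges exactly as the
    detector expects, heterozygosity included.
    """
    snps = dataset.genotypes.snps
    cases = list(dataset.genotypes.sample_ids)
    for c in planted.carriers:
        if c not in cases:
            raise ValueError(f"carrier {c!r} is not a genotyped case")
    mask = (
        (snps["chrom"] == planted.chrom).to_numpy()
        & (snps["bp"].to_numpy() >= planted.start_bp)
        & (snps["bp"].to_numpy() <= planted.end_bp)
    )
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("planted interval contains no SNPs")
    from .ldmap import sample_founder_haplotypes

    shared = sample_founder_haplotypes(dataset.model, 1, rng)[0]
    case_haps = dataset.case_haplotypes.copy()
    for c in planted.carriers:
        j = cases.index(c)
        case_haps[2 * j, idx] = shared[idx]
    geno = (case_haps[0::2] + case_haps[1::2]).astype(np.int8)
    gm = GenotypeMatrix(snps.copy(), cases, geno.T.copy())
    return SynthDataset(
        config=dataset.config,
        pedigree=dataset.pedigree,
        genotypes=gm,
        gmap=dataset.gmap,
        model=dataset.model,
        case_haplotypes=case_haps,
        planted=planted,
    )


def simulate_dataset(config: SynthConfig) -> SynthDataset:
    """Pedigree + genotypes (+ optional planted segment) from one master seed."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    pedigree = make_pedigree(config, rng)
    ds = generate_genotypes(pedigree, config, rng)
    if config.planted is not None:
        planted = config.planted
        if not planted.carriers:
            planted = PlantedSegment(
                planted.chrom, planted.start_bp, planted.end_bp,
                tuple(pedigree.genotyped_cases),
            )
        ds = plant_shared_segment(ds, planted, rng)
    return ds
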