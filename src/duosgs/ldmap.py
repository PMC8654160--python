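"""Genetic-map interpolation and the population LD model for founder haplotypes.

The LD model is a first-order Markov chain over the 0/1 allele sequence of
each chromosome: the alternate-allele frequency of the first SNP plus, for
every adjacent SNP pair, the probability of carrying the alternate allele
given the allele at the previous SNP.  This is the standard founder-
haplotype engine for gene-drop simulation; it captures the adjacent-marker
LD that inflates chance IBS runs while remaining cheap to sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels
from .pedio import GenotypeMatrix, MISSING, _chrom_sort_key

EPS = 1e-6
"""Clamp applied to every transition probability (kept inside [EPS, 1-EPS])."""


@dataclass
class GeneticMap:
    """Per-chromosome (bp, cM) anchor lists; cM non-decreasing in bp."""

    anchors: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        clean = {}
        for chrom, (bp, cm) in self.anchors.items():
            bp = np.asarray(bp, dtype=np.int64)
            cm = np.asarray(cm, dtype=np.float64)
            if bp.size == 0:
                raise ValueError(f"chromosome {chrom}: empty map")
            order = np.argsort(bp)
            bp, cm = bp[order], cm[order]
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"chromosome {chrom}: cM decreases with bp")
            clean[chrom] = (bp, cm)
        self.anchors = clean

    @property
    def chromosomes(self) -> list[str]:
        return list(self.anchors)

    def total_morgans(self) -> float:
        """Genome length G in Morgans: sum of per-chromosome cM spans / 100."""
        return sum((cm[-1] - cm[0]) / 100.0 for _, cm in self.anchors.values())


def read_genetic_map(path: str | Path) -> GeneticMap:
    """HapMap-style 3-column map: chromosome, bp, cM (tab/space separated)."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["chrom", "bp", "cm"],
        dtype={"chrom": str, "bp": int, "cm": float}, comment="#",
    )
    key = _chrom_sort_key(list(df["chrom"]))
    anchors = {
        chrom: (g["bp"].to_numpy(), g["cm"].to_numpy())
        for chrom, g in sorted(df.groupby("chrom"), key=lambda kv: key[kv[0]])
    }
    return GeneticMap(anchors)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, (bp, cm) in gmap.anchors.items():
            for b, c in zip(bp, cm):
                fh.write(f"{chrom}\t{b}\t{c:g}\n")


def interpolate_cm(gmap: GeneticMap, chrom: str, bp) -> np.ndarray | float:
    """Linear interpolation between anchors, constant beyond the ends."""
    if chrom not in gmap.anchors:
        raise KeyError(f"chromosome {chrom!r} not in genetic map")
    abp, acm = gmap.anchors[chrom]
    out = np.interp(np.asarray(bp, dtype=float), abp.astype(float), acm)
    return float(out) if np.isscalar(bp) else out


def haldane(d_cm) -> np.ndarray | float:
    """Haldane map function: recombination fraction for a distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


@dataclass
class LDModel:
    """First-order haplotype Markov chain aligned to a SNP table.

    ``t0[c][i]`` / ``t1[c][i]`` give P(allele_i = 1 | allele_{i-1} = 0 / 1)
    for chromosome c; at index 0 both equal the marginal frequency of the
    first SNP.  ``snps`` carries chrom/bp metadata in matrix order.
    """

    snps: pd.DataFrame
    t0: dict[str, np.ndarray]
    t1: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom in self.t0:
            a, b = self.t0[chrom], self.t1[chrom]
            if a.shape != b.shape:
                raise ValueError(f"chromosome {chrom}: t0/t1 length mismatch")
            for arr in (a, b):
                if np.any(arr < 0) or np.any(arr > 1):
                    raise ValueError(f"chromosome {chrom}: probability outside [0,1]")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.t0)

    def transition_matrix(self, chrom: str, i: int) -> np.ndarray:
        """2x2 row-stochastic matrix P(allele_i | allele_{i-1}), i >= 1."""
        t0, t1 = self.t0[chrom][i], self.t1[chrom][i]
        return np.array([[1 - t0, t0], [1 - t1, t1]])

    def marginals(self, chrom: str) -> np.ndarray:
        """Allele-1 frequency implied by the chain at every SNP."""
        t0, t1 = self.t0[chrom], self.t1[chrom]
        f = np.empty_like(t0)
        f[0] = t0[0]
        for i in range(1, len(t0)):
            f[i] = f[i - 1] * t1[i] + (1 - f[i - 1]) * t0[i]
        return f

    def flat_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(chrom_off, t0, t1) flattened genome-wide for the kernels."""
        t0 = np.concatenate([self.t0[c] for c in self.chromosomes])
        t1 = np.concatenate([self.t1[c] for c in self.chromosomes])
        sizes = [len(self.t0[c]) for c in self.chromosomes]
        off = np.concatenate([[0], np.cumsum(sizes)]).astype(np.int64)
        return off, t0, t1


def fit_ld_model(
    genotypes: GenotypeMatrix | None = None,
    haplotypes: np.ndarray | None = None,
    snps: pd.DataFrame | None = None,
    eps: float = EPS,
) -> LDModel:
    """Estimate the haplotype chain from a phased panel or from genotypes.

    With ``haplotypes`` (0/1 array of shape (n_hap, n_snps) aligned to
    ``snps``), pair frequencies are counted directly.  With genotypes only,
    a composite-haplotype approximation is used: the haplotype covariance of
    each adjacent pair is estimated as half the genotype covariance
    (composite LD), and pair frequencies are reconstructed from it.
    Monomorphic previous SNPs fall back to independence at the marginal
    frequency.  All transitions are clamped to [eps, 1-eps].
    """
    if (genotypes is None) == (haplotypes is None):
        raise ValueError("pass exactly one of genotypes or haplotypes")
    if haplotypes is not None:
        if snps is None:
            raise ValueError("snps metadata required with a haplotype panel")
        snps = snps.reset_index(drop=True)
        H = np.asarray(haplotypes)
    else:
        snps = genotypes.snps
        H = None

    chrom_blocks: list[tuple[str, int, int]] = []
    chroms = snps["chrom"].to_numpy()
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            chrom_blocks.append((chroms[start], start, i))
            start = i

    t0d: dict[str, np.ndarray] = {}
    t1d: dict[str, np.ndarray] = {}
    for chrom, lo, hi in chrom_blocks:
        n = hi - lo
        if n < 2:
            raise ValueError(f"chromosome {chrom}: need at least 2 SNPs")
        t0 = np.empty(n)
        t1 = np.empty(n)
        if H is not None:
            block = H[:, lo:hi].astype(float)
            p = block.mean(axis=0)
            t0[0] = t1[0] = p[0]
            for i in range(1, n):
                prev, cur = block[:, i - 1], block[:, i]
                n1 = prev.sum()
                n0 = len(prev) - n1
                if n1 == 0 or n0 == 0:
                    t0[i] = t1[i] = p[i]  # monomorphic: independence fallback
                else:
                    t1[i] = cur[prev == 1].mean()
                    t0[i] = cur[prev == 0].mean()
        else:
            calls = genotypes.calls[lo:hi].astype(float)
            calls[calls == MISSING] = np.nan
            p = np.nanmean(calls, axis=1) / 2.0
            t0[0] = t1[0] = p[0]
            for i in range(1, n):
                gi, gj = calls[i - 1], calls[i]
                ok = ~np.isnan(gi) & ~np.isnan(gj)
                pi, pj = p[i - 1], p[i]
                if ok.sum() < 2 or pi <= 0 or pi >= 1:
                    t0[i] = t1[i] = pj  # monomorphic/uninformative: independence
                    continue
                # composite LD: haplotype covariance ~ genotype covariance / 2
                D = np.cov(gi[ok], gj[ok], ddof=0)[0, 1] / 2.0
                h11 = pi * pj + D
                h11 = min(max(h11, 0.0), min(pi, pj))
                t1[i] = h11 / pi
                t0[i] = (pj - h11) / (1.0 - pi)
        np.clip(t0, eps, 1.0 - eps, out=t0)
        np.clip(t1, eps, 1.0 - eps, out=t1)
        t0d[chrom], t1d[chrom] = t0, t1
    return LDModel(snps=snps, t0=t0d, t1=t1d)


def sample_founder_chromosome(
    model: LDModel, chrom: str, rng: np.random.Generator
) -> np.ndarray:
    """Draw an independent haplotype pair (2, n_snps) for one chromosome."""
    if chrom not in model.t0:
        raise KeyError(f"chromosome {chrom!r} not covered by LD model")
    t0, t1 = model.t0[chrom], model.t1[chrom]
    off = np.array([0, len(t0)], dtype=np.int64)
    seed = np.uint64(rng.integers(0, 2**63, dtype=np.int64))
    return _kernels.sample_haplotype_batch(seed, t0, t1, off, 2)


def sample_founder_haplotypes(
    model: LDModel, n_hap: int, rng: np.random.Generator
) -> np.ndarray:
    """Genome-wide chain haplotypes (n_hap, n_snps) in matrix SNP order."""
    off, t0, t1 = model.flat_arrays()
    seed = np.uint64(rng.integers(0, 2**63, dtype=np.int64))
    return _kernels.sample_haplotype_batch(seed, t0, t1, off, n_hap)
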