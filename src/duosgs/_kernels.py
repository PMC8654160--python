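"""Numba kernels for the gene-drop engine.

Layout conventions shared by all kernels:

* SNPs are flattened genome-wide; ``chrom_off`` (int64, len n_chrom+1) gives
  the half-open index range of each chromosome.
* ``t0[i]`` / ``t1[i]`` are the first-order haplotype-chain transition
  probabilities P(allele_i = 1 | allele_{i-1} = 0 / 1); at each chromosome
  start both equal the marginal alternate-allele frequency of the first SNP
  (so the chain restarts there without a special case).  For speed the
  kernels consume them as interleaved uint64 thresholds ``thr[2i + prev]``
  compared directly against raw 64-bit RNG output.
* ``cm[i]`` is the genetic position of SNP i on its chromosome.
* Individuals are indexed 0..n_ind-1 in parents-before-children order;
  ``father``/``mother`` are -1 for founders.  Haplotypes live in an
  int8 array of shape (2*n_ind, n_snps): rows 2i and 2i+1.

Randomness: an inline xoshiro256** generator seeded through splitmix64, so
replicates are reproducible from a single uint64 seed and fast enough for
millions of gene drops.  Founder chains advance lane-parallel (one RNG
stream per founder haplotype) to keep the CPU pipeline full.  Crossovers
are realised as a Poisson event process on the centimorgan scale
(exponential inter-event distances, haplotype source toggling at each
event), which reproduces the Haldane recombination fraction
r = 0.5(1 - exp(-2d/100)) between any two markers.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_U64 = np.uint64
_DNORM = 1.0 / 9007199254740992.0  # 2^-53
_LANE_MIX = _U64(0xD1342543DE82EF95)
_TRANSMIT_TAG = _U64(0x5851F42D4C957F2D)


def thresholds_from_transitions(t0: np.ndarray, t1: np.ndarray) -> np.ndarray:
    """Interleave chain transitions as uint64 comparison thresholds."""
    thr = np.empty(2 * len(t0), np.uint64)
    scale = float(2.0**64)
    thr[0::2] = np.minimum(t0 * scale, np.nextafter(scale, 0)).astype(np.uint64)
    thr[1::2] = np.minimum(t1 * scale, np.nextafter(scale, 0)).astype(np.uint64)
    return thr


@njit(inline="always", cache=True)
def _rotl(x, k):
    return _U64((x << k) | (x >> (_U64(64) - k)))


@njit(cache=True)
def rng_init(seed):
    """xoshiro256** state from a uint64 seed via splitmix64."""
    s = np.empty(4, np.uint64)
    z = _U64(seed)
    for i in range(4):
        z = _U64(z + _U64(0x9E3779B97F4A7C15))
        w = z
        w = _U64((w ^ (w >> _U64(30))) * _U64(0xBF58476D1CE4E5B9))
        w = _U64((w ^ (w >> _U64(27))) * _U64(0x94D049BB133111EB))
        s[i] = _U64(w ^ (w >> _U64(31)))
    if s[0] == 0 and s[1] == 0 and s[2] == 0 and s[3] == 0:
        s[0] = _U64(1)
    return s


@njit(inline="always", cache=True)
def rng_u64(s):
    result = _U64(_rotl(_U64(s[1] * _U64(5)), _U64(7)) * _U64(9))
    t = _U64(s[1] << _U64(17))
    s[2] ^= s[0]
    s[3] ^= s[1]
    s[1] ^= s[2]
    s[0] ^= s[3]
    s[2] ^= t
    s[3] = _rotl(s[3], _U64(45))
    return result


@njit(inline="always", cache=True)
def rng_double(s):
    """Uniform double in [0, 1)."""
    return float(rng_u64(s) >> _U64(11)) * _DNORM


@njit(inline="always", cache=True)
def _rng_u64_lane(S, l):
    # xoroshiro128+ per lane: cheap update, top bits drive the compare
    s0 = S[l, 0]
    s1 = S[l, 1]
    result = _U64(s0 + s1)
    s1 ^= s0
    S[l, 0] = _U64(_rotl(s0, _U64(24)) ^ s1 ^ _U64(s1 << _U64(16)))
    S[l, 1] = _rotl(s1, _U64(37))
    return result


@njit(cache=True)
def _lane_states(seed, n_lanes):
    S = np.empty((n_lanes, 2), np.uint64)
    for l in range(n_lanes):
        s = rng_init(_U64(_U64(seed) + _U64(l + 1) * _LANE_MIX))
        S[l, 0] = s[0]
        S[l, 1] = s[1]
    return S


@njit(cache=True)
def _sample_founder_lanes(thr, rows, states, prev, haps):
    """Advance every founder-haplotype chain one SNP at a time, lane-parallel.

    Chromosome restarts need no special case because thr[2i] == thr[2i+1]
    at chromosome-start SNPs (marginal frequency).
    """
    n_snps = haps.shape[1]
    n_lanes = rows.shape[0]
    for i in range(n_snps):
        base = 2 * i
        for l in range(n_lanes):
            u = _rng_u64_lane(states, l)
            pv = 1 if u < thr[base + prev[l]] else 0
            prev[l] = pv
            haps[rows[l], i] = np.int8(pv)


@njit(inline="always", cache=True)
def _transmit(haps, child_row, parent, lo, hi, cm, s):
    """Copy one recombinant gamete of ``parent`` over [lo, hi) into child_row."""
    h = 2 * parent + int(rng_u64(s) & _U64(1))
    other = 4 * parent + 1 - h
    # Poisson crossover process: events every Exp(mean 100 cM); between
    # events the gamete is a contiguous block copy of one parental haplotype
    event = cm[lo] - 100.0 * np.log(1.0 - rng_double(s))
    i = lo
    while i < hi:
        j = i
        while j < hi and cm[j] < event:
            j += 1
        for q in range(i, j):
            haps[child_row, q] = haps[h, q]
        i = j
        if i < hi:
            tmp = h
            h = other
            other = tmp
            event = event - 100.0 * np.log(1.0 - rng_double(s))


@njit(cache=True)
def drop_haplotypes(seed, father, mother, chrom_off, cm, thr, haps):
    """One gene-drop replicate: fill ``haps`` for every individual.

    ``haps`` must be int8 of shape (2*n_ind, n_snps); individuals must be
    ordered so parents precede children.
    """
    n_ind = father.shape[0]
    n_founder_rows = 0
    for ind in range(n_ind):
        if father[ind] < 0:
            n_founder_rows += 2
    rows = np.empty(n_founder_rows, np.int64)
    j = 0
    for ind in range(n_ind):
        if father[ind] < 0:
            rows[j] = 2 * ind
            rows[j + 1] = 2 * ind + 1
            j += 2
    states = _lane_states(_U64(seed), n_founder_rows)
    prev = np.zeros(n_founder_rows, np.int64)
    _sample_founder_lanes(thr, rows, states, prev, haps)
    s = rng_init(_U64(_U64(seed) ^ _TRANSMIT_TAG))
    n_chrom = chrom_off.shape[0] - 1
    for c in range(n_chrom):
        lo = chrom_off[c]
        hi = chrom_off[c + 1]
        for ind in range(n_ind):
            if father[ind] >= 0:
                _transmit(haps, 2 * ind, father[ind], lo, hi, cm, s)
                _transmit(haps, 2 * ind + 1, mother[ind], lo, hi, cm, s)
    return haps


@njit(cache=True)
def case_genotypes(haps, case_rows, out):
    """Genotypes (alt-allele counts) of the case individuals from haplotypes."""
    n_cases = case_rows.shape[0]
    n_snps = haps.shape[1]
    for j in range(n_cases):
        r = 2 * case_rows[j]
        for i in range(n_snps):
            out[j, i] = haps[r, i] + haps[r + 1, i]
    return out


@njit(cache=True)
def null_containment_counts(
    n_sims,
    seed,
    father,
    mother,
    case_rows,
    chrom_off,
    cm,
    thr,
    subset_bits,
    seg_off,
    seg_a,
    seg_len,
):
    """Count, per observed segment, null replicates whose sharing run for the
    segment's subset is identical to or encompasses the segment.

    A replicate encompasses segment [a, b] exactly when the subset's IBS
    sharing indicator is true at every SNP in [a, b]; a single backward
    sweep maintains the current forward run length of every subset and
    tests each segment when the sweep reaches its first SNP.

    ``subset_bits[k]`` is the case bitmask of subset k; segments are grouped
    by subset via CSR offsets ``seg_off`` and must be sorted by first SNP
    *descending* within each subset (``seg_a`` global first-SNP index,
    ``seg_len`` run length in SNPs).
    """
    n_ind = father.shape[0]
    n_snps = cm.shape[0]
    n_subsets = subset_bits.shape[0]
    n_cases = case_rows.shape[0]
    n_chrom = chrom_off.shape[0] - 1
    counts = np.zeros(seg_a.shape[0], np.int64)
    haps = np.empty((2 * n_ind, n_snps), np.int8)
    run = np.empty(n_subsets, np.int64)
    ptr = np.empty(n_subsets, np.int64)
    s = rng_init(_U64(seed))
    for _rep in range(n_sims):
        rep_seed = rng_u64(s)
        drop_haplotypes(rep_seed, father, mother, chrom_off, cm, thr, haps)
        for k in range(n_subsets):
            ptr[k] = seg_off[k]
        for c in range(n_chrom - 1, -1, -1):
            lo = chrom_off[c]
            hi = chrom_off[c + 1]
            for k in range(n_subsets):
                run[k] = 0
            for i in range(hi - 1, lo - 1, -1):
                m0 = 0
                m2 = 0
                for j in range(n_cases):
                    r = 2 * case_rows[j]
                    g = haps[r, i] + haps[r + 1, i]
                    m0 |= (1 if g == 0 else 0) << j
                    m2 |= (1 if g == 2 else 0) << j
                for k in range(n_subsets):
                    b = subset_bits[k]
                    shared = 1 if ((m0 & b) == 0 or (m2 & b) == 0) else 0
                    run[k] = (run[k] + 1) * shared
                    while ptr[k] < seg_off[k + 1] and seg_a[ptr[k]] == i:
                        if run[k] >= seg_len[ptr[k]]:
                            counts[ptr[k]] += 1
                        ptr[k] += 1
    return counts


@njit(cache=True)
def sample_chain(t0, t1, lo, hi, out, row, s):
    """Draw one founder haplotype over SNP range [lo, hi) from the chain."""
    prev = np.int8(1) if rng_double(s) < t0[lo] else np.int8(0)
    out[row, lo] = prev
    for i in range(lo + 1, hi):
        p = t1[i] if prev == 1 else t0[i]
        prev = np.int8(1) if rng_double(s) < p else np.int8(0)
        out[row, i] = prev
    return out


@njit(cache=True)
def sample_haplotype_batch(seed, t0, t1, chrom_off, n_hap):
    """Independent chain haplotypes (n_hap, n_snps) across all chromosomes."""
    n_snps = t0.shape[0]
    out = np.empty((n_hap, n_snps), np.int8)
    s = rng_init(_U64(seed))
    for h in range(n_hap):
        for c in range(chrom_off.shape[0] - 1):
            sample_chain(t0, t1, chrom_off[c], chrom_off[c + 1], out, h, s)
    return out
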