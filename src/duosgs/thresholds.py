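"""Genome-wide duo-SGS thresholds: perturbation, gamma fit, Large Deviations.

For each fixed pedigree the observed optimization is echoed in null data:
every pedigree's optimal profile is perturbed (each empirical p replaced by
a uniform draw from its Wilson score 95% interval, which keeps bounds
non-negative), the duo optimization is re-run on the perturbed profiles,
and the resulting null duo p-values are -log10-transformed and fitted to a
gamma distribution with shape k and rate sigma.  The Theory of Large
Deviations then converts the fitted tail into genome-wide thresholds by
solving

    mu(X) = [C + 2 G X] * alpha(X),

where alpha(X) is the upper tail of a chi-square with 2k degrees of
freedom, C the chromosome count, G the genome length in Morgans, and mu
the expected genome-wide false-positive rate (0.05 for significant, 1.0
for suggestive).  Since 2*sigma*(-log10 p) ~ chi-square(2k) under the
fitted gamma, the solved X back-transforms to the p-value threshold
T = 10^(-X / (2 sigma)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .duo import optimize_duo
from .ldmap import GeneticMap
from .sgs_core import OptimalProfile


def wilson_interval(phat, n: int, z: float = 1.96) -> tuple:
    """Wilson score confidence interval for a binomial proportion.

    Center (phat + z^2/2n) / (1 + z^2/n), half-width
    (z / (1 + z^2/n)) * sqrt(phat(1-phat)/n + z^2/4n^2); bounds clipped to
    [0, 1].  Vectorises over ``phat``.
    """
    phat = np.asarray(phat, float)
    if np.any(phat < 0) or np.any(phat > 1):
        raise ValueError("phat must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    z2n = z * z / n
    denom = 1.0 + z2n
    center = (phat + z2n / 2.0) / denom
    half = (z / denom) * np.sqrt(phat * (1.0 - phat) / n + z2n / (4.0 * n))
    lower = np.clip(center - half, 0.0, 1.0)
    upper = np.clip(center + half, 0.0, 1.0)
    if phat.ndim == 0:
        return float(lower), float(upper)
    return lower, upper


def perturb_profile(
    profile: OptimalProfile, n_sims: int, seed: int
) -> OptimalProfile:
    """Null version of a profile: each p drawn uniformly from its Wilson
    95% interval (deterministic under ``seed``), kept inside (0, 1]."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lower, upper = wilson_interval(profile.p, n_sims)
    draw = rng.uniform(lower, upper)
    tiny = np.finfo(float).tiny
    draw = np.clip(draw, tiny, 1.0)
    return OptimalProfile(
        pedigree_id=profile.pedigree_id,
        p=draw,
        seg_index=profile.seg_index.copy(),
        segments=list(profile.segments),
    )


def fit_gamma_neglog(null_ps: np.ndarray) -> tuple[float, float]:
    """Gamma MLE (shape k, rate sigma) for y = -log10(p), location fixed at 0.

    Values with p >= 1 carry no tail information; they are dropped and the
    count logged.  Exactly-uniform p-values give the exponential special
    case k = 1 with rate ln(10) ~ 2.3026 on the log10 scale.
    """
    ps = np.asarray(null_ps, float)
    if np.any(ps <= 0):
        raise ValueError("p-values must be positive")
    kept = ps[ps < 1.0]
    if kept.size < ps.size:
        logging.getLogger(__name__).info(
            "fit_gamma_neglog: dropped %d of %d values with p >= 1",
            ps.size - kept.size, ps.size,
        )
    if kept.size == 0:
        raise ValueError("all p-values >= 1; nothing to fit")
    y = -np.log10(kept)
    if np.ptp(y) == 0:
        raise ValueError("degenerate (constant) -log10 p; gamma MLE diverges")
    shape, _, scale = stats.gamma.fit(y, floc=0)
    return float(shape), float(1.0 / scale)


def solve_tld(
    k: float,
    sigma: float,
    mu_target: float,
    C: int,
    G: float,
    back_transform: str = "rate",
) -> tuple[float, float]:
    """Solve [C + 2 G X] * alpha(X) = mu_target for X and back-transform to T.

    alpha is the survival function of chi-square with 2k df.  The left-hand
    side is eventually strictly decreasing in X; the root beyond its
    maximum is located by a doubling bracket and Brent's method (relative
    tolerance 1e-10).  ``back_transform="rate"`` (default) treats sigma as
    the gamma rate, T = 10^(-X/(2 sigma)); "scale" gives the alternative
    reading T = 10^(-X sigma / 2).
    """
    if k <= 0 or sigma <= 0 or G <= 0:
        raise ValueError("k, sigma and G must be positive")
    if C < 1:
        raise ValueError("C must be >= 1")
    if mu_target <= 0:
        raise ValueError("mu_target must be positive")
    df = 2.0 * k

    def h(x: float) -> float:
        return (C + 2.0 * G * x) * stats.chi2.sf(x, df) - mu_target

    lo, hi = 1e-9, 1.0
    while h(hi) > 0:
        lo = hi
        hi *= 2.0
        if hi > 10_000.0:
            raise RuntimeError("no sign change while bracketing up to X = 10,000")
    x = optimize.brentq(h, lo, hi, rtol=1e-12, maxiter=200)
    if back_transform == "rate":
        t = 10.0 ** (-x / (2.0 * sigma))
    elif back_transform == "scale":
        t = 10.0 ** (-x * sigma / 2.0)
    else:
        raise ValueError("back_transform must be 'rate' or 'scale'")
    return float(x), float(t)


def expected_rate(k: float, sigma: float, C: int, G: float, p: float) -> float:
    """Genome-wide expected rate mu(t) of duo results as extreme as p."""
    x = -2.0 * sigma * np.log10(p)
    return float((C + 2.0 * G * x) * stats.chi2.sf(x, 2.0 * k))


@dataclass
class ThresholdFit:
    """Fitted null tail and genome-wide thresholds for one fixed pedigree."""

    fixed_id: str
    k: float
    sigma: float
    X_sig: float
    X_sugg: float
    T_sig: float
    T_sugg: float
    C: int
    G: float
    n_sims: int

    def __post_init__(self) -> None:
        if not (self.T_sig < self.T_sugg):
            raise ValueError("significant threshold must be below suggestive")

    def mu_of_p(self, p: float) -> float:
        return expected_rate(self.k, self.sigma, self.C, self.G, p)


def thresholds_for_pedigree(
    fixed_id: str,
    profiles: dict[str, OptimalProfile],
    n_sims: int,
    seed: int,
    gmap: GeneticMap,
    C: int | None = None,
    mu_sig: float = 0.05,
    mu_sugg: float = 1.0,
) -> ThresholdFit:
    """Echo the duo optimization in null data and derive thresholds.

    Every pedigree's profile is perturbed once (independent substreams per
    pedigree), the duo optimization re-run for the fixed pedigree, the null
    duo p-values gamma-fitted, and solve_tld applied at mu = 0.05
    (significant) and 1.0 (suggestive).  G comes from the genetic map; C
    defaults to the number of chromosomes in the map.
    """
    if C is None:
        C = len(gmap.chromosomes)
    G = gmap.total_morgans()
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(profiles))
    perturbed = {
        pid: perturb_profile(profiles[pid], n_sims, int(cs.generate_state(1)[0] % (2**31)))
        for pid, cs in zip(sorted(profiles), child_seeds)
    }
    null_duo = optimize_duo(fixed_id, perturbed)
    k, sigma = fit_gamma_neglog(null_duo.combined_p)
    X_sig, T_sig = solve_tld(k, sigma, mu_sig, C, G)
    X_sugg, T_sugg = solve_tld(k, sigma, mu_sugg, C, G)
    return ThresholdFit(
        fixed_id=fixed_id,
        k=k,
        sigma=sigma,
        X_sig=X_sig,
        X_sugg=X_sugg,
        T_sig=T_sig,
        T_sugg=T_sugg,
        C=C,
        G=G,
        n_sims=n_sims,
    )
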