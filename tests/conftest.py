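"""Shared fixtures: small synthetic datasets and hand-built pedigrees."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from duosgs.pedio import GenotypeMatrix, Pedigree, Person
from duosgs.synth import SynthConfig, simulate_dataset


def make_matrix(calls, chrom="1", bp_start=1000, bp_step=1000, sample_ids=None):
    """GenotypeMatrix from an (n_snps, n_samples) int array on one chromosome."""
    calls = np.asarray(calls, dtype=np.int8)
    n_snps, n_samples = calls.shape
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    snps = pd.DataFrame(
        {
            "chrom": [chrom] * n_snps,
            "snp_id": [f"m{i}" for i in range(n_snps)],
            "cm": np.arange(n_snps, dtype=float),
            "bp": bp_start + bp_step * np.arange(n_snps),
            "a1": "A",
            "a2": "B",
        }
    )
    return GenotypeMatrix(snps, list(sample_ids), calls)


def trio_pedigree(pedigree_id="T1"):
    persons = {
        "fa": Person("fa", None, None, sex=1),
        "mo": Person("mo", None, None, sex=2),
        "kid": Person("kid", "fa", "mo", sex=1, affected=True, sampled=True),
    }
    return Pedigree(pedigree_id, persons)


def sibs_pedigree():
    persons = {
        "fa": Person("fa", None, None, 1),
        "mo": Person("mo", None, None, 2),
        "s1": Person("s1", "fa", "mo", 1, affected=True, sampled=True),
        "s2": Person("s2", "fa", "mo", 2, affected=True, sampled=True),
    }
    return Pedigree("SIBS", persons, genotyped_cases=("s1", "s2"))


def cousins_pedigree():
    persons = {
        "gf": Person("gf", None, None, 1),
        "gm": Person("gm", None, None, 2),
        "p1": Person("p1", "gf", "gm", 1),
        "p2": Person("p2", "gf", "gm", 2),
        "sp1": Person("sp1", None, None, 2),
        "sp2": Person("sp2", None, None, 1),
        "c1": Person("c1", "p1", "sp1", 1, affected=True, sampled=True),
        "c2": Person("c2", "sp2", "p2", 2, affected=True, sampled=True),
    }
    return Pedigree("COUS", persons, genotyped_cases=("c1", "c2"))


TINY = dict(n_chromosomes=2, n_snps_per_chrom=300, chrom_length_cm=120.0,
            chrom_length_bp=30_000_000)


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 chromosomes x 300 SNPs, 4 cases; session-scoped for reuse."""
    return simulate_dataset(SynthConfig(pedigree_id="TINY", seed=42, **TINY))


@pytest.fixture(scope="session")
def tiny_pair():
    """Two independent tiny pedigrees on the same SNP grid."""
    a = simulate_dataset(SynthConfig(pedigree_id="PA", seed=7, **TINY))
    b = simulate_dataset(SynthConfig(pedigree_id="PB", seed=8, **TINY))
    return a, b
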