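"""Pedigree structures, PED/MAP genotype I/O, and array-QC filtering.

File dialects
-------------
Pedigree file: whitespace-delimited LINKAGE-extended rows with columns
``family  id  father  mother  sex  affection  sampled``.  ``0`` in the
father/mother columns means "no parent in the pedigree"; affection is coded
1 (unaffected) / 2 (affected); sampled is 0/1.  Genotyped cases are the
individuals that are both affected and sampled.

Genotypes: PLINK-style text PED/MAP.  The MAP file has columns
``chromosome  snp_id  cM  bp``; the PED file has the six standard leading
columns followed by two allele characters per SNP, ``0`` meaning missing.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = np.int8(-1)
"""Internal sentinel for a missing genotype call."""


class PedigreeError(ValueError):
    """Structural problem in a pedigree definition."""


@dataclass(frozen=True)
class Person:
    id: str
    father: str | None
    mother: str | None
    sex: int = 0
    affected: bool = False
    sampled: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class Pedigree:
    """A validated directed ancestry graph.

    Every non-founder has exactly two parents present in the pedigree;
    founders have none.  ``genotyped_cases`` is the affected-and-sampled
    subset actually analysed (typically 2-4 cases per pedigree).
    """

    pedigree_id: str
    persons: dict[str, Person]
    genotyped_cases: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        for p in self.persons.values():
            if (p.father is None) != (p.mother is None):
                raise PedigreeError(
                    f"{self.pedigree_id}/{p.id}: exactly one parent listed; "
                    "individuals must have two parents or none"
                )
            for parent in (p.father, p.mother):
                if parent is not None and parent not in self.persons:
                    raise PedigreeError(
                        f"{self.pedigree_id}/{p.id}: parent {parent!r} not defined"
                    )
        self.topological_order()  # raises on cycles
        missing = set(self.genotyped_cases) - set(self.persons)
        if missing:
            raise PedigreeError(f"genotyped cases not in pedigree: {sorted(missing)}")
        self.genotyped_cases = tuple(sorted(self.genotyped_cases))

    @property
    def founders(self) -> list[str]:
        return [p.id for p in self.persons.values() if p.is_founder]

    @property
    def non_founders(self) -> list[str]:
        return [p.id for p in self.persons.values() if not p.is_founder]

    def topological_order(self) -> list[str]:
        """Individual ids ordered parents-before-children (cycle check)."""
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(pid: str, stack: list[str]) -> None:
            st = state.get(pid, 0)
            if st == 1:
                raise PedigreeError(
                    f"{self.pedigree_id}: ancestry cycle through {pid!r}"
                )
            if st == 2:
                return
            state[pid] = 1
            person = self.persons[pid]
            for parent in (person.father, person.mother):
                if parent is not None:
                    visit(parent, stack + [pid])
            state[pid] = 2
            order.append(pid)

        for pid in self.persons:
            visit(pid, [])
        return order


def read_pedigrees(path: str | Path) -> dict[str, Pedigree]:
    """Read every family in a LINKAGE-extended pedigree file."""
    rows: dict[str, dict[str, Person]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 7:
                raise PedigreeError(f"{path}:{ln}: expected 7 columns, got {len(fields)}")
            fam, pid, fa, mo, sex, aff, samp = fields[:7]
            rows.setdefault(fam, {})[pid] = Person(
                id=pid,
                father=None if fa == "0" else fa,
                mother=None if mo == "0" else mo,
                sex=int(sex),
                affected=aff == "2",
                sampled=samp not in ("0", "-9"),
            )
    out = {}
    for fam, persons in rows.items():
        cases = tuple(p.id for p in persons.values() if p.affected and p.sampled)
        out[fam] = Pedigree(pedigree_id=fam, persons=persons, genotyped_cases=cases)
    return out


def read_pedigree(path: str | Path, pedigree_id: str | None = None) -> Pedigree:
    """Read a single pedigree; ``pedigree_id`` selects among multiple families."""
    peds = read_pedigrees(path)
    if not peds:
        raise PedigreeError(f"{path}: no pedigree rows")
    if pedigree_id is not None:
        try:
            return peds[pedigree_id]
        except KeyError:
            raise PedigreeError(f"{path}: no family {pedigree_id!r}") from None
    if len(peds) > 1:
        raise PedigreeError(
            f"{path}: multiple families {sorted(peds)}; pass pedigree_id"
        )
    return next(iter(peds.values()))


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pedigree.persons.values():
            fh.write(
                f"{pedigree.pedigree_id}\t{p.id}\t{p.father or 0}\t{p.mother or 0}"
                f"\t{p.sex}\t{2 if p.affected else 1}\t{1 if p.sampled else 0}\n"
            )


# ---------------------------------------------------------------------------
# Genotypes


@dataclass
class GenotypeMatrix:
    """Biallelic SNP calls for sampled individuals.

    ``snps`` columns: chrom, snp_id, cm, bp, a1, a2 (a2 is the counted
    allele).  ``calls`` is int8 of shape (n_snps, n_samples) holding alt
    allele counts 0/1/2 with -1 for missing; SNPs are strictly sorted by
    (chromosome, bp).
    """

    snps: pd.DataFrame
    sample_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.snps), len(self.sample_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.snps)}, {len(self.sample_ids)})"
            )
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.snps = self.snps.reset_index(drop=True)
        for chrom, start, stop in self.chrom_slices():
            bp = self.snps["bp"].to_numpy()[start:stop]
            if not np.all(np.diff(bp) > 0):
                raise ValueError(f"chromosome {chrom}: bp not strictly increasing")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def chrom_slices(self) -> list[tuple[str, int, int]]:
        """(chromosome, start index, stop index) per contiguous chromosome block."""
        chroms = self.snps["chrom"].to_numpy()
        out = []
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out.append((chroms[start], start, i))
                start = i
        if len({c for c, _, _ in out}) != len(out):
            raise ValueError("chromosome blocks are not contiguous")
        return out

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in genotype matrix") from None

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(i) for i in ids]
        return GenotypeMatrix(self.snps.copy(), list(ids), self.calls[:, idx].copy())


def _chrom_sort_key(labels: list[str]):
    if all(lbl.isdigit() for lbl in labels):
        return {lbl: int(lbl) for lbl in labels}
    return {lbl: i for i, lbl in enumerate(dict.fromkeys(labels))}


def read_map(path: str | Path) -> pd.DataFrame:
    mp = pd.read_csv(
        path, sep=r"\s+", header=None, names=["chrom", "snp_id", "cm", "bp"],
        dtype={"chrom": str, "snp_id": str, "cm": float, "bp": int},
    )
    key = _chrom_sort_key(list(mp["chrom"]))
    mp["_ck"] = mp["chrom"].map(key)
    mp = mp.sort_values(["_ck", "bp"], kind="stable").drop(columns="_ck")
    return mp.reset_index(drop=True)


def read_genotypes(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read a PLINK-style text PED/MAP pair into a GenotypeMatrix.

    Allele labels per SNP are taken from the data (at most two non-zero
    labels; the lexicographically larger one is counted as a2).  SNPs are
    returned sorted by (chromosome, bp) regardless of map row order.
    """
    raw = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["chrom", "snp_id", "cm", "bp"],
        dtype={"chrom": str, "snp_id": str, "cm": float, "bp": int},
    )
    n_snps = len(raw)
    sample_ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_snps} columns "
                    f"for {n_snps} SNPs, got {len(fields)}"
                )
            sample_ids.append(fields[1])
            allele_rows.append(np.array(fields[6:], dtype="U8"))
    if not sample_ids:
        raise ValueError(f"{ped_path}: no individuals")
    alleles = np.stack(allele_rows)          # (n_ind, 2*n_snps), raw map order
    a_first = alleles[:, 0::2]
    a_second = alleles[:, 1::2]
    a1_lbl = np.empty(n_snps, dtype=object)
    a2_lbl = np.empty(n_snps, dtype=object)
    calls = np.empty((n_snps, len(sample_ids)), dtype=np.int8)
    for j in range(n_snps):
        f, s = a_first[:, j], a_second[:, j]
        labels = sorted(set(f) | set(s) - {"0"})
        labels = [x for x in labels if x != "0"]
        if len(labels) > 2:
            raise ValueError(
                f"SNP {raw['snp_id'].iloc[j]!r}: more than two alleles {labels}"
            )
        a1 = labels[0] if labels else "A"
        a2 = labels[1] if len(labels) > 1 else None
        a1_lbl[j], a2_lbl[j] = a1, (a2 if a2 is not None else a1)
        if np.any((f == "0") != (s == "0")):
            raise ValueError(f"SNP {raw['snp_id'].iloc[j]!r}: half-missing genotype")
        cnt = np.zeros(len(sample_ids), dtype=np.int8)
        if a2 is not None:
            cnt = (f == a2).astype(np.int8) + (s == a2).astype(np.int8)
        cnt[(f == "0") | (s == "0")] = MISSING
        calls[j] = cnt
    snps = raw.assign(a1=a1_lbl, a2=a2_lbl)
    key = _chrom_sort_key(list(snps["chrom"]))
    order = np.lexsort((snps["bp"].to_numpy(), snps["chrom"].map(key).to_numpy()))
    return GenotypeMatrix(
        snps.iloc[order].reset_index(drop=True), sample_ids, calls[order]
    )


def write_genotypes(
    gm: GenotypeMatrix,
    ped_path: str | Path,
    map_path: str | Path,
    pedigree: Pedigree | None = None,
) -> None:
    """Write a GenotypeMatrix as a PED/MAP pair (round-trips with read_genotypes)."""
    snps = gm.snps
    with open(map_path, "w") as fh:
        for r in snps.itertuples():
            fh.write(f"{r.chrom}\t{r.snp_id}\t{r.cm:g}\t{r.bp}\n")
    a1 = snps["a1"].to_numpy()
    a2 = snps["a2"].to_numpy()
    with open(ped_path, "w") as fh:
        for k, sid in enumerate(gm.sample_ids):
            fam, fa, mo, sex, pheno = "0", "0", "0", "0", "-9"
            if pedigree is not None and sid in pedigree.persons:
                p = pedigree.persons[sid]
                fam = pedigree.pedigree_id
                fa, mo = p.father or "0", p.mother or "0"
                sex = str(p.sex)
                pheno = "2" if p.affected else "1"
            col = gm.calls[:, k]
            pair = np.where(
                col[:, None] == MISSING,
                np.array(["0", "0"], dtype=object),
                np.stack(
                    [np.where(col >= 1, a2, a1), np.where(col == 2, a2, a1)], axis=1
                ),
            )
            fh.write(
                "\t".join([fam, sid, fa, mo, sex, pheno] + list(pair.ravel())) + "\n"
            )


def qc_filter(
    gm: GenotypeMatrix,
    snp_call_rate_min: float = 0.95,
    individual_call_rate_min: float = 0.90,
) -> GenotypeMatrix:
    """Array QC: drop low-call-rate SNPs, then low-call-rate individuals.

    SNPs with call rate below ``snp_call_rate_min`` across all individuals
    are removed first; individuals called at fewer than
    ``individual_call_rate_min`` of the *surviving* SNPs are removed second.
    The two-pass order is fixed.
    """
    if not (0 <= snp_call_rate_min <= 1 and 0 <= individual_call_rate_min <= 1):
        raise ValueError("call-rate thresholds must be in [0, 1]")
    called = gm.calls != MISSING
    snp_rate = called.mean(axis=1)
    keep_snps = snp_rate >= snp_call_rate_min
    if not keep_snps.any():
        raise ValueError("QC removed every SNP; input unusable")
    calls = gm.calls[keep_snps]
    ind_rate = (calls != MISSING).mean(axis=0)
    keep_ind = ind_rate >= individual_call_rate_min
    if not keep_ind.any():
        raise ValueError("QC removed every individual; input unusable")
    return GenotypeMatrix(
        gm.snps.loc[keep_snps].reset_index(drop=True),
        [s for s, k in zip(gm.sample_ids, keep_ind) if k],
        calls[:, keep_ind].copy(),
    )


# ---------------------------------------------------------------------------
# Meiosis counting


def _couple_graph(pedigree: Pedigree) -> dict[object, dict[object, int]]:
    # Nodes: individual ids and ("couple", father, mother) tuples.
    # child--couple edges cost 1 (one meiosis); parent--couple edges cost 0.
    adj: dict[object, dict[object, int]] = {}

    def add(u, v, w):
        adj.setdefault(u, {})
        adj.setdefault(v, {})
        if w < adj[u].get(v, np.inf):
            adj[u][v] = w
            adj[v][u] = w

    for p in pedigree.persons.values():
        if p.father is not None:
            couple = ("couple", p.father, p.mother)
            add(p.id, couple, 1)
            add(p.father, couple, 0)
            add(p.mother, couple, 0)
    for pid in pedigree.persons:
        adj.setdefault(pid, {})
    return adj


def _dijkstra(adj, sources: dict) -> dict:
    dist = dict(sources)
    pq = [(d, id(u), u) for u, d in sources.items()]
    heapq.heapify(pq)
    while pq:
        d, _, u = heapq.heappop(pq)
        if d > dist.get(u, np.inf):
            continue
        for v, w in adj[u].items():
            nd = d + w
            if nd < dist.get(v, np.inf):
                dist[v] = nd
                heapq.heappush(pq, (nd, id(v), v))
    return dist


def count_meioses(pedigree: Pedigree, case_ids: set[str] | None = None) -> int:
    """Meioses separating a case set: edge count of the minimal connecting
    subpedigree (exact Steiner tree, couples contracted to single nodes).

    Two full siblings are separated by 2 meioses; first cousins by 4.  With
    more than two cases the minimal subtree joining all of them through
    their common ancestors is counted, matching how linkage studies report
    "N meioses between cases".
    """
    if case_ids is None:
        case_ids = set(pedigree.genotyped_cases)
    terms = sorted(case_ids)
    if not terms:
        raise ValueError("no cases given")
    for t in terms:
        if t not in pedigree.persons:
            raise PedigreeError(f"case {t!r} not in pedigree {pedigree.pedigree_id}")
    if len(terms) == 1:
        return 0
    adj = _couple_graph(pedigree)
    # Dreyfus-Wagner DP: dp[S][v] = min cost of a tree spanning S ∪ {v}
    full = (1 << len(terms)) - 1
    dp: dict[int, dict] = {}
    for i, t in enumerate(terms):
        dp[1 << i] = _dijkstra(adj, {t: 0})
    for size in range(2, len(terms) + 1):
        for combo in itertools.combinations(range(len(terms)), size):
            S = sum(1 << i for i in combo)
            base: dict = {}
            sub = S
            seen = set()
            T = (S - 1) & S
            while T:
                U = S & ~T
                if T not in seen and U and T in dp and U in dp:
                    seen.add(T)
                    for v in adj:
                        c = dp[T].get(v, np.inf) + dp[U].get(v, np.inf)
                        if c < base.get(v, np.inf):
                            base[v] = c
                T = (T - 1) & S
            finite = {v: c for v, c in base.items() if np.isfinite(c)}
            dp[S] = _dijkstra(adj, finite) if finite else {}
    best = min((dp[full].get(t, np.inf) for t in terms), default=np.inf)
    if not np.isfinite(best):
        raise PedigreeError(
            f"cases {terms} are not connected within pedigree {pedigree.pedigree_id}"
        )
    return int(best)
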