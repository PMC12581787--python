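"""Minimal discriminating SNP sets for variety fingerprinting.

Given genotyped candidates, each SNP "distinguishes" an unordered sample
pair when the two samples carry unequal, non-missing genotype codes (a
heterozygote counts as its own class). Selecting the fewest SNPs that
distinguish every pair is a set-cover problem; the package uses the greedy
heuristic, with exhaustive search available as an exact oracle on small
candidate sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, FeatureTable, GenomeSequence, GenotypeMatrix, VariantTable
from .panel import flank_qc


@dataclass
class DiscriminationIndex:
    """For each candidate SNP, the set of unordered sample pairs (i, j),
    i < j, that it distinguishes."""

    pair_sets: list[frozenset[tuple[int, int]]]
    n_samples: int
    snp_ids: list[str] = field(default_factory=list)

    @property
    def all_pairs(self) -> frozenset[tuple[int, int]]:
        return frozenset(itertools.combinations(range(self.n_samples), 2))

    @property
    def coverable_pairs(self) -> frozenset[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for s in self.pair_sets:
            out |= s
        return frozenset(out)


@dataclass
class CoreSet:
    """An ordered selection of SNPs with its residual undistinguished pairs."""

    selected: list[int]               # indices into the candidate list
    residual: frozenset[tuple[int, int]]
    coverage: float                   # fraction of all pairs distinguished
    snp_ids: list[str] = field(default_factory=list)


def discrimination_matrix(G: GenotypeMatrix) -> DiscriminationIndex:
    """Exact per-SNP sets of sample pairs with unequal non-missing codes."""
    if G.n_samples < 2:
        raise ValueError("need at least 2 samples")
    g = G.matrix
    pair_sets = []
    pairs = list(itertools.combinations(range(G.n_samples), 2))
    for m in range(G.n_snps):
        col = g[:, m]
        s = frozenset(
            (i, j) for i, j in pairs
            if col[i] != MISSING and col[j] != MISSING and col[i] != col[j]
        )
        pair_sets.append(s)
    return DiscriminationIndex(pair_sets, G.n_samples, list(G.snp_ids))


def greedy_core_set(index: DiscriminationIndex,
                    max_snps: int | None = None) -> CoreSet:
    """Greedy set cover: repeatedly take the SNP distinguishing the most
    still-undistinguished pairs (tie: lower candidate index, i.e. locus
    order). Stops at full coverage, at ``max_snps``, or when no candidate
    adds a pair. Deterministic; never selects a zero-gain SNP."""
    if not index.pair_sets:
        raise ValueError("empty discrimination index")
    residual = set(index.all_pairs)
    selected: list[int] = []
    remaining = set(range(len(index.pair_sets)))
    while residual and remaining and (max_snps is None or len(selected) < max_snps):
        best, best_gain = None, 0
        for m in sorted(remaining):
            gain = len(index.pair_sets[m] & residual)
            if gain > best_gain:
                best, best_gain = m, gain
        if best is None:
            break
        selected.append(best)
        remaining.discard(best)
        residual -= index.pair_sets[best]
    n_all = len(index.all_pairs)
    coverage = 1.0 - len(residual) / n_all if n_all else 1.0
    ids = [index.snp_ids[i] for i in selected] if index.snp_ids else []
    return CoreSet(selected, frozenset(residual), coverage, ids)


def exhaustive_core_set(index: DiscriminationIndex,
                        max_candidates: int = 20) -> CoreSet:
    """Exact minimum set cover by subset enumeration; only feasible for
    small candidate sets (refuses more than ``max_candidates``)."""
    m = len(index.pair_sets)
    if m > max_candidates:
        raise ValueError(f"exhaustive search limited to {max_candidates} candidates")
    target = index.coverable_pairs
    n_all = len(index.all_pairs)
    for size in range(1, m + 1):
        for combo in itertools.combinations(range(m), size):
            covered: set[tuple[int, int]] = set()
            for i in combo:
                covered |= index.pair_sets[i]
            if covered >= target:
                residual = index.all_pairs - covered
                ids = [index.snp_ids[i] for i in combo] if index.snp_ids else []
                return CoreSet(list(combo), frozenset(residual),
                               1.0 - len(residual) / n_all if n_all else 1.0, ids)
    return CoreSet([], index.all_pairs, 0.0, [])


def kasp_candidate_filter(
    vt: VariantTable, features: FeatureTable, genome: GenomeSequence,
    min_maf: float = 0.15, flank: int = 100,
    gc_min: float = 0.4, gc_max: float = 0.6,
) -> np.ndarray:
    """Indices of SNPs suitable for allele-specific (KASP-style) assays:
    no missing calls, MAF >= ``min_maf``, exonic location, and flank QC pass
    (a proxy for primer designability)."""
    keep = []
    missing = vt.missing_rate()
    maf = vt.maf()
    for i in range(vt.n_records):
        if missing[i] > 0 or not maf[i] >= min_maf:
            continue
        genes = features.genes_at(str(vt.chrom[i]), int(vt.pos[i]))
        if not any(g.in_exon(int(vt.pos[i])) for g in genes):
            continue
        try:
            _, ok = flank_qc(str(vt.chrom[i]), int(vt.pos[i]), genome,
                             flank=flank, gc_min=gc_min, gc_max=gc_max)
        except IndexError:
            ok = False
        if ok:
            keep.append(i)
    return np.array(keep, dtype=int)


def fingerprint_table(G: GenotypeMatrix, core: CoreSet) -> "pd.DataFrame":
    """Samples x core-SNPs genotype table with 0/0, 0/1, 1/1 (./.) strings."""
    import pandas as pd

    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    cols = {}
    for rank, idx in enumerate(core.selected):
        name = core.snp_ids[rank] if core.snp_ids else G.snp_ids[idx]
        cols[name] = [code[int(v)] for v in G.matrix[:, idx]]
    return pd.DataFrame(cols, index=G.sample_ids)
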