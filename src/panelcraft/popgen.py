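"""Population characterization: p-distances, neighbor-joining trees, PCA,
nucleotide diversity and Weir–Cockerham F_ST from genotype codes.

Missing-data policy: distances and diversity use pairwise-complete
observations; PCA mean-imputes columns (and only PCA imputes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    """Symmetric n x n p-distance matrix with zero diagonal, values in [0,1]."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or not np.allclose(v, v.T):
            raise ValueError("distance matrix must be square and symmetric")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)


def p_distance(G: GenotypeMatrix) -> DistanceMatrix:
    """Mean per-site allele-sharing dissimilarity over co-observed sites:
    d(i,j) = sum_sites |g_i - g_j| / (2 * n_co-observed). A pair with zero
    co-observed sites is an error."""
    if G.n_samples < 2:
        raise ValueError("need at least 2 samples")
    g = G.matrix.astype(float)
    obs = G.matrix != MISSING
    g[~obs] = 0.0
    n = G.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            L = int(both.sum())
            if L == 0:
                raise ValueError(
                    f"samples {G.sample_ids[i]} and {G.sample_ids[j]} share no "
                    "co-observed sites"
                )
            d[i, j] = d[j, i] = np.abs(g[i, both] - g[j, both]).sum() / (2.0 * L)
    return DistanceMatrix(d, list(G.sample_ids))


def nj_tree(D: DistanceMatrix):
    """Neighbor-joining (Saitou–Nei) tree from a distance matrix, as a
    scikit-bio ``TreeNode``. Negative branch lengths are clamped to zero."""
    import skbio
    from skbio.tree import nj

    if len(D.sample_ids) < 3:
        raise ValueError("neighbor-joining needs >= 3 taxa")
    dm = skbio.DistanceMatrix(D.values, ids=[str(s) for s in D.sample_ids])
    return nj(dm, neg_as_zero=True)


def bootstrap_support(G: GenotypeMatrix, n_replicates: int = 100,
                      seed: int = 0) -> dict[frozenset, float]:
    """Clade support by site resampling: fraction of replicate NJ trees
    containing each bipartition (keyed by the smaller taxon set) of the
    full-data tree."""
    rng = np.random.default_rng(seed)
    base = nj_tree(p_distance(G))
    taxa = frozenset(t.name for t in base.tips())

    def bipartitions(tree) -> set[frozenset]:
        out = set()
        for node in tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            other = taxa - side
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out

    base_parts = bipartitions(base)
    counts = {p: 0 for p in base_parts}
    for _ in range(n_replicates):
        cols = rng.integers(0, G.n_snps, size=G.n_snps)
        rep = nj_tree(p_distance(G.subset_snps(cols)))
        rep_parts = bipartitions(rep)
        for p in base_parts:
            if p in rep_parts:
                counts[p] += 1
    return {p: c / n_replicates for p, c in counts.items()}


def pca_genotypes(G: GenotypeMatrix, n_components: int = 3
                  ) -> tuple[np.ndarray, np.ndarray]:
    """PCA of centered, mean-imputed genotype columns.

    Returns (coordinates, explained_variance) with components ordered by
    decreasing eigenvalue. Sign convention: the largest-|loading| entry of
    each component's SNP-loading vector is positive. Columns with no
    observed calls are an error.
    """
    if n_components >= min(G.n_samples, G.n_snps):
        raise ValueError("n_components must be < min(n_samples, n_snps)")
    if (G.matrix == MISSING).all(axis=0).any():
        raise ValueError("all-missing genotype column")
    X = G.mean_imputed()
    X = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    coords = U[:, :n_components] * s[:n_components]
    expl = (s[:n_components] ** 2) / (G.n_samples - 1)
    for k in range(n_components):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            coords[:, k] *= -1
    return coords, expl


def _allele_stats(col: np.ndarray) -> tuple[float, int]:
    """(alt-allele frequency, number of observed alleles) for one SNP column."""
    obs = col != MISSING
    n_al = 2 * int(obs.sum())
    if n_al == 0:
        return np.nan, 0
    return float(col[obs].sum()) / n_al, n_al


def nucleotide_diversity(G: GenotypeMatrix, labels: np.ndarray) -> pd.Series:
    """Per-group nucleotide diversity over the genotyped sites: the average
    over sites of the unbiased expected heterozygosity 2*p*q*n/(n-1), where n
    is the number of observed alleles in the group at that site."""
    labels = np.asarray(labels)
    out = {}
    for grp in pd.unique(labels):
        members = np.nonzero(labels == grp)[0]
        if len(members) < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 samples")
        pis = []
        for m in range(G.n_snps):
            p, n_al = _allele_stats(G.matrix[members, m])
            if n_al < 2:
                continue
            pis.append(2.0 * p * (1.0 - p) * n_al / (n_al - 1))
        out[grp] = float(np.mean(pis)) if pis else 0.0
    return pd.Series(out, name="pi")


def _wc_components(col_a: np.ndarray, col_b: np.ndarray) -> tuple[float, float, float]:
    """Weir–Cockerham (1984) per-site variance components a, b, c for two
    populations, from diploid genotype codes (observed heterozygosity used)."""
    pops = [col_a[col_a != MISSING], col_b[col_b != MISSING]]
    n_i = np.array([len(p) for p in pops], dtype=float)  # individuals
    if (n_i < 1).any():
        return 0.0, 0.0, 0.0
    p_i = np.array([p.sum() / (2 * len(p)) for p in pops])
    h_i = np.array([(p == 1).mean() for p in pops])  # observed het freq
    r = 2.0
    n_bar = n_i.mean()
    if n_bar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * n_bar - (n_i ** 2).sum() / (r * n_bar)) / (r - 1.0)
    p_bar = (n_i * p_i).sum() / (r * n_bar)
    s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1.0) * n_bar)
    h_bar = (n_i * h_i).sum() / (r * n_bar)
    a = (n_bar / nc) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    return a, b, c


def fst_weir_cockerham(G: GenotypeMatrix, labels: np.ndarray) -> pd.DataFrame:
    """Pairwise Weir–Cockerham F_ST between groups, ratio-of-sums over sites
    (sum of a-components over sum of a+b+c). Pairs monomorphic at every site
    are reported as NaN; small negative estimates are reported as-is."""
    labels = np.asarray(labels)
    groups = list(pd.unique(labels))
    for grp in groups:
        if (labels == grp).sum() < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 samples")
    out = pd.DataFrame(np.nan, index=groups, columns=groups, dtype=float)
    for gi in range(len(groups)):
        out.iloc[gi, gi] = 0.0
        for gj in range(gi + 1, len(groups)):
            ia = np.nonzero(labels == groups[gi])[0]
            ib = np.nonzero(labels == groups[gj])[0]
            num = den = 0.0
            for m in range(G.n_snps):
                a, b, c = _wc_components(G.matrix[ia, m], G.matrix[ib, m])
                num += a
                den += a + b + c
            fst = num / den if den > 0 else np.nan
            out.iloc[gi, gj] = out.iloc[gj, gi] = fst
    return out


def kmeans_groups(coords: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Convenience grouping of samples by k-means on PCA coordinates (for
    users without an assignment table)."""
    from scipy.cluster.vq import kmeans2

    _, labels = kmeans2(coords.astype(float), k, seed=seed, minit="++")
    return labels
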