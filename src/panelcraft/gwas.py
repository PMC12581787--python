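"""Single-marker mixed-linear-model association scans (EMMAX-style).

The model is y = X b + u + e with u ~ N(0, sigma_g^2 K) and
e ~ N(0, sigma_e^2 I), where K is a simple-matching-coefficient kinship.
Variance components are estimated once by REML under the null (spectral
decomposition of K + one-dimensional optimization over the variance ratio),
then each SNP is tested by generalized least squares with the variance
fixed — the EMMAX approximation. Per-SNP tests are Wald tests.

Also here: the effective-test significance threshold (-log10(1/N) with N
from LD pruning), single-SNP genotype-group trait tests, and pairwise LD
(EM haplotype frequencies -> D, D', r^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import MISSING, GenotypeMatrix
from .panel import ld_prune
from .popgen import pca_genotypes


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


@dataclass
class KinshipMatrix:
    """n x n simple-matching similarity; symmetric, unit diagonal, in [0,1]."""

    values: np.ndarray
    sample_ids: list[str]


def smc_kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """Simple-matching-coefficient kinship: over co-observed sites the pair
    scores 1 for equal codes, 0.5 for codes differing by one allele, 0 for
    opposite homozygotes; K(i,j) is the mean score."""
    if G.n_samples < 2:
        raise ValueError("need at least 2 samples")
    g = G.matrix.astype(float)
    obs = G.matrix != MISSING
    n = G.n_samples
    K = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            L = int(both.sum())
            if L == 0:
                raise ValueError(
                    f"samples {G.sample_ids[i]} and {G.sample_ids[j]} share no "
                    "co-observed sites"
                )
            score = 1.0 - np.abs(g[i, both] - g[j, both]) / 2.0
            K[i, j] = K[j, i] = score.mean()
    return KinshipMatrix(K, list(G.sample_ids))


# ---------------------------------------------------------------------------
# REML under the null
# ---------------------------------------------------------------------------


@dataclass
class NullModelFit:
    sigma_g2: float
    sigma_e2: float
    delta: float           # sigma_e2 / sigma_g2
    loglik: float          # restricted log-likelihood at the optimum
    beta: np.ndarray       # GLS fixed-effect estimates under the null
    eigenvalues: np.ndarray = field(repr=False, default=None)
    eigenvectors: np.ndarray = field(repr=False, default=None)

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


def reml_null(y: np.ndarray, X: np.ndarray, K: np.ndarray,
              ridge: float = 1e-8, tol: float = 1e-10) -> NullModelFit:
    """REML variance components of y = Xb + u + e, Var(u) = sigma_g^2 K.

    Works in the rotated basis of K's eigendecomposition; the restricted
    likelihood is maximized over log lambda (lambda = sigma_g^2/sigma_e^2)
    by grid + Brent refinement, giving delta reproducible to ~1e-6.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("covariate matrix X is rank deficient")
    K = np.asarray(K, dtype=float)
    K = (K + K.T) / 2 + ridge * np.eye(n)
    w, U = np.linalg.eigh(K)
    if w.min() < -1e-6:
        raise ValueError("kinship matrix is not positive semidefinite")
    w = np.clip(w, 0.0, None)
    yr = U.T @ y
    Xr = U.T @ X

    def neg_restricted_ll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        d = lam * w + 1.0          # Var = sigma_e^2 (lam K + I)
        Xd = Xr / d[:, None]
        XtVX = Xr.T @ Xd
        try:
            beta = np.linalg.solve(XtVX, Xd.T @ yr)
        except np.linalg.LinAlgError:
            return np.inf
        r = yr - Xr @ beta
        rss = float(r @ (r / d))
        if rss <= 0:
            return np.inf
        sigma_e2 = rss / (n - p)
        ll = -0.5 * (
            (n - p) * np.log(2 * np.pi * sigma_e2)
            + np.log(d).sum()
            + np.linalg.slogdet(XtVX)[1]
            - np.linalg.slogdet(X.T @ X)[1]
            + (n - p)
        )
        return -ll

    grid = np.linspace(-12.0, 12.0, 49)
    vals = np.array([neg_restricted_ll(g) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(lo, hi),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    log_lam = float(res.x)
    lam = np.exp(log_lam)
    d = lam * w + 1.0
    Xd = Xr / d[:, None]
    XtVX = Xr.T @ Xd
    beta = np.linalg.solve(XtVX, Xd.T @ yr)
    r = yr - Xr @ beta
    sigma_e2 = float(r @ (r / d)) / (n - p)
    sigma_g2 = lam * sigma_e2
    # boundary handling: effectively no genetic variance
    if log_lam <= grid[0] + 1e-9:
        sigma_g2 = lam * sigma_e2  # tiny by construction
    delta = sigma_e2 / sigma_g2 if sigma_g2 > 0 else np.inf
    return NullModelFit(sigma_g2, sigma_e2, delta, -float(res.fun), beta,
                        eigenvalues=w, eigenvectors=U)


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------


@dataclass
class GWASResults:
    """Per-SNP association results plus the null model they condition on."""

    table: pd.DataFrame
    null_fit: NullModelFit
    threshold: float | None = None

    def significant(self, threshold: float | None = None) -> pd.DataFrame:
        t = threshold if threshold is not None else self.threshold
        if t is None:
            raise ValueError("no significance threshold set")
        return self.table[self.table["minus_log10_p"] >= t]

    def lambda_gc(self) -> float:
        """Genomic-control inflation factor (median chi-square ratio)."""
        chi2 = stats.chi2.isf(self.table["p"].dropna(), df=1)
        return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))

    def summary(self) -> str:
        nf = self.null_fit
        lines = [
            "Mixed linear model association scan (EMMAX approximation)",
            f"  SNPs tested:          {self.table['p'].notna().sum()}"
            f" of {len(self.table)}",
            f"  sigma_g^2:            {nf.sigma_g2:.6g}",
            f"  sigma_e^2:            {nf.sigma_e2:.6g}",
            f"  pseudo-heritability:  {nf.h2:.4f}",
            f"  lambda_GC:            {self.lambda_gc():.4f}",
        ]
        if self.threshold is not None:
            lines.append(f"  -log10(p) threshold:  {self.threshold:.3f}"
                         f"  ({len(self.significant())} significant SNPs)")
        return "\n".join(lines)


class MixedLMGWAS:
    """EMMAX-style GWAS model: build from phenotype + genotypes, then
    :meth:`fit` to scan every SNP.

    Parameters
    ----------
    y : phenotype vector (n,)
    genotypes : GenotypeMatrix with the markers to scan
    covariates : optional extra fixed-effect columns (n, c)
    kinship : optional KinshipMatrix / ndarray; default simple-matching
        kinship computed from ``genotypes``
    n_pcs : number of genotype principal components added as fixed effects
        (population-structure correction); default 3
    """

    def __init__(self, y, genotypes: GenotypeMatrix, covariates=None,
                 kinship=None, n_pcs: int = 3):
        self.y = np.asarray(y, dtype=float).ravel()
        if len(self.y) != genotypes.n_samples:
            raise ValueError("phenotype length does not match genotype samples")
        self.genotypes = genotypes
        cols = [np.ones((len(self.y), 1))]
        if n_pcs > 0:
            coords, _ = pca_genotypes(genotypes, n_components=n_pcs)
            cols.append(coords)
        if covariates is not None:
            cov = np.atleast_2d(np.asarray(covariates, dtype=float))
            if cov.shape[0] != len(self.y):
                cov = cov.T
            cols.append(cov)
        self.X = np.hstack(cols)
        if kinship is None:
            kinship = smc_kinship(genotypes)
        self.K = kinship.values if isinstance(kinship, KinshipMatrix) else \
            np.asarray(kinship, dtype=float)

    def fit(self, threshold: float | None = None) -> GWASResults:
        null = reml_null(self.y, self.X, self.K)
        table = emmax_scan(self.y, self.X, null, self.genotypes)
        return GWASResults(table, null, threshold=threshold)


def emmax_scan(y: np.ndarray, X: np.ndarray, null: NullModelFit,
               G: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP GLS with the null-model variance held fixed.

    Each SNP (mean-imputed codes) is appended to X and tested with a Wald
    test under V = sigma_g^2 K + sigma_e^2 I. Monomorphic SNPs give NA rows.
    """
    y = np.asarray(y, dtype=float).ravel()
    U, w = null.eigenvectors, null.eigenvalues
    d = null.sigma_g2 * w + null.sigma_e2
    sd = np.sqrt(d)
    # whitened responses/design: V^{-1/2} = D^{-1/2} U'
    yt = (U.T @ y) / sd
    Xt = (U.T @ X) / sd[:, None]
    W = G.mean_imputed()
    Wt = (U.T @ W) / sd[:, None]
    maf = G.maf()
    m = G.n_snps
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    XtX = Xt.T @ Xt
    Xty = Xt.T @ yt
    for k in range(m):
        s = Wt[:, k]
        if np.allclose(G.matrix[:, k][G.matrix[:, k] != MISSING],
                       G.matrix[:, k][G.matrix[:, k] != MISSING][0]
                       if (G.matrix[:, k] != MISSING).any() else 0):
            continue  # monomorphic
        A = np.empty((XtX.shape[0] + 1, XtX.shape[0] + 1))
        A[:-1, :-1] = XtX
        A[:-1, -1] = Xt.T @ s
        A[-1, :-1] = A[:-1, -1]
        A[-1, -1] = s @ s
        b = np.append(Xty, s @ yt)
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            continue
        est = Ainv @ b
        beta[k] = est[-1]
        se[k] = np.sqrt(Ainv[-1, -1])
        z = beta[k] / se[k]
        pval[k] = stats.chi2.sf(z * z, df=1)
    chrom, pos = [], []
    for sid in G.snp_ids:
        c, _, p = str(sid).rpartition("_")
        chrom.append(c or sid)
        pos.append(int(p) if p.isdigit() else -1)
    with np.errstate(divide="ignore"):
        mlp = -np.log10(pval)
    return pd.DataFrame({
        "snp": G.snp_ids, "chrom": chrom, "pos": pos, "maf": maf,
        "beta": beta, "se": se, "p": pval, "minus_log10_p": mlp,
    })


# ---------------------------------------------------------------------------
# significance threshold
# ---------------------------------------------------------------------------


def significance_threshold(
    G: GenotypeMatrix, prune_r2: float = 0.1, window: int = 100,
    step: int = 10, override: float | None = None,
) -> dict:
    """Effective-test-count threshold: N = SNPs surviving LD pruning at
    ``prune_r2``; the genome-wide threshold is -log10(1/N) = log10(N), and
    the working threshold is min(threshold, override) when an override is
    configured (trading a few false negatives for sensitivity)."""
    kept = ld_prune(G, window_snps=window, step_snps=step, r2_max=prune_r2)
    n_eff = len(kept)
    thr = float(np.log10(n_eff)) if n_eff > 0 else 0.0
    working = min(thr, override) if override is not None else thr
    return {"n_effective": n_eff, "threshold": thr, "working_threshold": working}


# ---------------------------------------------------------------------------
# genotype-group trait tests
# ---------------------------------------------------------------------------


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def genotype_group_test(y: np.ndarray, snp: np.ndarray,
                        min_class_size: int = 2) -> dict:
    """Trait differences among the genotype classes of one SNP.

    Classes (codes 0/1/2) with at least ``min_class_size`` non-missing
    observations enter a one-way ANOVA plus pairwise Welch t-tests with
    significance stars at 0.05 / 0.01 / 0.001.
    """
    y = np.asarray(y, dtype=float).ravel()
    snp = np.asarray(snp)
    groups, keys = [], []
    for code in (0, 1, 2):
        sel = (snp == code) & ~np.isnan(y)
        if sel.sum() >= min_class_size:
            groups.append(y[sel])
            keys.append(code)
    if len(groups) < 2:
        raise ValueError("need >= 2 genotype classes with enough observations")
    F, p_anova = stats.f_oneway(*groups)
    out = {
        "classes": keys,
        "n": {k: len(g) for k, g in zip(keys, groups)},
        "mean": {k: float(np.mean(g)) for k, g in zip(keys, groups)},
        "median": {k: float(np.median(g)) for k, g in zip(keys, groups)},
        "anova_F": float(F),
        "anova_p": float(p_anova),
        "pairwise": {},
    }
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            t, p = stats.ttest_ind(groups[a], groups[b], equal_var=False)
            out["pairwise"][(keys[a], keys[b])] = {
                "t": float(t), "p": float(p), "stars": _stars(float(p)),
            }
    return out


# ---------------------------------------------------------------------------
# pairwise LD
# ---------------------------------------------------------------------------


def em_haplotype_freqs(ga: np.ndarray, gb: np.ndarray,
                       tol: float = 1e-10, max_iter: int = 500
                       ) -> np.ndarray | None:
    """EM estimate of the four 2-locus haplotype frequencies (AB, Ab, aB, ab;
    'A'/'B' = alt alleles) from unphased diploid codes. Returns None when
    either locus is monomorphic among co-observed samples."""
    sel = (ga != MISSING) & (gb != MISSING)
    a = ga[sel].astype(int)
    b = gb[sel].astype(int)
    n = len(a)
    if n == 0 or len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        return None
    counts = np.zeros((3, 3))
    for i in range(n):
        counts[a[i], b[i]] += 1
    pA = a.sum() / (2 * n)
    pB = b.sum() / (2 * n)
    # init at linkage equilibrium
    f = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()
    n_dh = counts[1, 1]  # double heterozygotes: phase-ambiguous
    for _ in range(max_iter):
        # expected fraction of double hets in cis (AB/ab) configuration
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        hap = np.zeros(4)
        # unambiguous contributions
        hap[0] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2] + w * n_dh
        hap[1] = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0] + (1 - w) * n_dh
        hap[2] = 2 * counts[0, 2] + counts[1, 2] + counts[0, 1] + (1 - w) * n_dh
        hap[3] = 2 * counts[0, 0] + counts[1, 0] + counts[0, 1] + w * n_dh
        new = hap / (2 * n)
        if np.abs(new - f).max() < tol:
            f = new
            break
        f = new
    return f


def ld_pair(ga: np.ndarray, gb: np.ndarray) -> dict:
    """D, D' and r^2 for one SNP pair via EM haplotype frequencies; falls
    back to composite (genotype-correlation) r^2 if EM is degenerate.
    Monomorphic input gives NaNs."""
    f = em_haplotype_freqs(ga, gb)
    if f is None:
        return {"D": np.nan, "Dprime": np.nan, "r2": np.nan, "method": "NA"}
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    D = f[0] - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        sel = (ga != MISSING) & (gb != MISSING)
        r = np.corrcoef(ga[sel], gb[sel])[0, 1]
        return {"D": np.nan, "Dprime": np.nan, "r2": float(r * r),
                "method": "composite"}
    r2 = D * D / denom
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = abs(D) / dmax if dmax > 0 else np.nan
    return {"D": float(D), "Dprime": float(min(dprime, 1.0)),
            "r2": float(min(r2, 1.0)), "method": "EM"}


def ld_pairwise(G: GenotypeMatrix, window: int = 50) -> pd.DataFrame:
    """All SNP pairs within ``window`` consecutive columns: D, D', r^2."""
    rows = []
    for i in range(G.n_snps):
        for j in range(i + 1, min(i + window + 1, G.n_snps)):
            st = ld_pair(G.matrix[:, i], G.matrix[:, j])
            rows.append({"snp_a": G.snp_ids[i], "snp_b": G.snp_ids[j],
                         "idx_a": i, "idx_b": j, **st})
    return pd.DataFrame(rows)


def haplotype_blocks(ld_table: pd.DataFrame, dprime_min: float = 0.98
                     ) -> list[tuple[int, int]]:
    """Maximal runs of consecutive SNPs whose adjacent pairs all have
    D' >= ``dprime_min`` (a threshold-run simplification of block calling).
    Returns (start_idx, end_idx) inclusive pairs with end > start."""
    adj = ld_table[ld_table["idx_b"] == ld_table["idx_a"] + 1]
    adj = adj.sort_values("idx_a")
    blocks = []
    run_start = None
    prev = None
    for _, row in adj.iterrows():
        ok = bool(row["Dprime"] >= dprime_min) if np.isfinite(row["Dprime"]) else False
        i = int(row["idx_a"])
        contiguous = prev is not None and i == prev + 1
        if ok:
            if run_start is None or not contiguous:
                if run_start is not None:
                    blocks.append((run_start, prev + 1))
                run_start = i
            prev = i
        else:
            if run_start is not None:
                blocks.append((run_start, prev + 1))
                run_start = None
            prev = i
    if run_start is not None:
        blocks.append((run_start, prev + 1))
    return blocks
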