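"""Genomic prediction: GBLUP and the Bayes alphabet, with repeated k-fold
cross-validation and the derived breeding metrics.

GBLUP fits y = Xb + u + e with u ~ N(0, sigma_g^2 G), G a VanRaden genomic
relationship matrix; variance components come from spectral REML and GEBVs
from the mixed-model equations. BayesA/B/C fit y = Xb + W a + e by Gibbs
sampling with, respectively, per-marker scaled-t shrinkage, a spike-and-slab
with per-marker slab variances, and a spike-and-slab with a common slab
variance. Predictive ability (PA) is the Pearson correlation between
observed phenotypes and cross-validated GEBVs; prediction accuracy is
PC = PA / sqrt(H^2) with H^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix
from .gwas import reml_null, NullModelFit


# ---------------------------------------------------------------------------
# the relationship matrix
# ---------------------------------------------------------------------------


@dataclass
class GRM:
    """VanRaden (method 1) genomic relationship matrix."""

    values: np.ndarray
    sample_ids: list[str]


def vanraden_grm(W: GenotypeMatrix | np.ndarray,
                 sample_ids: list[str] | None = None,
                 ridge: float = 1e-8) -> GRM:
    """G = M M' / (2 * sum p_k (1 - p_k)) with M the mean-imputed codes
    centered by twice the allele frequency. A small ridge keeps G positive
    semidefinite; all-monomorphic input (zero denominator) is an error."""
    if isinstance(W, GenotypeMatrix):
        X = W.mean_imputed()
        ids = list(W.sample_ids)
    else:
        X = np.asarray(W, dtype=float)
        ids = sample_ids or [f"S{i}" for i in range(X.shape[0])]
    p = X.mean(axis=0) / 2.0
    denom = 2.0 * float((p * (1.0 - p)).sum())
    if denom <= 0:
        raise ValueError("all markers monomorphic: GRM denominator is zero")
    M = X - 2.0 * p
    G = (M @ M.T) / denom
    G = G + ridge * np.eye(G.shape[0])
    return GRM(G, ids)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def heritability(sigma_g2: float, sigma_e2: float) -> float:
    """Broad-sense heritability H^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)."""
    if sigma_g2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be non-negative")
    tot = sigma_g2 + sigma_e2
    if tot == 0:
        raise ValueError("both variance components are zero")
    return sigma_g2 / tot


def prediction_accuracy(pa: float, h2: float) -> float:
    """PC = PA / sqrt(H^2); requires H^2 in (0, 1]."""
    if not 0.0 < h2 <= 1.0:
        raise ValueError("heritability must be in (0, 1]")
    return pa / np.sqrt(h2)


def improvement_pct(before: float, after: float) -> float:
    """Percent improvement 100 * (after - before) / before."""
    if before == 0:
        raise ValueError("baseline value must be nonzero")
    return 100.0 * (after - before) / before


# ---------------------------------------------------------------------------
# GBLUP
# ---------------------------------------------------------------------------


@dataclass
class GBLUPResults:
    sigma_g2: float
    sigma_e2: float
    h2: float
    beta: np.ndarray
    gebv: np.ndarray
    loglik: float
    model: "GBLUP" = field(repr=False, default=None)

    def summary(self) -> str:
        return "\n".join([
            "GBLUP fit (REML)",
            f"  n:            {len(self.gebv)}",
            f"  sigma_g^2:    {self.sigma_g2:.6g}",
            f"  sigma_e^2:    {self.sigma_e2:.6g}",
            f"  H^2:          {self.h2:.4f}",
            f"  REML loglik:  {self.loglik:.4f}",
        ])


class GBLUP:
    """GBLUP model y = Xb + u + e, Var(u) = sigma_g^2 G.

    ``relationship`` is a :class:`GRM` (or raw PSD matrix); ``X`` defaults to
    an intercept. :meth:`fit` estimates variance components by REML and
    returns a :class:`GBLUPResults` carrying GEBVs and H^2.
    """

    def __init__(self, y, relationship: GRM | np.ndarray, X=None):
        self.y = np.asarray(y, dtype=float).ravel()
        self.G = relationship.values if isinstance(relationship, GRM) \
            else np.asarray(relationship, dtype=float)
        n = len(self.y)
        if self.G.shape != (n, n):
            raise ValueError("relationship matrix shape does not match y")
        if X is None:
            X = np.ones((n, 1))
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != n:
            X = X.T
        self.X = X

    def fit(self) -> GBLUPResults:
        null = reml_null(self.y, self.X, self.G)
        V = null.sigma_g2 * self.G + null.sigma_e2 * np.eye(len(self.y))
        Vinv_r = np.linalg.solve(V, self.y - self.X @ null.beta)
        gebv = null.sigma_g2 * (self.G @ Vinv_r)
        h2 = heritability(null.sigma_g2, null.sigma_e2)
        return GBLUPResults(null.sigma_g2, null.sigma_e2, h2, null.beta, gebv,
                            null.loglik, model=self)


def gblup_fit(y, relationship, X=None) -> GBLUPResults:
    """Functional wrapper around :class:`GBLUP`."""
    return GBLUP(y, relationship, X=X).fit()


def gblup_train_predict(y: np.ndarray, G_full: np.ndarray,
                        train_idx: np.ndarray, test_idx: np.ndarray,
                        X: np.ndarray | None = None) -> np.ndarray:
    """Fit GBLUP on the training samples only and predict test GEBVs via
    u_test = sigma_g^2 G[test, train] V_train^{-1} (y_train - X_train b).
    Test phenotypes are never touched."""
    n = G_full.shape[0]
    if X is None:
        X = np.ones((n, 1))
    tr = np.asarray(train_idx)
    te = np.asarray(test_idx)
    y_tr = np.asarray(y, dtype=float)[tr]
    null = reml_null(y_tr, X[tr], G_full[np.ix_(tr, tr)])
    V = null.sigma_g2 * G_full[np.ix_(tr, tr)] + null.sigma_e2 * np.eye(len(tr))
    r = y_tr - X[tr] @ null.beta
    return null.sigma_g2 * (G_full[np.ix_(te, tr)] @ np.linalg.solve(V, r))


# ---------------------------------------------------------------------------
# Bayes alphabet
# ---------------------------------------------------------------------------


@dataclass
class BayesResults:
    model: str
    effect_means: np.ndarray          # posterior mean marker effects
    inclusion_probs: np.ndarray | None
    beta: np.ndarray                  # posterior mean fixed effects
    sigma_e2: float                   # posterior mean residual variance
    gebv: np.ndarray
    n_samples_kept: int
    _W_columns_mean: np.ndarray = field(repr=False, default=None)

    def predict(self, W_new: np.ndarray) -> np.ndarray:
        """GEBVs for new individuals from their marker codes."""
        return np.asarray(W_new, dtype=float) @ self.effect_means

    def summary(self) -> str:
        lines = [
            f"Bayes{self.model} fit ({self.n_samples_kept} posterior draws)",
            f"  markers:        {len(self.effect_means)}",
            f"  sigma_e^2:      {self.sigma_e2:.6g}",
        ]
        if self.inclusion_probs is not None:
            lines.append(f"  mean inclusion: {self.inclusion_probs.mean():.4f}")
        return "\n".join(lines)


class BayesAlphabet:
    """Gibbs-sampled marker-effect model y = Xb + W a + e.

    model='A': every marker has an effect with its own variance (scaled-t
    shrinkage). model='B': spike-and-slab, per-marker slab variance,
    exclusion probability ``pi``. model='C': spike-and-slab with a common
    slab variance.

    Hyperpriors are scaled-inverse-chi-square with ``df`` degrees of freedom
    and scales chosen so the prior genetic / residual variances split the
    phenotypic variance at an assumed marker R^2 (default 0.5). The chain is
    fully determined by the seed passed to :meth:`fit`.
    """

    def __init__(self, y, W, X=None, model: str = "A",
                 n_iter: int = 3000, burn_in: int = 500, thin: int = 5,
                 pi: float = 0.99, df: float = 5.0, r2: float = 0.5):
        if model not in ("A", "B", "C"):
            raise ValueError("model must be 'A', 'B' or 'C'")
        if n_iter <= burn_in:
            raise ValueError("n_iter must exceed burn_in")
        self.y = np.asarray(y, dtype=float).ravel()
        self.W = W.mean_imputed() if isinstance(W, GenotypeMatrix) \
            else np.asarray(W, dtype=float)
        n = len(self.y)
        if self.W.shape[0] != n:
            raise ValueError("marker matrix rows must match phenotype length")
        if X is None:
            X = np.ones((n, 1))
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != n:
            X = X.T
        self.X = X
        self.model = model
        self.n_iter, self.burn_in, self.thin = n_iter, burn_in, thin
        self.pi = pi
        self.df = df
        self.r2 = r2

    def fit(self, seed: int) -> BayesResults:
        rng = np.random.default_rng(seed)
        y, W, X = self.y, self.W, self.X
        n, m = W.shape
        p_fix = X.shape[1]
        wtw = (W ** 2).sum(axis=0)
        wtw = np.where(wtw == 0, 1e-12, wtw)
        xtx = (X ** 2).sum(axis=0)
        var_y = y.var()
        mean_wvar = max(W.var(axis=0).mean(), 1e-12)
        df = self.df
        incl_prior = 1.0 if self.model == "A" else (1.0 - self.pi)
        # prior per-marker slab variance targeting R^2 of phenotypic variance
        sigma_a2_0 = self.r2 * var_y / max(m * incl_prior * mean_wvar, 1e-12)
        S_a = sigma_a2_0 * (df - 2.0) / df if df > 2 else sigma_a2_0
        S_e = (1.0 - self.r2) * var_y * (df - 2.0) / df if df > 2 else var_y

        a = np.zeros(m)
        delta = np.ones(m, dtype=bool) if self.model == "A" \
            else np.zeros(m, dtype=bool)
        s2_m = np.full(m, sigma_a2_0)       # per-marker variances (A, B)
        s2_common = sigma_a2_0              # common slab variance (C)
        beta = np.zeros(p_fix)
        sigma_e2 = max(var_y * (1.0 - self.r2), 1e-8)
        e = y - X @ beta                    # residual (a = 0 initially)

        kept = 0
        a_sum = np.zeros(m)
        incl_sum = np.zeros(m)
        beta_sum = np.zeros(p_fix)
        se_sum = 0.0

        for it in range(self.n_iter):
            # fixed effects (flat prior)
            for j in range(p_fix):
                e += X[:, j] * beta[j]
                rhs = X[:, j] @ e
                cj = xtx[j]
                beta[j] = rng.normal(rhs / cj, np.sqrt(sigma_e2 / cj))
                e -= X[:, j] * beta[j]
            # marker effects
            logit_prior = np.log(incl_prior) - np.log(max(1 - incl_prior, 1e-300)) \
                if incl_prior < 1.0 else np.inf
            for k in range(m):
                if a[k] != 0.0:
                    e += W[:, k] * a[k]
                rhs = W[:, k] @ e
                var_k = s2_common if self.model == "C" else s2_m[k]
                if self.model == "A":
                    include = True
                else:
                    # Bayes factor for inclusion from the marginal of w'e
                    v0 = sigma_e2 * wtw[k]
                    v1 = v0 + var_k * wtw[k] ** 2
                    log_bf = 0.5 * (np.log(v0 / v1)
                                    + rhs * rhs * (1.0 / v0 - 1.0 / v1))
                    log_odds = log_bf + logit_prior
                    p_incl = 1.0 / (1.0 + np.exp(-np.clip(log_odds, -700, 700)))
                    include = rng.random() < p_incl
                if include:
                    prec = wtw[k] + sigma_e2 / var_k
                    mu = rhs / prec
                    a[k] = rng.normal(mu, np.sqrt(sigma_e2 / prec))
                    e -= W[:, k] * a[k]
                    delta[k] = True
                else:
                    a[k] = 0.0
                    delta[k] = False
            # marker variances
            if self.model == "A":
                s2_m = (df * S_a + a ** 2) / rng.chisquare(df + 1.0, size=m)
            elif self.model == "B":
                chi = rng.chisquare(df + 1.0, size=m)
                s2_m = np.where(
                    delta, (df * S_a + a ** 2) / chi, (df * S_a) / chi
                )
            else:  # C
                n_in = int(delta.sum())
                s2_common = (df * S_a + float((a ** 2).sum())) \
                    / rng.chisquare(df + n_in)
            # residual variance
            sigma_e2 = (float(e @ e) + df * S_e) / rng.chisquare(n + df)
            # accumulate
            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                kept += 1
                a_sum += a
                incl_sum += delta
                beta_sum += beta
                se_sum += sigma_e2

        a_mean = a_sum / kept
        incl = None if self.model == "A" else incl_sum / kept
        return BayesResults(
            self.model, a_mean, incl, beta_sum / kept, se_sum / kept,
            W @ a_mean, kept, _W_columns_mean=W.mean(axis=0),
        )


def bayes_fit(y, W, model: str = "A", X=None, n_iter: int = 3000,
              burn_in: int = 500, thin: int = 5, seed: int = 0,
              pi: float = 0.99, df: float = 5.0, r2: float = 0.5) -> BayesResults:
    """Functional wrapper around :class:`BayesAlphabet`."""
    return BayesAlphabet(y, W, X=X, model=model, n_iter=n_iter,
                         burn_in=burn_in, thin=thin, pi=pi, df=df,
                         r2=r2).fit(seed)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    """Per-fold predictive abilities of a repeated k-fold cross-validation."""

    table: pd.DataFrame            # columns: repeat, fold, pa, n_test
    settings: dict = field(default_factory=dict)

    @property
    def mean_pa(self) -> float:
        return float(self.table["pa"].mean())

    @property
    def sd_pa(self) -> float:
        return float(self.table["pa"].std(ddof=1))

    def per_repeat(self) -> pd.Series:
        return self.table.groupby("repeat")["pa"].mean()


def cross_validate(y: np.ndarray, predictor, k: int = 5, repeats: int = 10,
                   seed: int = 0, settings: dict | None = None) -> CVResult:
    """Repeated k-fold cross-validation of a genomic-prediction procedure.

    ``predictor(y_train, train_idx, test_idx) -> predictions`` receives ONLY
    the training phenotypes (masking is structural: test phenotypes are
    never passed in), fits on the training fold and returns test GEBVs.
    PA per fold is the Pearson correlation of observed vs predicted in the
    held-out fold; a constant prediction vector gives PA = NaN for that fold.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 2 * k:
        raise ValueError("need at least 2k samples for k-fold CV")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(repeats):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            pred = np.asarray(predictor(y[train_idx], train_idx, test_idx))
            obs = y[test_idx]
            if np.std(pred) == 0 or np.std(obs) == 0:
                pa = np.nan
            else:
                pa = float(stats.pearsonr(obs, pred)[0])
            rows.append({"repeat": rep, "fold": f, "pa": pa,
                         "n_test": len(test_idx)})
    return CVResult(pd.DataFrame(rows), settings=dict(settings or {},
                                                      k=k, repeats=repeats,
                                                      seed=seed))


def gblup_cv_predictor(G_full: np.ndarray, X: np.ndarray | None = None):
    """A :func:`cross_validate` predictor for GBLUP with a fixed GRM."""

    def predictor(y_train, train_idx, test_idx):
        n = G_full.shape[0]
        Xf = np.ones((n, 1)) if X is None else X
        y_full = np.zeros(n)
        y_full[train_idx] = y_train
        return gblup_train_predict(y_full, G_full, train_idx, test_idx, X=Xf)

    return predictor


def bayes_cv_predictor(W: np.ndarray, model: str = "C",
                       X: np.ndarray | None = None, seed: int = 0,
                       **kwargs):
    """A :func:`cross_validate` predictor for the Bayes alphabet."""
    W = W.mean_imputed() if isinstance(W, GenotypeMatrix) else np.asarray(W, float)

    def predictor(y_train, train_idx, test_idx):
        Xt = None if X is None else X[train_idx]
        res = BayesAlphabet(y_train, W[train_idx], X=Xt, model=model,
                            **kwargs).fit(seed)
        return res.predict(W[test_idx])

    return predictor


# ---------------------------------------------------------------------------
# marker titration and GWAS-hit integration
# ---------------------------------------------------------------------------


def marker_titration(W: GenotypeMatrix, y: np.ndarray,
                     sizes: list[int], k: int = 5, repeats: int = 5,
                     seed: int = 0, X: np.ndarray | None = None
                     ) -> dict[int, CVResult]:
    """GBLUP cross-validation on random marker subsets of the given sizes
    (without replacement; a size equal to the panel uses every marker).
    The same seed reproduces both the subsets and the folds."""
    rng = np.random.default_rng(seed)
    out: dict[int, CVResult] = {}
    for size in sizes:
        if size > W.n_snps:
            raise ValueError(f"subset size {size} exceeds panel size {W.n_snps}")
        if size == W.n_snps:
            sub = W
        else:
            cols = np.sort(rng.choice(W.n_snps, size=size, replace=False))
            sub = W.subset_snps(cols)
        G = vanraden_grm(sub).values
        out[size] = cross_validate(
            y, gblup_cv_predictor(G, X=X), k=k, repeats=repeats,
            seed=seed + size, settings={"subset_size": size},
        )
    return out


def integrate_fixed_effect_snps(X: np.ndarray | None, W: GenotypeMatrix,
                                snp_indices) -> tuple[np.ndarray, np.ndarray]:
    """Append the genotype codes of GWAS-hit SNPs to the fixed-effect design
    and drop them from the random-effect marker set (no double counting).

    Collinear columns (monomorphic, or dependent on columns already in X)
    are dropped with a warning; if every listed SNP is monomorphic that is
    an error. Returns (augmented X, kept random-marker column indices).
    """
    snp_indices = list(np.atleast_1d(np.asarray(snp_indices, dtype=int)))
    n = W.n_samples
    Xa = np.ones((n, 1)) if X is None else np.atleast_2d(np.asarray(X, float))
    if Xa.shape[0] != n:
        Xa = Xa.T
    codes = W.mean_imputed()
    if snp_indices:
        maf = W.maf()
        if all(not maf[i] > 0 for i in snp_indices):
            raise ValueError("all listed fixed-effect SNPs are monomorphic")
    added = 0
    for idx in snp_indices:
        col = codes[:, [idx]]
        cand = np.hstack([Xa, col])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(Xa):
            Xa = cand
            added += 1
        else:
            warnings.warn(
                f"fixed-effect SNP column {W.snp_ids[idx]} is collinear; dropped",
                stacklevel=2,
            )
    keep = np.setdiff1d(np.arange(W.n_snps), np.asarray(snp_indices, dtype=int))
    return Xa, keep
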