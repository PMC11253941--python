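"""Mixed-model association for body weight with kinship control.

The model is y = W a + x b + u + e with u ~ N(0, sg^2 K) and
e ~ N(0, se^2 I).  The variance ratio delta = se^2/sg^2 is estimated
once under the null (no SNP) by REML on the eigendecomposition of the
kinship matrix, then each SNP's effect is tested by generalized least
squares with the fixed covariance (the EMMAX approximation).  SNPs are
filtered by minor allele frequency and missingness; a sample with a
missing dosage is dropped for that SNP only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .datatypes import MISSING, GenotypeTable


def kinship_matrix(table: GenotypeTable) -> np.ndarray:
    """Standardized-genotype kinship K = Z Z^T / m.

    Per site, dosage is centered by 2p and scaled by the binomial s.d.
    sqrt(2 p (1-p)); missing entries become 0 after centering.
    Monomorphic sites are excluded.
    """
    calls = table.calls.astype(float)
    calls[calls == MISSING] = np.nan
    p = np.nanmean(calls, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic sites for kinship")
    g = calls[:, poly]
    p = p[poly]
    z = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
    z = np.nan_to_num(z)
    return z @ z.T / z.shape[1]


def _reml_delta(y: np.ndarray, w: np.ndarray, evals: np.ndarray,
                evecs: np.ndarray) -> tuple[float, float, float]:
    """Null-model REML for delta = se^2/sg^2 on the rotated system.

    Returns (delta, sg2, se2).
    """
    n, q = w.shape
    yr = evecs.T @ y
    wr = evecs.T @ w

    def neg_reml(log_delta: float) -> float:
        d = np.exp(log_delta)
        v = evals + d
        wtv = wr.T / v
        a = wtv @ wr
        b = wtv @ yr
        try:
            beta = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            return np.inf
        r = yr - wr @ beta
        rss = float(r @ (r / v))
        df = n - q
        sg2 = rss / df
        ll = -0.5 * (df * np.log(2 * np.pi * sg2) + np.log(v).sum()
                     + np.linalg.slogdet(a)[1] + df)
        return -ll

    res = optimize.minimize_scalar(neg_reml, bounds=(-10.0, 10.0),
                                   method="bounded")
    delta = float(np.exp(res.x))
    d = evals + delta
    wtv = (evecs.T @ w).T / d
    beta = np.linalg.solve(wtv @ (evecs.T @ w), wtv @ (evecs.T @ y))
    r = evecs.T @ y - (evecs.T @ w) @ beta
    sg2 = float(r @ (r / d)) / (n - w.shape[1])
    return delta, sg2, sg2 * delta


@dataclass
class GwasResult:
    table: pd.DataFrame        # per SNP: site, effect, se, p, q, n_used
    sigma2_g: float
    sigma2_e: float
    heritability: float        # sg^2 / (sg^2 + se^2) under the null model
    filters: dict


class MixedModelGWAS(BaseEstimator):
    """EMMAX-style single-trait LMM association.

    ``fit(table, y, covariates=...)`` estimates the null variance
    components once, then scans every SNP passing the MAF/missingness
    filters.  Fitted attributes: ``result_`` (:class:`GwasResult`),
    ``delta_``, ``heritability_``.
    """

    def __init__(self, min_maf: float = 0.05, max_missing: float = 0.10,
                 fdr: float = 0.05):
        self.min_maf = min_maf
        self.max_missing = max_missing
        self.fdr = fdr

    def fit(self, table: GenotypeTable, y, covariates=None,
            kinship: np.ndarray | None = None):
        y = np.asarray(y, float)
        n = table.n_samples
        if y.size != n or np.isnan(y).any():
            raise ValueError("phenotype must be complete, one value per sample")
        if covariates is None:
            w = np.ones((n, 1))
        else:
            cov = np.atleast_2d(np.asarray(covariates, float))
            if cov.shape[0] != n:
                cov = cov.T
            w = np.column_stack([np.ones(n), cov])
        if np.linalg.matrix_rank(w) < w.shape[1]:
            raise ValueError("singular covariate design")
        k = kinship_matrix(table) if kinship is None else np.asarray(kinship)
        evals, evecs = np.linalg.eigh(k)
        if evals.min() < -1e-8:
            # clip tiny negative eigenvalues so K is PSD
            evals = np.maximum(evals, 0.0)
        evals = np.maximum(evals, 0.0)
        delta, sg2, se2 = _reml_delta(y, w, evals, evecs)
        self.delta_, self.sigma2_g_, self.sigma2_e_ = delta, sg2, se2
        self.heritability_ = sg2 / (sg2 + se2) if sg2 + se2 > 0 else 0.0

        calls = table.calls.astype(float)
        calls[calls == MISSING] = np.nan
        missing_frac = np.mean(np.isnan(calls), axis=0)
        with np.errstate(invalid="ignore"):
            p_alt = np.nanmean(calls, axis=0) / 2.0
        maf = np.minimum(p_alt, 1 - p_alt)
        keep = (missing_frac <= self.max_missing) & (maf >= self.min_maf)
        keep &= np.isfinite(p_alt)
        idx = np.nonzero(keep)[0]

        # covariance V = sg2 (K + delta I); GLS per SNP on its complete
        # samples.  Complete columns go through the fast rotated path.
        v_full = k + delta * np.eye(n)
        rot_w = evecs.T @ w
        rot_y = evecs.T @ y
        dvec = evals + delta
        ids = table.site_ids
        rows = []
        for j in idx:
            x = calls[:, j]
            ok = ~np.isnan(x)
            if ok.all():
                design = np.column_stack([rot_w, evecs.T @ x])
                wt = design.T / dvec
                a = wt @ design
                b = wt @ rot_y
                try:
                    coef = np.linalg.solve(a, b)
                except np.linalg.LinAlgError:
                    continue
                r = rot_y - design @ coef
                rss = float(r @ (r / dvec))
                dof = n - design.shape[1]
                cov_last = np.linalg.inv(a)[-1, -1]
            else:
                sub = np.nonzero(ok)[0]
                design = np.column_stack([w[sub], x[sub]])
                try:
                    cf = linalg.cho_factor(v_full[np.ix_(sub, sub)])
                except linalg.LinAlgError:
                    continue
                vy = linalg.cho_solve(cf, y[sub])
                vd = linalg.cho_solve(cf, design)
                a = design.T @ vd
                try:
                    coef = np.linalg.solve(a, design.T @ vy)
                except np.linalg.LinAlgError:
                    continue
                r = y[sub] - design @ coef
                rss = float(r @ linalg.cho_solve(cf, r))
                dof = sub.size - design.shape[1]
                cov_last = np.linalg.inv(a)[-1, -1]
            if dof <= 0 or cov_last <= 0:
                continue
            s2 = rss / dof
            se = np.sqrt(s2 * cov_last)
            beta = coef[-1]
            z = beta / se if se > 0 else 0.0
            rows.append({"site": ids[j], "effect": beta, "se": se,
                         "z": z, "p": 2 * stats.norm.sf(abs(z)),
                         "n_used": int(ok.sum())})
        out = pd.DataFrame(rows)
        if len(out):
            out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        else:
            out["q"] = []
        self.result_ = GwasResult(
            out, sg2, se2, self.heritability_,
            {"min_maf": self.min_maf, "max_missing": self.max_missing,
             "fdr": self.fdr},
        )
        return self

    def significant_snps(self) -> set[str]:
        t = self.result_.table
        return set(t.loc[t["q"] <= self.fdr, "site"])


def lmm_association(phenotype, covariates, table: GenotypeTable,
                    kin: np.ndarray | None = None, min_maf: float = 0.05,
                    max_missing: float = 0.10, fdr: float = 0.05) -> GwasResult:
    """Functional wrapper over :class:`MixedModelGWAS`."""
    model = MixedModelGWAS(min_maf=min_maf, max_missing=max_missing, fdr=fdr)
    model.fit(table, phenotype, covariates=covariates, kinship=kin)
    return model.result_


def gwas_scan_overlap(gwas_genes, scan_genes, universe,
                      n_replicates: int = 100_000, seed: int = 0):
    """GWAS x selection-scan candidate-gene overlap permutation test
    (same resampling engine as the cross-transect overlap test)."""
    from .shared import overlap_permutation_test

    return overlap_permutation_test(gwas_genes, scan_genes,
                                    universe, universe,
                                    n_replicates=n_replicates, seed=seed)
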