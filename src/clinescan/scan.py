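"""Genotype-environment association scan with latent-factor confounders.

The scan regresses each SNP's dosage on one environmental variable
while K latent factors absorb neutral population structure, then
recalibrates the per-site z-scores with the genomic inflation factor
(lambda = median(z^2) / median chi^2_1) and converts them to
Benjamini-Hochberg q-values.  Outliers are sites passing both a
q-value and a |z| threshold.

The latent factors are the deterministic ridge-free analogue of the
MCMC latent factor mixed model: the top-K left singular vectors of the
genotype matrix after projecting out the environmental covariate, so
that structure orthogonal to the environment is absorbed while clinal
signal is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .datatypes import MISSING, GenotypeTable

#: median of the chi-square distribution with 1 d.f.
CHI2_1_MEDIAN: float = float(stats.chi2.ppf(0.5, 1))


@dataclass
class ScanConfig:
    """Thresholds of one scan.

    K is the number of latent factors (3 for the six-population South
    American transect, 2 for the five-population North American ones);
    the headline within-transect scan thresholds at q <= 0.01, the
    cross-transect comparisons at q <= 0.05, both with |z| >= 2.
    """

    K: int = 3
    variables: list[str] = field(default_factory=lambda: ["LAT", "MAT", "PDM"])
    q_threshold: float = 0.05
    z_threshold: float = 2.0
    min_maf: float = 0.05
    min_call_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("K must be >= 0")
        for name in ("q_threshold", "min_maf", "min_call_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.z_threshold < 0:
            raise ValueError("z_threshold must be positive")


class LatentFactorScan(BaseEstimator):
    """Per-site association of dosage with one environmental variable.

    Parameters
    ----------
    K : int
        Number of latent factors.  K=0 reduces exactly to simple
        per-site regression of dosage on the environment.

    Attributes (after ``fit(X, y)`` with X the samples x sites dosage
    matrix, already filtered and mean-imputed, and y the environment)
    ----------
    factors_ : (n_samples, K) orthonormal latent factor scores
    loadings_ : (n_sites, K) factor loadings
    effects_, stderr_, zscores_ : per-site environmental coefficient
    """

    def __init__(self, K: int = 3):
        self.K = K

    def fit(self, X, y):
        G = np.asarray(X, float)
        env = np.asarray(y, float).ravel()
        n, m = G.shape
        if env.size != n:
            raise ValueError("environment length must match sample count")
        if np.ptp(env) == 0:
            raise ValueError("constant environmental variable")
        if self.K >= n:
            raise ValueError("K must be smaller than the sample count")
        Gc = G - G.mean(axis=0)
        e = (env - env.mean()) / env.std()
        if self.K > 0:
            # project the environment out, then SVD for the factors
            resid = Gc - np.outer(e, e @ Gc) / n
            U, s, _ = np.linalg.svd(resid, full_matrices=False)
            self.factors_ = U[:, : self.K]
        else:
            self.factors_ = np.empty((n, 0))
        D = np.column_stack([np.ones(n), e, self.factors_])
        q = D.shape[1]
        DtD_inv = np.linalg.inv(D.T @ D)
        B = DtD_inv @ D.T @ Gc
        resid = Gc - D @ B
        dof = max(n - q, 1)
        sigma2 = (resid ** 2).sum(axis=0) / dof
        se = np.sqrt(np.maximum(sigma2 * DtD_inv[1, 1], 1e-300))
        self.loadings_ = B[2:].T
        self.effects_ = B[1]
        self.stderr_ = se
        with np.errstate(invalid="ignore", divide="ignore"):
            self.zscores_ = np.where(se > 0, self.effects_ / se, 0.0)
        self.dof_ = dof
        return self


def calibrate_pvalues(z) -> tuple[float, np.ndarray, np.ndarray]:
    """Genomic-control calibration of a vector of z-scores.

    Returns (lambda, calibrated p, BH q).  lambda is median(z^2)
    divided by the chi^2_1 median; the calibrated p is the chi^2_1
    upper tail of z^2 / lambda.  lambda = 0 (all-zero z) is flagged by
    returning uncalibrated p = 1 everywhere.
    """
    z = np.asarray(z, float)
    if np.sum(np.isfinite(z)) < 2:
        raise ValueError("need >= 2 finite z-scores")
    lam = float(np.median(z ** 2) / CHI2_1_MEDIAN)
    if lam <= 0:
        p = np.ones_like(z)
        return 0.0, p, p
    p = stats.chi2.sf(z ** 2 / lam, 1)
    q = multipletests(p, method="fdr_bh")[1]
    return lam, p, q


@dataclass
class ScanResult:
    """Per-site scan output for one transect and one variable."""

    table: pd.DataFrame     # chrom, pos, site, effect, z, p_raw, p_cal, q
    lambda_: float
    variable: str
    transect: str = ""
    K: int = 0
    n_sites_tested: int = 0


def scan_genotypes(table: GenotypeTable, env_values, config: ScanConfig,
                   variable: str = "", transect: str = "") -> ScanResult:
    """Filter sites (MAF, call fraction), mean-impute missing dosages,
    fit the latent-factor scan and calibrate."""
    env = np.asarray(env_values, float)
    if np.isnan(env).any():
        raise ValueError("environmental values contain missing entries")
    calls = table.calls.astype(float)
    calls[calls == MISSING] = np.nan
    call_frac = np.mean(~np.isnan(calls), axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(calls, axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    keep = (call_frac >= config.min_call_fraction) & (maf >= config.min_maf)
    keep &= np.isfinite(freq)
    idx = np.nonzero(keep)[0]
    G = calls[:, idx]
    col_mean = np.nanmean(G, axis=0)
    G = np.where(np.isnan(G), col_mean, G)
    model = LatentFactorScan(K=config.K).fit(G, env)
    lam, p_cal, q = calibrate_pvalues(model.zscores_)
    p_raw = stats.chi2.sf(model.zscores_ ** 2, 1)
    out = table.sites.iloc[idx].reset_index(drop=True).copy()
    out["site"] = out["chrom"].astype(str) + ":" + out["pos"].astype(str)
    out["effect"] = model.effects_
    out["z"] = model.zscores_
    out["p_raw"] = p_raw
    out["p_cal"] = p_cal
    out["q"] = q
    return ScanResult(out, lam, variable, transect, config.K, len(idx))


def call_outliers(result: ScanResult, config: ScanConfig) -> set[str]:
    """Candidate SNPs: q <= q_threshold AND |z| >= z_threshold."""
    t = result.table
    hit = (t["q"] <= config.q_threshold) & (t["z"].abs() >= config.z_threshold)
    return set(t.loc[hit, "site"])
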