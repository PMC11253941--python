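"""Population differentiation, structure and relatedness statistics.

Implements the Weir & Cockerham (1984) two-level theta estimator
(ratio-of-averages aggregation, per-site negatives retained), a
tie-corrected normal-approximation Mann-Whitney U test, a Mantel test
with simultaneous row/column permutation, a moment estimator of
pairwise relatedness on called genotypes with greedy pruning at a
configurable threshold (0.25 = half-siblings), PCA and simple OLS
correlation summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA as _SkPCA

from .datatypes import MISSING, GenotypeTable

# ---------------------------------------------------------------- frequencies

def allele_frequencies(table: GenotypeTable,
                       min_call_fraction: float = 0.0) -> pd.DataFrame:
    """Alt-allele frequency and call-fraction per site.

    Sites called in fewer than ``min_call_fraction`` of samples (the
    paper-style "called in at least 80% of individuals" filter) are
    flagged ``excluded``; their frequency is reported from whatever
    calls exist, or 0.0 when every call is missing (never NaN).
    """
    if not 0.0 <= min_call_fraction <= 1.0:
        raise ValueError("min_call_fraction outside [0, 1]")
    calls = table.calls
    called = calls != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, alt / (2.0 * np.maximum(n_called, 1)), 0.0)
    call_fraction = n_called / table.n_samples
    return pd.DataFrame({
        "site": table.site_ids,
        "freq": freq,
        "call_fraction": call_fraction,
        "excluded": (call_fraction < min_call_fraction) | (n_called == 0),
    })


# ------------------------------------------------------------------- WC F_ST

@dataclass
class FstResult:
    per_site: pd.DataFrame      # columns a, b, c, theta
    theta: float                # multi-site sum(a)/sum(a+b+c)
    n_excluded: int             # sites with undefined denominator
    labels: tuple[str, str] = ("pop1", "pop2")


def _pop_stats(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    called = calls != MISSING
    n = called.sum(axis=0).astype(float)
    alt = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * np.maximum(n, 1)), np.nan)
        h = np.where(n > 0, np.where(called, calls == 1, 0).sum(axis=0)
                     / np.maximum(n, 1), np.nan)
    return n, p, h


def pairwise_wc_fst(table_a: GenotypeTable, table_b: GenotypeTable,
                    labels: tuple[str, str] = ("pop1", "pop2")) -> FstResult:
    """Weir-Cockerham theta between two populations over shared sites."""
    if not table_a.sites[["chrom", "pos"]].equals(table_b.sites[["chrom", "pos"]]):
        raise ValueError("tables must carry the same site set")
    r = 2.0
    n1, p1, h1 = _pop_stats(table_a.calls)
    n2, p2, h2 = _pop_stats(table_b.calls)
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        denom = a + b + c
    # undefined: any pop unobserved, nbar <= 1, nc <= 0, or zero denominator
    bad = (~np.isfinite(denom)) | (n1 == 0) | (n2 == 0) | (nbar <= 1) | (nc <= 0)
    informative = ~bad & (denom != 0)
    if informative.sum() == 0:
        raise ValueError("no informative sites for F_ST")
    per_site = pd.DataFrame({"a": a, "b": b, "c": c})
    per_site["theta"] = np.where(informative, a / np.where(denom == 0, np.nan, denom),
                                 np.nan)
    theta = float(a[informative].sum() / denom[informative].sum())
    return FstResult(per_site, theta, int((~informative).sum()), labels)


def fst_matrix(tables: dict[str, GenotypeTable]) -> pd.DataFrame:
    """Multi-site theta for every population pair (S3-style layout)."""
    names = list(tables)
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for a, b in combinations(names, 2):
        th = pairwise_wc_fst(tables[a], tables[b], (a, b)).theta
        out.loc[a, b] = out.loc[b, a] = th
    np.fill_diagonal(out.values, 0.0)
    return out


# -------------------------------------------------------------- Mann-Whitney

@dataclass
class MannWhitneyResult:
    u: float
    z: float | None          # None when tie-corrected variance is zero
    p: float | None
    degenerate: bool = False


def mann_whitney(values_a, values_b) -> MannWhitneyResult:
    """U from midrank sums; z and two-sided p by the tie-corrected
    normal approximation."""
    x = np.asarray(values_a, float)
    y = np.asarray(values_b, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return MannWhitneyResult(u1, None, None, degenerate=True)
    z = (u1 - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return MannWhitneyResult(float(u1), float(z), float(min(p, 1.0)))


# --------------------------------------------------------------------- Mantel

@dataclass
class MantelResult:
    r: float | None
    r2: float | None
    p: float | None
    n_perm: int
    degenerate: bool = False


def mantel_test(dist1, dist2, n_perm: int = 999, seed: int = 0) -> MantelResult:
    """Pearson Mantel statistic with add-one permutation p-value.

    Permutations act simultaneously on rows and columns of ``dist2``;
    significance is two-sided on \\|r\\|.
    """
    d1 = np.asarray(dist1, float)
    d2 = np.asarray(dist2, float)
    for d in (d1, d2):
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] < 3:
            raise ValueError("distance matrices must be square, order >= 3")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ValueError("matrices must be symmetric with zero diagonal")
    if d1.shape != d2.shape:
        raise ValueError("matrices must have equal order")
    iu = np.triu_indices(d1.shape[0], 1)
    v1, v2 = d1[iu], d2[iu]
    if v1.std() == 0 or v2.std() == 0:
        return MantelResult(None, None, None, n_perm, degenerate=True)
    r_obs = float(np.corrcoef(v1, v2)[0, 1])
    rng = np.random.default_rng(seed)
    n = d1.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        v2p = d2[np.ix_(perm, perm)][iu]
        if abs(np.corrcoef(v1, v2p)[0, 1]) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return MantelResult(r_obs, r_obs ** 2, p, n_perm)


# ---------------------------------------------------------------- relatedness

class RelatednessPruner(BaseEstimator):
    """Greedy removal of close relatives from a genotype table.

    Pairwise relatedness is a moment estimator: the average over sites
    of standardized-genotype cross-products,
    ``r_jk = mean_i (g_ij - 2 p_i)(g_ik - 2 p_i) / (2 p_i (1 - p_i))``
    (pairwise-complete sites), which is ~1 on the diagonal for outbred
    samples, ~0.5 for parent-offspring and ~0 for unrelateds.  Pairs
    above ``threshold`` (default 0.25 = half-siblings) lose the member
    with more missing data; ties break toward the lexicographically
    later sample id.  Deterministic, idempotent.
    """

    def __init__(self, threshold: float = 0.25, min_maf: float = 0.05):
        self.threshold = threshold
        self.min_maf = min_maf

    def fit(self, table: GenotypeTable, y=None):
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold outside (0, 1]")
        if table.n_samples < 2:
            raise ValueError("need >= 2 samples")
        calls = table.calls.astype(float)
        calls[calls == MISSING] = np.nan
        p = np.nanmean(calls, axis=0) / 2.0
        keep = (np.minimum(p, 1 - p) >= self.min_maf) & np.isfinite(p)
        g = calls[:, keep]
        p = p[keep]
        z = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
        obs = np.isfinite(z)
        z0 = np.nan_to_num(z)
        num = z0 @ z0.T
        cnt = obs.astype(float) @ obs.astype(float).T
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num / np.maximum(cnt, 1)
        self.relatedness_ = pd.DataFrame(r, index=table.sample_ids,
                                         columns=table.sample_ids)
        n_missing = dict(zip(table.sample_ids,
                             (table.calls == MISSING).sum(axis=1)))
        alive = set(table.sample_ids)
        ids = sorted(table.sample_ids)
        for sa, sb in combinations(ids, 2):
            if sa not in alive or sb not in alive:
                continue
            if self.relatedness_.loc[sa, sb] > self.threshold:
                if n_missing[sa] > n_missing[sb]:
                    alive.discard(sa)
                elif n_missing[sb] > n_missing[sa]:
                    alive.discard(sb)
                else:
                    alive.discard(max(sa, sb))
        self.kept_ids_ = [s for s in table.sample_ids if s in alive]
        self.removed_ids_ = [s for s in table.sample_ids if s not in alive]
        return self

    def transform(self, table: GenotypeTable) -> GenotypeTable:
        return table.take_samples(self.kept_ids_)

    def fit_transform(self, table: GenotypeTable, y=None) -> GenotypeTable:
        return self.fit(table).transform(table)


def relatedness_prune(table: GenotypeTable, threshold: float = 0.25
                      ) -> tuple[pd.DataFrame, list[str]]:
    """Functional wrapper over :class:`RelatednessPruner`."""
    pruner = RelatednessPruner(threshold=threshold).fit(table)
    return pruner.relatedness_, pruner.kept_ids_


# ------------------------------------------------------------------------ PCA

def pca(matrix, standardize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """PCA of an observations x variables matrix.

    Returns (scores, proportion of variance per component).  With
    ``standardize`` the columns are z-scored and zero-variance columns
    dropped first (correlation-matrix PCA, the convention for bioclim
    variables measured in different units).
    """
    x = np.asarray(matrix, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 observations")
    if standardize:
        sd = x.std(axis=0, ddof=1)
        x = (x[:, sd > 0] - x[:, sd > 0].mean(axis=0)) / sd[sd > 0]
    model = _SkPCA(n_components=min(x.shape))
    scores = model.fit_transform(x)
    return scores, model.explained_variance_ratio_


def corr_r2(x, y) -> tuple[float, float, float, float]:
    """OLS fit of y on x: (slope, intercept, R^2, p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if x.std() == 0:
        raise ValueError("zero variance in x")
    fit = stats.linregress(x, y)
    return fit.slope, fit.intercept, fit.rvalue ** 2, fit.pvalue
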