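"""Cross-transect shared candidates and parallel allele-frequency shifts.

Overlap between candidate gene sets from independent transects is
tested against a resampling null that redraws each set (with
replacement, duplicates collapsed) from that transect's tested-gene
universe.  Parallelism asks whether the allele-frequency shift between
the extreme-latitude end populations of each transect points the same
way in all transects, gene by gene, against the analytic 25% null for
three transects (two equiprobable directions agreeing across three
independent draws: 2 / 2^3) and a gene-resampling permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MISSING, GenotypeTable
from .popstructure import allele_frequencies


@dataclass
class OverlapTestResult:
    observed: int
    null_mean: float
    null_sd: float
    z: float | None          # None when the null s.d. is zero
    p: float                 # add-one empirical, alternative "greater"
    n_replicates: int


def _draw_distinct(rng: np.random.Generator, universe: np.ndarray,
                   k: int) -> np.ndarray:
    return np.unique(rng.choice(universe, size=k, replace=True))


def overlap_permutation_test(set_a, set_b, universe_a, universe_b,
                             n_replicates: int = 100_000, seed: int = 0,
                             set_c=None, universe_c=None) -> OverlapTestResult:
    """Permutation test for candidate-set overlap (two- or three-way).

    Each replicate redraws every set from its own universe, uniformly
    with replacement (duplicate draws collapse), and records the size
    of the intersection.
    """
    sets = [set(set_a), set(set_b)]
    universes = [np.asarray(sorted(universe_a)), np.asarray(sorted(universe_b))]
    if set_c is not None:
        sets.append(set(set_c))
        universes.append(np.asarray(sorted(universe_c)))
    for s, u in zip(sets, universes):
        if not s <= set(u):
            raise ValueError("candidate set not contained in its universe")
    observed = len(set.intersection(*sets))
    rng = np.random.default_rng(seed)
    null = np.empty(n_replicates)
    for i in range(n_replicates):
        drawn = [_draw_distinct(rng, u, len(s)) for s, u in zip(sets, universes)]
        inter = drawn[0]
        for d in drawn[1:]:
            inter = np.intersect1d(inter, d, assume_unique=True)
        null[i] = inter.size
    mean, sd = float(null.mean()), float(null.std())
    z = (observed - mean) / sd if sd > 0 else None
    p = (1 + int((null >= observed).sum())) / (n_replicates + 1)
    return OverlapTestResult(observed, mean, sd, z, p, n_replicates)


# ------------------------------------------------------------- directions

def shift_directions(end_low: GenotypeTable, end_high: GenotypeTable,
                     shared_snps, min_call_fraction: float = 0.6
                     ) -> pd.DataFrame:
    """Direction of the alt-allele frequency shift from the low-latitude
    to the high-latitude end population, per shared SNP.

    direction = sign(freq_high - freq_low) in {"up", "down", "none"};
    "none" when the frequencies are equal or either end population
    fails the 60% call-fraction rule.  SNPs whose ref/alt are swapped
    between the two tables are re-polarized by flipping dosage; SNPs
    with different alleles or absent from a table are excluded (column
    ``excluded`` True).
    """
    f_low = allele_frequencies(end_low, min_call_fraction).set_index("site")
    f_high = allele_frequencies(end_high, min_call_fraction).set_index("site")
    alle_low = end_low.sites.assign(site=end_low.site_ids).set_index("site")
    alle_high = end_high.sites.assign(site=end_high.site_ids).set_index("site")
    rows = []
    for snp in shared_snps:
        if snp not in f_low.index or snp not in f_high.index:
            rows.append({"site": snp, "freq_low": np.nan, "freq_high": np.nan,
                         "direction": "none", "excluded": True})
            continue
        a_lo, a_hi = alle_low.loc[snp], alle_high.loc[snp]
        flo = float(f_low.loc[snp, "freq"])
        fhi = float(f_high.loc[snp, "freq"])
        if (a_lo["ref"], a_lo["alt"]) == (a_hi["alt"], a_hi["ref"]):
            fhi = 1.0 - fhi           # swapped polarization: flip dosage
        elif (a_lo["ref"], a_lo["alt"]) != (a_hi["ref"], a_hi["alt"]):
            rows.append({"site": snp, "freq_low": np.nan, "freq_high": np.nan,
                         "direction": "none", "excluded": True})
            continue
        ok = not (f_low.loc[snp, "excluded"] or f_high.loc[snp, "excluded"])
        if not ok or fhi == flo:
            direction = "none"
        else:
            direction = "up" if fhi > flo else "down"
        rows.append({"site": snp, "freq_low": flo, "freq_high": fhi,
                     "direction": direction, "excluded": not ok})
    return pd.DataFrame(rows)


def extreme_latitude_tables(table: GenotypeTable, samples: pd.DataFrame
                            ) -> tuple[GenotypeTable, GenotypeTable]:
    """Split out the minimum- and maximum-|latitude| end populations."""
    pops = samples.groupby("population")["latitude"].mean().abs()
    low_pop, high_pop = pops.idxmin(), pops.idxmax()
    ids_low = samples.loc[samples["population"] == low_pop, "sample_id"]
    ids_high = samples.loc[samples["population"] == high_pop, "sample_id"]
    return table.take_samples(list(ids_low)), table.take_samples(list(ids_high))


def gene_parallel_calls(direction_tables: dict[str, pd.DataFrame],
                        assignment: pd.DataFrame,
                        rule: str = "all") -> pd.DataFrame:
    """Per-gene concordance across transects.

    A SNP is evaluable when its direction is not "none" in any transect.
    Under the default conjunction rule a gene is concordant iff every
    evaluable SNP in it has the same direction in all transects
    (``rule`` in {"all", "any", "majority"}).  Genes with no evaluable
    SNP are omitted.
    """
    if rule not in ("all", "any", "majority"):
        raise ValueError(f"unknown rule {rule!r}")
    if len(direction_tables) < 2:
        raise ValueError("need >= 2 transects")
    merged: pd.DataFrame | None = None
    for t, df in direction_tables.items():
        cur = df[["site", "direction"]].rename(columns={"direction": t})
        merged = cur if merged is None else merged.merge(cur, on="site")
    tcols = list(direction_tables)
    evaluable = merged[(merged[tcols] != "none").all(axis=1)]
    gene_of = assignment.dropna(subset=["gene_id"])[["site", "gene_id"]]
    joined = evaluable.merge(gene_of, on="site")
    rows = []
    for gene, grp in joined.groupby("gene_id"):
        per_snp = (grp[tcols].nunique(axis=1) == 1).to_numpy()
        n_total = len(per_snp)
        n_conc = int(per_snp.sum())
        if rule == "all":
            flag = n_conc == n_total
        elif rule == "any":
            flag = n_conc >= 1
        else:
            flag = n_conc * 2 > n_total
        rows.append({"gene_id": gene, "n_snps": n_total,
                     "n_concordant_snps": n_conc, "concordant": flag})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- tests

def parallel_chisq(n_parallel: int, n_total: int,
                   expected_fraction: float = 0.25) -> tuple[float, float, bool]:
    """1-d.f. chi-square of observed parallel genes against the
    analytic null fraction; returns (chi2, upper-tail p, small-sample
    warning when an expected cell < 1)."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    e1 = n_total * expected_fraction
    e2 = n_total * (1 - expected_fraction)
    chi2 = (n_parallel - e1) ** 2 / e1 + ((n_total - n_parallel) - e2) ** 2 / e2
    p = float(stats.chi2.sf(chi2, 1))
    return float(chi2), p, bool(min(e1, e2) < 1)


def expected_parallel_fraction(n_transects: int = 3) -> float:
    """Probability that independent equiprobable up/down shifts agree
    across all transects: 2 / 2^n (25% for three transects)."""
    return 2.0 / (2 ** n_transects)


@dataclass
class ParallelPermutationResult:
    observed: int
    null_mean: float
    null_sd: float
    cutoff_95: float
    z: float | None
    p: float
    n_iterations: int
    seed: int


def parallel_permutation(concordant_flags, n_select: int,
                         observed: int | None = None,
                         n_iter: int = 1000, seed: int = 0
                         ) -> ParallelPermutationResult:
    """Resampling null for the count of concordant genes.

    Each iteration draws ``n_select`` genes with replacement from the
    genome-wide universe of genes with shared SNPs (their concordance
    flags given) and counts the concordant ones.  ``observed`` defaults
    to n_select (all selected genes parallel) if not supplied.
    """
    flags = np.asarray(concordant_flags, bool)
    if flags.size < n_select:
        raise ValueError("universe smaller than n_select")
    if observed is None:
        observed = int(flags.sum())
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, flags.size, size=(n_iter, n_select))
    null = flags[draws].sum(axis=1)
    mean, sd = float(null.mean()), float(null.std())
    z = (observed - mean) / sd if sd > 0 else None
    p = (1 + int((null >= observed).sum())) / (n_iter + 1)
    cutoff = float(np.quantile(null, 0.95))
    return ParallelPermutationResult(observed, mean, sd, cutoff, z, p,
                                     n_iter, seed)
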