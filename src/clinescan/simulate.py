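"""Synthetic multi-transect exome datasets.

Emulates the sampling design the analysis assumes: several latitudinal
transects, each a chain of populations whose allele frequencies drift
around shared ancestral frequencies under the Balding-Nichols model,
with a subset of sites whose frequencies are clinal in the environmental
gradient, block LD created by leader-copying, uniform genotype
missingness, and a polygenic sex-affected body-weight phenotype.

Genotype matrices share one site index across transects, so SNP
identity (chrom, pos, ref, alt) is directly comparable between
transects, as it is for variants called against one reference genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, GeneAnnotation, GenotypeTable

_BASES = np.array(list("ACGT"))


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class WeightModel:
    """Additive body-weight model, units grams (wild adult house mice)."""

    intercept: float = 14.0        # g, baseline adult female weight
    sex_effect: float = 2.5        # g, added for males
    n_causal: int = 10             # sites with a direct effect
    causal_effect: float = 0.5     # g per alternate allele at each causal site
    polygenic_sd: float = 1.0      # g, sd of the standardized-burden term
    residual_sd: float = 1.5       # g, environmental noise


@dataclass
class EnvSpec:
    """Per-transect latitude range and the latitude->climate maps.

    MAT (mean annual temperature, deg C) is a noisy linear function of
    distance from the equator; PDM (precipitation of the driest month,
    mm) is drawn independently per population, with transect-specific
    ranges that barely overlap.
    """

    latitude_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "SA": (-55.0, -3.0),
            "ENA": (26.0, 45.0),
            "WNA": (32.0, 54.0),
        }
    )
    mat_intercept: float = 25.0    # deg C at the equator
    mat_slope: float = -0.42       # deg C per degree of |latitude|
    mat_noise_sd: float = 1.0
    pdm_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "SA": (20.0, 120.0),
            "ENA": (60.0, 100.0),
            "WNA": (5.0, 40.0),
        }
    )


@dataclass
class SimConfig:
    """Knobs of the synthetic world; defaults mirror the field design
    (six populations of ~9 mice per transect, three transects) at a
    desk-scale number of sites."""

    n_transects: int = 3
    populations_per_transect: int = 6
    samples_per_population: int = 9
    n_sites: int = 4000
    n_genes: int = 400
    exons_per_gene: int = 4
    go_terms: int = 40
    n_chromosomes: int = 5
    drift_F: float = 0.1
    clinal_fraction: float = 0.05
    clinal_slope: float = 1.5
    shared_clinal_fraction: float = 0.5
    ld_block_span: int = 50_000
    ld_copy_prob: float = 0.5
    missing_rate: float = 0.05
    juvenile_fraction: float = 0.1
    env_spec: EnvSpec = field(default_factory=EnvSpec)
    weight_model: WeightModel = field(default_factory=WeightModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("clinal_fraction", "shared_clinal_fraction", "ld_copy_prob",
                     "missing_rate", "juvenile_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.drift_F < 1.0:
            raise ValueError("drift_F must lie in (0, 1)")
        if self.n_sites < self.n_genes:
            raise ValueError("need n_sites >= n_genes")

    def transect_names(self) -> list[str]:
        names = list(self.env_spec.latitude_ranges)
        while len(names) < self.n_transects:
            names.append(f"T{len(names) + 1}")
        return names[: self.n_transects]


@dataclass
class Truth:
    """Ground truth carried alongside a synthetic dataset."""

    clinal_sites: dict[str, set[str]]          # transect -> site ids
    shared_clinal_genes: set[str]
    transect_clinal_genes: dict[str, set[str]]  # includes shared genes
    causal_weight_sites: dict[str, float]       # site id -> effect (g/allele)


@dataclass
class SyntheticDataset:
    genotypes: dict[str, GenotypeTable]
    samples: dict[str, pd.DataFrame]
    genes: list[GeneAnnotation]
    go_map: dict[str, set[str]]
    truth: Truth
    config: SimConfig


# ---------------------------------------------------------------------------

def _build_genes(cfg: SimConfig) -> list[GeneAnnotation]:
    """Lay genes on chromosomes: fixed exon/intron geometry, 10 kb gaps."""
    exon_len, intron_len, gap = 600, 900, 10_000
    genes = []
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chromosomes))
    g = 0
    for c in range(cfg.n_chromosomes):
        pos = 5_000
        for _ in range(per_chrom):
            if g >= cfg.n_genes:
                break
            exons = []
            s = pos
            for e in range(cfg.exons_per_gene):
                exons.append((s, s + exon_len - 1))
                s += exon_len + intron_len
            end = exons[-1][1]
            genes.append(
                GeneAnnotation(f"g{g:04d}", f"chr{c + 1}", pos, end, exons, "+")
            )
            pos = end + gap
            g += 1
    return genes


def _place_sites(cfg: SimConfig, genes: list[GeneAnnotation],
                 rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
    """Scatter sites over gene spans (plus 2 kb flanks), >= 1 per gene.

    Returns the site table and, for each site, the index of its host
    gene (the gene whose extended span it was drawn in).
    """
    flank = 2_000
    gene_of_site = np.concatenate([
        np.arange(cfg.n_genes),
        rng.integers(0, cfg.n_genes, cfg.n_sites - cfg.n_genes),
    ])
    chosen: set[tuple[str, int]] = set()
    rows, host = [], []
    for gi in gene_of_site:
        gene = genes[gi]
        for _ in range(50):
            pos = int(rng.integers(gene.start - flank, gene.end + flank + 1))
            key = (gene.chrom, pos)
            if key not in chosen and pos > 0:
                chosen.add(key)
                rows.append(key)
                host.append(gi)
                break
    sites = pd.DataFrame(rows, columns=["chrom", "pos"])
    ref = _BASES[rng.integers(0, 4, len(sites))]
    alt_shift = rng.integers(1, 4, len(sites))
    alt = _BASES[(np.searchsorted(_BASES, ref) + alt_shift) % 4]
    sites["ref"], sites["alt"] = ref, alt
    sites["host_gene"] = host
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    return sites[["chrom", "pos", "ref", "alt"]], sites["host_gene"].to_numpy()


def _ld_structure(cfg: SimConfig, sites: pd.DataFrame,
                  rng: np.random.Generator) -> np.ndarray:
    """leader[j] = index of the site j copies, or j itself.

    Windows of ``ld_block_span`` are tiled from position 1 on each
    chromosome; the first site in a window leads it and each later site
    echoes the leader with probability ``ld_copy_prob``.
    """
    leader = np.arange(len(sites))
    win = (sites["pos"].to_numpy() - 1) // cfg.ld_block_span
    keys = pd.DataFrame({"chrom": sites["chrom"], "win": win})
    for _, grp in keys.groupby(["chrom", "win"], sort=False):
        idx = grp.index.to_numpy()
        head = idx[0]
        for j in idx[1:]:
            if rng.random() < cfg.ld_copy_prob:
                leader[j] = head
    return leader


def _assign_clinal(cfg: SimConfig, host_gene: np.ndarray,
                   rng: np.random.Generator,
                   genes: list[GeneAnnotation]) -> tuple[set, dict, dict, dict]:
    """Pick clinal genes until ~clinal_fraction of sites carry an effect."""
    target = cfg.clinal_fraction * cfg.n_sites
    gene_site_counts = np.bincount(host_gene, minlength=cfg.n_genes)
    order = rng.permutation(cfg.n_genes)
    clinal_gene_idx: list[int] = []
    total = 0
    for gi in order:
        if total >= target:
            break
        if gene_site_counts[gi] == 0:
            continue
        clinal_gene_idx.append(int(gi))
        total += int(gene_site_counts[gi])
    n_shared = int(round(cfg.shared_clinal_fraction * len(clinal_gene_idx)))
    shared = set(clinal_gene_idx[:n_shared])
    rest = clinal_gene_idx[n_shared:]
    transects = cfg.transect_names()
    per_transect: dict[str, set[int]] = {t: set(shared) for t in transects}
    for k, gi in enumerate(rest):
        per_transect[transects[k % len(transects)]].add(gi)
    sign = {gi: (1.0 if rng.random() < 0.5 else -1.0) for gi in clinal_gene_idx}
    shared_names = {genes[gi].gene_id for gi in shared}
    name_map = {t: {genes[gi].gene_id for gi in gs} for t, gs in per_transect.items()}
    return shared_names, per_transect, sign, name_map


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Draw a full multi-transect dataset; deterministic given the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = _build_genes(cfg)
    sites, host_gene = _place_sites(cfg, genes, rng)
    m = len(sites)
    leader = _ld_structure(cfg, sites, rng)
    shared_genes, clinal_by_transect, gene_sign, clinal_names = _assign_clinal(
        cfg, host_gene, rng, genes
    )

    p_anc = rng.uniform(0.05, 0.95, m)
    transects = cfg.transect_names()
    lat_ranges = cfg.env_spec.latitude_ranges
    n_pop, n_per = cfg.populations_per_transect, cfg.samples_per_population

    genotypes: dict[str, GenotypeTable] = {}
    sample_tables: dict[str, pd.DataFrame] = {}
    clinal_sites: dict[str, set[str]] = {}
    site_ids = (sites["chrom"].astype(str) + ":" + sites["pos"].astype(str)).to_numpy()

    for t in transects:
        lo, hi = lat_ranges.get(t, (25.0, 50.0))
        lats = np.linspace(lo, hi, n_pop)
        env_z = np.abs(lats)
        env_z = (env_z - env_z.mean()) / env_z.std()
        mats = (cfg.env_spec.mat_intercept
                + cfg.env_spec.mat_slope * np.abs(lats)
                + rng.normal(0, cfg.env_spec.mat_noise_sd, n_pop))
        plo, phi = cfg.env_spec.pdm_ranges.get(t, (10.0, 100.0))
        pdms = rng.uniform(plo, phi, n_pop)

        effect = np.zeros(m)
        my_clinal = clinal_by_transect[t]
        for j in range(m):
            gi = host_gene[j]
            if gi in my_clinal:
                effect[j] = cfg.clinal_slope * gene_sign[gi]

        calls = np.empty((n_pop * n_per, m), dtype=np.int16)
        rows = []
        for pi in range(n_pop):
            mu = _logit(np.clip(p_anc, 1e-6, 1 - 1e-6)) + effect * env_z[pi]
            base = _expit(mu)
            if cfg.drift_F > 1e-6:
                a = base * (1 - cfg.drift_F) / cfg.drift_F
                b = (1 - base) * (1 - cfg.drift_F) / cfg.drift_F
                p_pop = rng.beta(np.maximum(a, 1e-8), np.maximum(b, 1e-8))
            else:
                p_pop = base
            calls[pi * n_per:(pi + 1) * n_per] = rng.binomial(
                2, p_pop, size=(n_per, m)
            ).astype(np.int16)
            pop_name = f"{t}P{pi + 1}"
            for k in range(n_per):
                rows.append({
                    "sample_id": f"{t}_{pop_name}_{k + 1:02d}",
                    "population": pop_name,
                    "transect": t,
                    "sex": "M" if rng.random() < 0.5 else "F",
                    "latitude": lats[pi],
                    "LAT": abs(lats[pi]),
                    "MAT": mats[pi],
                    "PDM": pdms[pi],
                    "age_class": "juvenile" if rng.random() < cfg.juvenile_fraction
                                 else "adult",
                    "reproductive_status": "inactive",
                })
        # LD: copier columns echo their leader (pre-missingness)
        copiers = np.nonzero(leader != np.arange(m))[0]
        calls[:, copiers] = calls[:, leader[copiers]]
        if cfg.missing_rate > 0:
            mask = rng.random(calls.shape) < cfg.missing_rate
            calls[mask] = MISSING
        samples = pd.DataFrame(rows)
        genotypes[t] = GenotypeTable(samples["sample_id"].tolist(), sites.copy(), calls)
        sample_tables[t] = samples
        # truth: a site is clinal if the column it realized carries an effect
        realized = effect[leader] != 0.0
        clinal_sites[t] = set(site_ids[realized])

    # LD copying can leave a designated clinal gene with no realized clinal
    # site (every site echoes a neutral leader); restrict the truth gene
    # sets to genes that actually contain a realized clinal site, so that
    # downstream recovery checks target attainable genes.
    pos_arr = sites["pos"].to_numpy()
    in_span = np.array([
        genes[gi].start <= p <= genes[gi].end
        for gi, p in zip(host_gene, pos_arr)
    ])
    for t in transects:
        realized_ids = clinal_sites[t]
        realized_mask = np.isin(site_ids, list(realized_ids))
        genes_with_signal = {
            genes[gi].gene_id
            for gi in np.unique(host_gene[realized_mask & in_span])
        }
        clinal_names[t] = clinal_names[t] & genes_with_signal
    shared_genes = set.intersection(*(clinal_names[t] for t in transects)) \
        & shared_genes if transects else set()

    go_map: dict[str, set[str]] = {}
    terms = [f"GO:{i + 1:07d}" for i in range(cfg.go_terms)]
    for g in genes:
        k = int(rng.integers(1, 4))
        go_map[g.gene_id] = set(rng.choice(terms, size=k, replace=False))

    causal = _pick_causal_sites(cfg, site_ids, rng)
    truth = Truth(clinal_sites, shared_genes, clinal_names, causal)
    ds = SyntheticDataset(genotypes, sample_tables, genes, go_map, truth, cfg)
    simulate_body_weight(ds, cfg, rng)
    return ds


def _pick_causal_sites(cfg: SimConfig, site_ids: np.ndarray,
                       rng: np.random.Generator) -> dict[str, float]:
    wm = cfg.weight_model
    idx = rng.choice(len(site_ids), size=min(wm.n_causal, len(site_ids)),
                     replace=False)
    signs = np.where(rng.random(len(idx)) < 0.5, 1.0, -1.0)
    return {site_ids[i]: wm.causal_effect * s for i, s in zip(idx, signs)}


def simulate_body_weight(dataset: SyntheticDataset, config: SimConfig,
                         rng: np.random.Generator | None = None) -> None:
    """Fill the ``body_weight`` column of every transect's sample table.

    weight = intercept + sex_effect*[male] + sum(beta_j * dosage_j)
           + polygenic burden + Gaussian noise.
    Missing causal dosages are replaced by the population-mean dosage.
    The polygenic term is a random linear combination of standardized
    genotypes over all sites, scaled to ``polygenic_sd``.
    """
    wm = config.weight_model
    if rng is None:
        rng = np.random.default_rng(config.seed + 777)
    any_table = next(iter(dataset.genotypes.values()))
    m = any_table.n_sites
    poly_w = rng.normal(0.0, 1.0, m)
    poly_w *= wm.polygenic_sd / np.sqrt(m)

    for t, table in dataset.genotypes.items():
        samples = dataset.samples[t]
        ids = table.site_ids
        causal_idx = [ids.get_loc(s) for s in dataset.truth.causal_weight_sites
                      if s in ids]
        betas = np.array([dataset.truth.causal_weight_sites[ids[i]]
                          for i in causal_idx])
        G = table.calls.astype(float)
        G[G == MISSING] = np.nan
        col_mean = np.nanmean(np.where(np.isnan(G), np.nan, G), axis=0)
        col_mean = np.nan_to_num(col_mean)
        Gimp = np.where(np.isnan(G), col_mean, G)
        direct = Gimp[:, causal_idx] @ betas if causal_idx else 0.0
        sd = np.std(Gimp, axis=0)
        sd[sd == 0] = 1.0
        Z = (Gimp - col_mean) / sd
        poly = Z @ poly_w
        male = (samples["sex"] == "M").to_numpy(float)
        noise = rng.normal(0.0, wm.residual_sd, table.n_samples)
        samples["body_weight"] = (wm.intercept + wm.sex_effect * male
                                  + direct + poly + noise)


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write per-transect VCF + metadata TSV, gene BED, GO TSV, truth TSV."""
    from pathlib import Path

    from . import io as cio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for t, table in dataset.genotypes.items():
        cio.write_vcf(table, outdir / f"{t}.vcf")
        cio.write_sample_table(dataset.samples[t], outdir / f"{t}.samples.tsv")
    cio.write_gene_bed(dataset.genes, outdir / "genes.bed")
    cio.write_go_map(dataset.go_map, outdir / "go_map.tsv")
    rows = []
    for t, ss in dataset.truth.clinal_sites.items():
        rows += [("clinal_site", t, s) for s in sorted(ss)]
    rows += [("shared_clinal_gene", "*", g)
             for g in sorted(dataset.truth.shared_clinal_genes)]
    rows += [("causal_weight_site", "*", f"{s}={b:+.3f}")
             for s, b in sorted(dataset.truth.causal_weight_sites.items())]
    pd.DataFrame(rows, columns=["kind", "transect", "value"]).to_csv(
        outdir / "truth.tsv", sep="\t", index=False
    )
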