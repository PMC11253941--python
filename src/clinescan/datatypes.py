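"""Core in-memory containers shared by every pipeline stage.

Genotypes are stored as an integer dosage matrix (samples x sites) with
values in {0, 1, 2} counting copies of the alternate allele and ``MISSING``
(-1) for no-calls.  All genomic coordinates are 1-based inclusive
(VCF/GFF convention); BED input/output converts at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for a missing genotype call
MISSING: int = -1

SITE_COLUMNS = ("chrom", "pos", "ref", "alt")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenotypeTable:
    """Samples x biallelic-SNP dosage matrix with site metadata.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per matrix row.
    sites
        DataFrame with columns ``chrom, pos, ref, alt``; positions are
        1-based and strictly increasing within each chromosome.
    calls
        ``(n_samples, n_sites)`` integer array with entries in
        {0, 1, 2, MISSING}.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        self.sites = self.sites.reset_index(drop=True)
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        missing_cols = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing_cols:
            raise ValueError(f"site table lacks columns {missing_cols}")
        if self.calls.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"invalid genotype codes {bad}")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {chrom}")
        keys = list(zip(self.sites["chrom"], self.sites["pos"]))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, pos) site keys")

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> pd.Index:
        return pd.Index(
            self.sites["chrom"].astype(str) + ":" + self.sites["pos"].astype(str)
        )

    def take_samples(self, ids: list[str]) -> "GenotypeTable":
        order = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [order[s] for s in ids]
        return GenotypeTable(list(ids), self.sites.copy(), self.calls[idx])

    def take_sites(self, index: np.ndarray) -> "GenotypeTable":
        index = np.asarray(index)
        return GenotypeTable(
            list(self.sample_ids),
            self.sites.iloc[index].reset_index(drop=True),
            self.calls[:, index],
        )


@dataclass
class GeneAnnotation:
    """A gene model: 1-based inclusive span plus exon intervals.

    ``cds_start``/``cds_end`` delimit the coding span inside the exons;
    when None the whole exonic extent is treated as coding.  ``coding``
    False marks non-coding transcripts (their exonic SNPs fall in the
    non-coding-exon consequence class).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    strand: str = "+"
    coding: bool = True
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: degenerate span {self.start}..{self.end}")
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: degenerate exon {s}..{e}")
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon {s}..{e} outside gene span")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            self.exons = [(self.start, self.end)]


# GoMap: gene_id -> set of GO term ids; genes absent from the map have
# empty term sets by convention (use .get(g, set())).
GoMap = dict


def sample_table_schema() -> list[str]:
    """Required columns of a per-sample metadata table."""
    return ["sample_id", "population", "transect", "sex", "latitude"]


def check_sample_table(samples: pd.DataFrame, genotypes: GenotypeTable | None = None) -> None:
    """Validate a SampleTable DataFrame against its invariants."""
    for col in sample_table_schema():
        if col not in samples.columns:
            raise ValueError(f"sample table lacks required column {col!r}")
    if samples["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample table")
    if genotypes is not None:
        known = set(samples["sample_id"])
        absent = [s for s in genotypes.sample_ids if s not in known]
        if absent:
            raise ValueError(f"genotype samples without metadata: {absent[:5]}")
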