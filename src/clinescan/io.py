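"""Readers and writers for the formats the pipeline touches.

VCF reading goes through cyvcf2; only biallelic SNP records with GT
fields are accepted (multi-allelic or non-SNP records are skipped and
counted).  VCF writing emits minimal GT-only v4.2 text.  Gene models
arrive as BED (0-based half-open) and are converted to the internal
1-based inclusive convention at the boundary.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import (
    MISSING,
    FormatError,
    GeneAnnotation,
    GenotypeTable,
    check_sample_table,
)

logger = logging.getLogger(__name__)

# cyvcf2 gt_types codes: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
_GT_TYPE_TO_DOSAGE = np.array([0, 1, MISSING, 2], dtype=np.int16)


def read_vcf(path: str | Path) -> GenotypeTable:
    """Read a VCF into a :class:`GenotypeTable`.

    Phased separators are accepted and treated as unphased (only dosage
    is retained).  Returns a table whose ``skipped_records`` attribute
    counts multi-allelic / non-SNP records that were dropped.
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises OSError on malformed headers
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no samples in header")
    rows = []
    cols = []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            skipped += 1
            continue
        dosage = _GT_TYPE_TO_DOSAGE[rec.gt_types]
        if dosage.shape[0] != len(samples):
            raise FormatError(
                f"{path}: record {rec.CHROM}:{rec.POS} has "
                f"{dosage.shape[0]} genotypes for {len(samples)} samples"
            )
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        cols.append(dosage)
    if skipped:
        logger.info("read_vcf(%s): skipped %d non-biallelic-SNP records", path, skipped)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    calls = (
        np.array(cols, dtype=np.int16).T
        if cols
        else np.empty((len(samples), 0), dtype=np.int16)
    )
    table = GenotypeTable(samples, sites, calls)
    table.skipped_records = skipped
    return table


_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(table: GenotypeTable, path: str | Path) -> None:
    """Write a GT-only VCF v4.2; missing calls become ``./.``."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(table.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.sample_ids)
            + "\n"
        )
        sites = table.sites
        for j in range(table.n_sites):
            gts = "\t".join(_DOSAGE_TO_GT[int(d)] for d in table.calls[:, j])
            fh.write(
                f"{sites.at[j, 'chrom']}\t{sites.at[j, 'pos']}\t.\t"
                f"{sites.at[j, 'ref']}\t{sites.at[j, 'alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_gene_bed(path: str | Path) -> list[GeneAnnotation]:
    """Read gene models from a BED-like file.

    Columns: chrom, start, end, gene_id[, strand] in 0-based half-open
    coordinates.  Optional companion exon rows use gene_id suffixed with
    ``.exon`` and attach to the matching gene.  BED start 999 / end 1000
    becomes the internal inclusive span 1000..1000.
    """
    genes: dict[str, GeneAnnotation] = {}
    exon_rows: dict[str, list[tuple[int, int]]] = defaultdict(list)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected >= 4 BED columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start >= end:
                raise FormatError(f"{path}:{ln}: BED start {start} >= end {end}")
            strand = parts[4] if len(parts) > 4 and parts[4] in ("+", "-") else "+"
            if name.endswith(".exon"):
                exon_rows[name[: -len(".exon")]].append((start + 1, end))
            else:
                if name in genes:
                    raise FormatError(f"{path}:{ln}: duplicate gene id {name!r}")
                genes[name] = GeneAnnotation(name, chrom, start + 1, end, [], strand)
    out = []
    for name, gene in genes.items():
        if name in exon_rows:
            gene.exons = sorted(exon_rows.pop(name))
        out.append(gene)
    if exon_rows:
        raise FormatError(f"{path}: exon rows for unknown genes {sorted(exon_rows)}")
    return out


def write_gene_bed(genes: list[GeneAnnotation], path: str | Path) -> None:
    """Inverse of :func:`read_gene_bed` (1-based inclusive -> BED)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t{g.strand}\n")
            for s, e in g.exons:
                fh.write(f"{g.chrom}\t{s - 1}\t{e}\t{g.gene_id}.exon\t{g.strand}\n")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata from a header-rowed TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str})
    check_sample_table(df)
    return df


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """Read a gene->GO mapping TSV with columns gene_id, go_term."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "go_term"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns gene_id, go_term")
    if (df["go_term"].fillna("") == "").any():
        raise FormatError(f"{path}: empty GO term identifiers")
    out: dict[str, set[str]] = defaultdict(set)
    for gene, term in zip(df["gene_id"], df["go_term"]):
        out[gene].add(term)
    return dict(out)


def write_go_map(go: dict[str, set[str]], path: str | Path) -> None:
    rows = [(g, t) for g in sorted(go) for t in sorted(go[g])]
    pd.DataFrame(rows, columns=["gene_id", "go_term"]).to_csv(path, sep="\t", index=False)
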