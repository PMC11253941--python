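"""SNP-to-gene assignment and functional-consequence classification.

The six-class priority scheme (lower ordinal wins when a SNP carries
several labels):

  1 missense / stop-lost / stop-gained
  2 3' or 5' UTR
  3 synonymous
  4 non-coding exon or non-coding transcript
  5 intron or splice site
  6 upstream or downstream

The built-in annotator replaces an external effect predictor: it reads
the frame off the gene model's exon order and strand, reconstructs the
SNP's codon with a deterministic per-gene pseudo-sequence, and
translates ref vs alt with the standard genetic code.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pyranges as pr

from .datatypes import GeneAnnotation
from .scan import ScanResult

CONSEQUENCE_CLASSES = {
    "missense": 1, "stop_lost": 1, "stop_gained": 1,
    "utr3": 2, "utr5": 2,
    "synonymous": 3,
    "noncoding_exon": 4, "noncoding_transcript": 4,
    "intron": 5, "splice": 5,
    "upstream": 6, "downstream": 6,
}

CLASS_LABELS = {
    1: "missense/stop", 2: "UTR", 3: "synonymous",
    4: "non-coding exon", 5: "intron/splice", 6: "up/downstream",
}

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def classify_consequence(labels) -> int:
    """Highest-priority (lowest ordinal) class among the labels."""
    labels = list(labels)
    if not labels:
        raise ValueError("at least one consequence label required")
    ordinals = []
    for lab in labels:
        key = str(lab).lower()
        if key not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unrecognized consequence label {lab!r}")
        ordinals.append(CONSEQUENCE_CLASSES[key])
    return min(ordinals)


# ------------------------------------------------------------------ mapping

def map_snps_to_genes(sites: pd.DataFrame, genes: list[GeneAnnotation],
                      mode: str = "gene_body") -> pd.DataFrame:
    """Assign SNPs to genes by interval overlap (inclusive boundaries).

    ``mode='gene_body'`` overlaps full gene spans; ``'exon_only'``
    restricts to exon intervals (the enrichment convention).  A SNP may
    map to several overlapping genes; unmapped SNPs appear with
    ``gene_id`` NaN.  Columns: site, chrom, pos, gene_id.
    """
    if mode not in ("gene_body", "exon_only"):
        raise ValueError(f"unknown mode {mode!r}")
    snp_df = pd.DataFrame({
        "Chromosome": sites["chrom"].astype(str),
        "Start": sites["pos"].astype(int) - 1,
        "End": sites["pos"].astype(int),
        "site": sites["chrom"].astype(str) + ":" + sites["pos"].astype(str),
        "pos": sites["pos"].astype(int),
    })
    rows = []
    for g in genes:
        spans = [(g.start, g.end)] if mode == "gene_body" else g.exons
        for s, e in spans:
            rows.append((g.chrom, s - 1, e, g.gene_id))
    if rows:
        gene_df = pd.DataFrame(rows,
                               columns=["Chromosome", "Start", "End", "gene_id"])
        joined = pr.PyRanges(snp_df).join(pr.PyRanges(gene_df)).df
    else:
        joined = pd.DataFrame()
    if len(joined):
        hits = joined[["site", "Chromosome", "pos", "gene_id"]].rename(
            columns={"Chromosome": "chrom"})
        hits = hits.drop_duplicates(["site", "gene_id"])
    else:
        hits = pd.DataFrame(columns=["site", "chrom", "pos", "gene_id"])
    unmapped = snp_df.loc[~snp_df["site"].isin(hits["site"]),
                          ["site", "Chromosome", "pos"]].rename(
        columns={"Chromosome": "chrom"})
    unmapped["gene_id"] = np.nan
    frames = [df for df in (hits, unmapped) if len(df)]
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=["site", "chrom", "pos", "gene_id"]))
    out["chrom"] = out["chrom"].astype(str)
    return out.sort_values(["chrom", "pos", "gene_id"]).reset_index(drop=True)


# --------------------------------------------------- synthetic consequences

def _gene_base(gene_id: str, offset: int) -> str:
    """Deterministic pseudo-base at a coding offset of a gene (stable
    across processes; Python's builtin hash is salted)."""
    h = zlib.crc32(f"{gene_id}:{offset}".encode())
    return "ACGT"[h & 3]


def _coding_offset(gene: GeneAnnotation, pos: int) -> int | None:
    """0-based offset of ``pos`` in the spliced CDS, or None if intronic."""
    cds_s = gene.cds_start or gene.start
    cds_e = gene.cds_end or gene.end
    offset = 0
    for s, e in sorted(gene.exons):
        lo, hi = max(s, cds_s), min(e, cds_e)
        if lo > hi:
            continue
        if lo <= pos <= hi:
            off = offset + (pos - lo)
            if gene.strand == "-":
                total = sum(min(e2, cds_e) - max(s2, cds_s) + 1
                            for s2, e2 in gene.exons
                            if max(s2, cds_s) <= min(e2, cds_e))
                off = total - 1 - off
            return off
        offset += hi - lo + 1
    return None


def annotate_site(chrom: str, pos: int, ref: str, alt: str,
                  gene: GeneAnnotation, flank: int = 5_000) -> list[str]:
    """Consequence labels of one SNP with respect to one gene model."""
    labels: list[str] = []
    if pos < gene.start or pos > gene.end:
        if gene.start - flank <= pos < gene.start:
            labels.append("upstream" if gene.strand == "+" else "downstream")
        elif gene.end < pos <= gene.end + flank:
            labels.append("downstream" if gene.strand == "+" else "upstream")
        return labels
    in_exon = any(s <= pos <= e for s, e in gene.exons)
    if not in_exon:
        return ["intron"]
    if not gene.coding:
        return ["noncoding_exon"]
    cds_s = gene.cds_start or gene.start
    cds_e = gene.cds_end or gene.end
    if pos < cds_s:
        return ["utr5" if gene.strand == "+" else "utr3"]
    if pos > cds_e:
        return ["utr3" if gene.strand == "+" else "utr5"]
    off = _coding_offset(gene, pos)
    if off is None:
        return ["intron"]
    frame = off % 3
    codon_start = off - frame
    bases = [_gene_base(gene.gene_id, codon_start + k) for k in range(3)]
    r, a = ref.upper(), alt.upper()
    if gene.strand == "-":
        r, a = r.translate(_COMPLEMENT), a.translate(_COMPLEMENT)
    bases[frame] = r
    ref_codon = "".join(bases)
    bases[frame] = a
    alt_codon = "".join(bases)
    aa_ref = _CODON_TABLE[ref_codon]
    aa_alt = _CODON_TABLE[alt_codon]
    if aa_ref == aa_alt:
        return ["synonymous"]
    if aa_alt == "*":
        return ["stop_gained"]
    if aa_ref == "*":
        return ["stop_lost"]
    return ["missense"]


def classify_sites(sites: pd.DataFrame, genes: list[GeneAnnotation],
                   flank: int = 5_000) -> pd.DataFrame:
    """Primary consequence class per SNP over all nearby gene models."""
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for _, s in sites.iterrows():
        labels: list[str] = []
        for g in by_chrom.get(str(s["chrom"]), []):
            if g.start - flank <= s["pos"] <= g.end + flank:
                labels += annotate_site(str(s["chrom"]), int(s["pos"]),
                                        s["ref"], s["alt"], g, flank)
        ordinal = classify_consequence(labels) if labels else None
        rows.append({
            "site": f"{s['chrom']}:{s['pos']}",
            "class": ordinal,
            "label": CLASS_LABELS.get(ordinal, "intergenic"),
        })
    return pd.DataFrame(rows)


# ----------------------------------------------------------- candidate sets

@dataclass
class CandidateSet:
    transect: str
    variable: str
    snps: set[str]
    genes: set[str]
    top_genes: set[str]

    def __post_init__(self) -> None:
        if not self.top_genes <= self.genes:
            raise ValueError("top_genes must be a subset of genes")


def genes_of_snps(snps: set[str], assignment: pd.DataFrame) -> set[str]:
    hit = assignment["site"].isin(snps) & assignment["gene_id"].notna()
    return set(assignment.loc[hit, "gene_id"])


def top_candidate_genes(scan: ScanResult, assignment: pd.DataFrame,
                        n: int = 100) -> set[str]:
    """Genes of the n lowest calibrated-p SNPs (ties broken by genomic
    coordinate for determinism)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    t = scan.table.sort_values(["p_cal", "chrom", "pos"],
                               kind="mergesort").head(n)
    return genes_of_snps(set(t["site"]), assignment)


def build_candidate_set(scan: ScanResult, outlier_snps: set[str],
                        assignment: pd.DataFrame, n_top: int = 100) -> CandidateSet:
    genes = genes_of_snps(outlier_snps, assignment)
    # top genes restricted to candidates so the subset invariant holds
    top = top_candidate_genes(scan, assignment, n_top) & genes
    return CandidateSet(scan.transect, scan.variable, outlier_snps, genes, top)
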