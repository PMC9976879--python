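"""Readers and writers for the pipeline's tabular input formats.

Coordinates are converted to the internal 0-based half-open convention at
this boundary: BED-like enhancer tables are already 0-based, while MAF/VCF
mutation tables and CADD tables are 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .cohort import CaddTable, MUTATION_COLUMNS
from .genome import Genome, SteppedTrack, encode_sequence
from .intervals import EnhancerGeneLink, GeneAnnotation, GenomicInterval

logger = logging.getLogger(__name__)


def read_genome_fasta(path: str | Path) -> Genome:
    return Genome(
        {rec.id: encode_sequence(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}
    )


def read_genes_tsv(path: str | Path) -> dict[str, GeneAnnotation]:
    """Gene table: gene_id, gene_type, strand, chrom, tss, coding_blocks.

    ``coding_blocks`` is a semicolon-separated list of 0-based half-open
    ``start-end`` spans (BED12-like block list).
    """
    df = pd.read_csv(path, sep="\t", dtype={"coding_blocks": str})
    genes = {}
    for _, row in df.iterrows():
        blocks = []
        raw = row.get("coding_blocks")
        if isinstance(raw, str) and raw:
            for span in raw.split(";"):
                start, end = span.split("-")
                blocks.append(GenomicInterval(row["chrom"], int(start), int(end)))
        genes[row["gene_id"]] = GeneAnnotation(
            row["gene_id"], row["gene_type"], row["strand"], row["chrom"], int(row["tss"]), blocks
        )
    return genes


def read_enhancer_map(path: str | Path) -> list[EnhancerGeneLink]:
    """BED-compatible enhancer-gene map: chrom, start, end, TargetGene, CellType, base_activity."""
    df = pd.read_csv(path, sep="\t")
    return [
        EnhancerGeneLink(
            GenomicInterval(r["chrom"], int(r["start"]), int(r["end"])),
            r["TargetGene"],
            r["CellType"],
            float(r["base_activity"]),
        )
        for _, r in df.iterrows()
    ]


def read_bedgraph(path: str | Path) -> SteppedTrack:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    return SteppedTrack.from_records(df.itertuples(index=False, name=None))


def read_cadd_tsv(path: str | Path) -> CaddTable:
    """CADD-like table with 1-based positions: chrom, pos, ref, alt, phred."""
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["pos"].astype(np.int64) - 1
    return CaddTable(df)


def read_mutations_maf(path: str | Path) -> pd.DataFrame:
    """MAF-like SNV table (1-based positions); indels are rejected with a count."""
    df = pd.read_csv(path, sep="\t")
    rename = {"Sample": "sample_id", "Chrom": "chrom", "Pos_1based": "pos", "Ref": "ref", "Alt": "alt"}
    df = df.rename(columns={k: v for k, v in rename.items() if k in df.columns})
    snv = (df["ref"].str.len() == 1) & (df["alt"].str.len() == 1) & (df["ref"] != df["alt"])
    if (~snv).any():
        logger.warning("rejected %d non-SNV records at the reader", int((~snv).sum()))
    df = df[snv].copy()
    df["pos"] = df["pos"].astype(np.int64) - 1
    if "cadd_phred" not in df.columns:
        df["cadd_phred"] = np.nan
    return df[MUTATION_COLUMNS].reset_index(drop=True)


def read_mutations_vcf(path: str | Path, sample_id: str | None = None) -> pd.DataFrame:
    """Minimal VCF reader; the sample comes from a SAMPLE INFO tag or the argument."""
    from cyvcf2 import VCF

    rows = []
    skipped = 0
    for variant in VCF(str(path)):
        alts = variant.ALT or []
        for alt in alts:
            if len(variant.REF) != 1 or len(alt) != 1:
                skipped += 1
                continue
            sid = variant.INFO.get("SAMPLE") or sample_id
            if sid is None:
                raise ValueError("VCF record lacks a SAMPLE tag and no sample_id was given")
            rows.append((sid, variant.CHROM, variant.POS - 1, variant.REF, alt, np.nan))
    if skipped:
        logger.warning("rejected %d non-SNV VCF records", skipped)
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Gene x sample numeric matrix with a gene-id index column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_samples_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_exposures_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_tfbs_tsv(path: str | Path) -> pd.DataFrame:
    """TFBS event table (1-based positions): chrom, pos, alt, event, tf_name, tf_regulator_class."""
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["pos"].astype(np.int64) - 1
    return df


def read_signature_catalog(path: str | Path) -> pd.DataFrame:
    """96-row signature catalog, channel labels in the fixed COSMIC order."""
    return pd.read_csv(path, sep="\t", index_col=0)


@dataclass
class InputBundle:
    """In-memory pipeline inputs loaded from a bundle directory."""

    genome: Genome
    chrom_sizes: dict[str, int]
    genes: dict[str, GeneAnnotation]
    links: list[EnhancerGeneLink]
    repl_track: SteppedTrack
    cadd: CaddTable
    mutations: pd.DataFrame
    expression: pd.DataFrame
    cnv: pd.DataFrame | None
    samples: pd.DataFrame
    exposures: pd.DataFrame
    tfbs: pd.DataFrame | None = None


def load_bundle(directory: str | Path) -> InputBundle:
    d = Path(directory)
    genome = read_genome_fasta(d / "genome.fa")
    tfbs_path = d / "tfbs.tsv"
    cnv_path = d / "cnv.tsv"
    return InputBundle(
        genome=genome,
        chrom_sizes=genome.sizes,
        genes=read_genes_tsv(d / "genes.tsv"),
        links=read_enhancer_map(d / "enhancers.tsv"),
        repl_track=read_bedgraph(d / "repl_timing.bedgraph"),
        cadd=read_cadd_tsv(d / "cadd.tsv"),
        mutations=read_mutations_maf(d / "mutations.tsv"),
        expression=read_matrix(d / "expression.tsv"),
        cnv=read_matrix(cnv_path) if cnv_path.exists() else None,
        samples=read_samples_tsv(d / "samples.tsv"),
        exposures=read_exposures_tsv(d / "exposures.tsv"),
        tfbs=read_tfbs_tsv(tfbs_path) if tfbs_path.exists() else None,
    )


def write_results_tsv(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_candidates_bed(spaces, candidates, path: str | Path) -> None:
    """BED of the regulatory segments of candidate genes."""
    rows = []
    for gene in candidates:
        for seg in spaces[gene].segments:
            rows.append((seg.chrom, seg.start, seg.end, gene))
    rows.sort()
    with open(path, "w") as fh:
        for chrom, start, end, gene in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{gene}\n")
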