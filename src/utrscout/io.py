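"""Readers and writers for the pipeline's on-disk formats.

GFF3 is 1-based inclusive and is converted to the internal 0-based half-open
convention on read (and back on write); BEDGraph is already 0-based
half-open. FASTA/FASTQ go through Biopython; tables through pandas.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    CoverageTrack,
    GeneModel,
    PlantedUtr,
    RaceRead,
    RtPcrResult,
    AnnotationJoin,
    SyntheticTruth,
    UtrCandidate,
)

DEFAULT_CHROM = "synthetic_chr"


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_fasta(sequence: str, path, *, name: str = DEFAULT_CHROM) -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_reads_fasta(reads: Sequence[RaceRead], path) -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=r.read_id, description="") for r in reads
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reads(path) -> list:
    """RACE reads from FASTA or FASTQ (by extension)."""
    path = str(path)
    fmt = "fastq" if path.endswith((".fastq", ".fq")) else "fasta"
    return [RaceRead(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, fmt)]


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(genes: Sequence[GeneModel], path, *, chrom: str = DEFAULT_CHROM) -> None:
    """0-based half-open gene models -> 1-based inclusive GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};product={g.product}" if g.product else f"ID={g.gene_id}"
            fh.write(
                "\t".join(
                    [
                        chrom,
                        "utrscout",
                        "gene",
                        str(g.cds_start + 1),
                        str(g.cds_end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path, *, feature_types: tuple = ("gene", "CDS")) -> list:
    """GFF3 gene/CDS features -> GeneModel list (coordinates converted)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    seen = set()
    for ftype in feature_types:
        try:
            features = list(db.features_of_type(ftype))
        except Exception:
            continue
        for feat in features:
            gene_id = feat.attributes.get("ID", [feat.id])[0]
            if gene_id in seen:
                continue
            seen.add(gene_id)
            product = feat.attributes.get("product", [""])[0]
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    strand=feat.strand,
                    cds_start=feat.start - 1,  # GFF3 is 1-based inclusive
                    cds_end=feat.end,
                    product=product,
                )
            )
    genes.sort(key=lambda g: g.cds_start)
    return genes


# ---------------------------------------------------------------------------
# BEDGraph


def write_bedgraph(depth: np.ndarray, path, *, chrom: str = DEFAULT_CHROM) -> None:
    """Run-length-compressed BEDGraph (0-based half-open intervals)."""
    depth = np.asarray(depth)
    with open(path, "w") as fh:
        if depth.size == 0:
            return
        change = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [depth.size]))
        for s, e in zip(starts, ends):
            v = depth[s]
            fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path, genome_length: int) -> np.ndarray:
    """BEDGraph -> dense per-base depth vector of length ``genome_length``."""
    depth = np.zeros(genome_length, dtype=float)
    table = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
    )
    for start, end, value in zip(table["start"], table["end"], table["value"]):
        if end > genome_length:
            raise ValueError(f"BEDGraph interval [{start}, {end}) exceeds genome length")
        depth[int(start) : int(end)] = float(value)
    return depth


def read_coverage(plus_path, minus_path, genome_length: int) -> CoverageTrack:
    return CoverageTrack(
        plus=read_bedgraph(plus_path, genome_length),
        minus=read_bedgraph(minus_path, genome_length),
    )


# ---------------------------------------------------------------------------
# candidate tables


def write_candidates_tsv(candidates: Sequence[UtrCandidate], path) -> None:
    from .candidate_annotation import candidates_to_table

    candidates_to_table(candidates).to_csv(path, sep="\t", index=False)


def write_candidates_bed(candidates: Sequence[UtrCandidate], path, *, chrom: str = DEFAULT_CHROM) -> None:
    """BED6: candidate intervals, score = round(100 x expression ratio)."""
    with open(path, "w") as fh:
        for c in candidates:
            score = int(round(100 * c.expression_ratio))
            fh.write(
                f"{chrom}\t{c.utr_start}\t{c.utr_end}\tUTR_{c.gene_id}\t{score}\t{c.strand}\n"
            )


def read_candidates_tsv(path) -> list:
    """Candidate TSV (as written by :func:`write_candidates_tsv`) -> list of
    UtrCandidate."""
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str}).fillna("")
    candidates = []
    for _, r in table.iterrows():
        gfp = {t.strip() for t in str(r.get("gfp_stress_response", "")).split(";") if t.strip()}
        flags = {t for t in str(r.get("flags", "")).split(";") if t}
        candidates.append(
            UtrCandidate(
                gene_id=r["gene_id"],
                strand=r["strand"],
                tss=int(r["tss"]),
                utr_start=int(r["utr_start"]),
                utr_end=int(r["utr_end"]),
                mean_utr_depth=float(r["mean_utr_depth"]),
                mean_cds_depth=float(r["mean_cds_depth"]),
                expression_ratio=float(r["expression_ratio"]),
                flags=flags,
                product=str(r.get("gene_product", "")),
                rfam_family=str(r.get("rfam_prediction", "")) or None,
                conservation=str(r.get("conservation", "")) or None,
                transcript_stress_de=str(r.get("transcript_stress_de", "")) or None,
                protein_stress_de=str(r.get("protein_stress_de", "")) or None,
                gfp_stress_response=gfp or None,
            )
        )
    return candidates


def read_rtpcr_tsv(path) -> list:
    table = pd.read_csv(path, sep="\t")
    return [
        RtPcrResult(
            gene_id=str(r["gene_id"]),
            band_A=bool(r["band_A"]),
            band_B=bool(r["band_B"]),
            band_negative_control=bool(r["band_negative_control"]),
        )
        for _, r in table.iterrows()
    ]


def read_annotation_joins(path) -> list:
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    joins = []
    for _, r in table.iterrows():
        joins.append(
            AnnotationJoin(
                gene_id=r["gene_id"],
                rfam_family=r.get("rfam_family") or None,
                conservation=r.get("conservation") or None,
                transcript_stress_de=r.get("transcript_stress_de") or None,
                protein_stress_de=r.get("protein_stress_de") or None,
            )
        )
    return joins


# ---------------------------------------------------------------------------
# synthetic truth


def write_truth_json(truth: SyntheticTruth, path) -> None:
    payload = {
        "seed": truth.seed,
        "genes": [asdict(g) for g in truth.genes],
        "utrs": [asdict(u) for u in truth.utrs],
        "screen_truth": [
            {"strain": s, "condition": c, "median": m}
            for (s, c), m in truth.screen_truth.items()
        ],
        "qpcr_truth": truth.qpcr_truth,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth_json(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        genes=[GeneModel(**g) for g in payload["genes"]],
        utrs=[PlantedUtr(**u) for u in payload["utrs"]],
        screen_truth={
            (r["strain"], r["condition"]): r["median"] for r in payload["screen_truth"]
        },
        qpcr_truth=payload["qpcr_truth"],
        seed=payload["seed"],
    )
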