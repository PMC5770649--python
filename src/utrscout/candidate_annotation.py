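"""TSS refinement from 5'RACE reads, RT-PCR confirmation logic, annotation
joins and assembly/summary of the final candidate table.

RACE reads carry a known 45-nt adapter ligated to the mRNA 5' end; the base
immediately after the adapter is the transcription start. Refinement locates
the adapter in each read (tolerating one substitution), maps the following
transcript sequence upstream of the gene, and takes the modal mapped
position across reads as the TSS.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import replace
from typing import Sequence

import pandas as pd

from .models import AnnotationJoin, GeneModel, RaceRead, RtPcrResult, TssCall, UtrCandidate
from .synthetic_data import RACE_ADAPTER, RACE_ADAPTER_RNA, reverse_complement  # noqa: F401

#: Length of the error-free post-adapter prefix used to anchor a read on the
#: genome.
ANCHOR_LENGTH = 10

#: The search window for genomic placement extends this far *into* the CDS so
#: reads starting inside the coding region are seen (and rejected) rather
#: than silently unmapped.
DOWNSTREAM_SLACK = 50

RTPCR_CLASSES = ("confirmed", "undetected", "contaminated", "assay_failure")

#: Stress labels a reporter construct can respond to.
STRESSES = ("ethanol", "acetate", "xylose")

TABLE1_COLUMNS = (
    "gene_id",
    "gene_product",
    "conservation",
    "rfam_prediction",
    "transcript_stress_de",
    "protein_stress_de",
    "gfp_stress_response",
)


def _find_adapter(sequence: str, adapter: str, max_mismatches: int = 1) -> int:
    """Offset of the adapter in the read (<= ``max_mismatches`` substitutions),
    or -1. The best (fewest-mismatch, left-most) placement wins."""
    n, m = len(sequence), len(adapter)
    best, best_at = max_mismatches + 1, -1
    for i in range(n - m + 1):
        mm = 0
        for a, b in zip(sequence[i : i + m], adapter):
            if a != b:
                mm += 1
                if mm >= best:
                    break
        if mm < best:
            best, best_at = mm, i
            if best == 0:
                break
    return best_at


def _map_anchor(anchor: str, genome: str, gene: GeneModel, max_scan: int):
    """Map the post-adapter anchor upstream of ``gene``.

    Returns (tss, reason): a genomic TSS coordinate when the anchor has
    exactly one hit in the search window upstream of the translation start,
    else ``None`` and why ("unmapped", "ambiguous", "inside_cds").
    """
    if gene.strand == "+":
        lo = max(0, gene.cds_start - max_scan)
        hi = min(len(genome), gene.cds_start + DOWNSTREAM_SLACK)
        window = genome[lo:hi]
        query = anchor
    else:
        lo = max(0, gene.cds_end - DOWNSTREAM_SLACK)
        hi = min(len(genome), gene.cds_end + max_scan)
        window = genome[lo:hi]
        query = reverse_complement(anchor)
    hits = []
    at = window.find(query)
    while at != -1:
        hits.append(at)
        at = window.find(query, at + 1)
    if not hits:
        return None, "unmapped"
    if len(hits) > 1:
        return None, "ambiguous"
    if gene.strand == "+":
        tss = lo + hits[0]
        if tss >= gene.cds_start:
            return None, "inside_cds"
    else:
        tss = lo + hits[0] + len(query) - 1
        if tss < gene.cds_end:
            return None, "inside_cds"
    return tss, ""


def refine_tss_from_race(
    reads: Sequence[RaceRead],
    genome: str,
    gene: GeneModel,
    *,
    adapter: str = RACE_ADAPTER,
    min_support: int = 2,
    max_scan: int = 600,
) -> TssCall:
    """Refine a gene's TSS from adapter-ligated RACE reads.

    Per read: locate the adapter (U read as T, at most one mismatch), take
    the first :data:`ANCHOR_LENGTH` transcript bases after it, and place
    them by exact search in the window upstream of the gene on its strand.
    Reads with no adapter, no hit, multiple hits, or a placement inside the
    CDS are rejected with a reason. The call is the modal mapped position —
    ties break toward the most distal (longest-UTR) position — and requires
    ``min_support`` supporting reads.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    adapter = adapter.upper().replace("U", "T")
    genome = genome.upper()

    positions: Counter = Counter()
    rejected: Counter = Counter()
    for read in reads:
        seq = read.sequence.upper().replace("U", "T")
        at = _find_adapter(seq, adapter)
        if at == -1:
            rejected["no_adapter"] += 1
            continue
        anchor = seq[at + len(adapter) : at + len(adapter) + ANCHOR_LENGTH]
        if len(anchor) < ANCHOR_LENGTH:
            rejected["too_short"] += 1
            continue
        tss, reason = _map_anchor(anchor, genome, gene, max_scan)
        if tss is None:
            rejected[reason] += 1
            continue
        positions[tss] += 1

    if not positions:
        reason = (
            "adapter not found in any read"
            if rejected and set(rejected) == {"no_adapter"}
            else "no read mapped: " + ", ".join(f"{k}={v}" for k, v in sorted(rejected.items()))
            if rejected
            else "no reads"
        )
        return TssCall(gene.gene_id, None, "no_call", reason)

    n_mapped = sum(positions.values())
    top = max(positions.values())
    modal = [p for p, c in positions.items() if c == top]
    # most distal = farthest from the CDS on the gene's strand
    tss = min(modal) if gene.strand == "+" else max(modal)
    if top < min_support:
        return TssCall(
            gene.gene_id,
            None,
            "no_call",
            f"max support {top} < min_support {min_support}",
            support=top,
            n_reads_mapped=n_mapped,
        )
    return TssCall(gene.gene_id, tss, "called", support=top, n_reads_mapped=n_mapped)


def classify_rtpcr(result: RtPcrResult) -> str:
    """Classify one RT-PCR gel read-out.

    A no-RT negative-control band means genomic DNA contamination and
    overrides everything. Otherwise a missing set-B band (the mRNA positive
    control) is an assay failure; with B present, an A band proves the UTR
    is transcribed contiguously with the mRNA (confirmed) and its absence
    means the UTR was not detected.
    """
    if result.band_negative_control:
        return "contaminated"
    if not result.band_B:
        return "assay_failure"
    if result.band_A:
        return "confirmed"
    return "undetected"


def join_annotations(
    candidates: Sequence[UtrCandidate], joins: Sequence[AnnotationJoin]
) -> list:
    """Left-join external annotation onto candidates by gene_id.

    No candidate is dropped; join rows matching no candidate are reported as
    warnings; a duplicated gene_id in ``joins`` is an error. Candidates are
    returned as copies, so joining twice equals joining once.
    """
    by_id: dict = {}
    for join in joins:
        if join.gene_id in by_id:
            raise ValueError(f"duplicate gene_id in annotation joins: {join.gene_id}")
        by_id[join.gene_id] = join

    matched = set()
    out = []
    for cand in candidates:
        join = by_id.get(cand.gene_id)
        if join is None:
            out.append(replace(cand, flags=set(cand.flags)))
            continue
        matched.add(cand.gene_id)
        out.append(
            replace(
                cand,
                flags=set(cand.flags),
                rfam_family=join.rfam_family if join.rfam_family is not None else cand.rfam_family,
                conservation=join.conservation if join.conservation is not None else cand.conservation,
                transcript_stress_de=join.transcript_stress_de
                if join.transcript_stress_de is not None
                else cand.transcript_stress_de,
                protein_stress_de=join.protein_stress_de
                if join.protein_stress_de is not None
                else cand.protein_stress_de,
            )
        )
    unmatched = sorted(set(by_id) - matched)
    if unmatched:
        warnings.warn(f"annotation rows matched no candidate: {', '.join(unmatched)}")
    return out


def candidates_to_table(candidates: Sequence[UtrCandidate]) -> pd.DataFrame:
    """Render candidates as a final-table DataFrame (see TABLE1_COLUMNS),
    plus provenance columns (coordinates, depths, flags)."""
    rows = []
    for c in candidates:
        gfp = ";".join(sorted(c.gfp_stress_response)) if c.gfp_stress_response else ""
        rows.append(
            {
                "gene_id": c.gene_id,
                "gene_product": c.product,
                "conservation": c.conservation or "",
                "rfam_prediction": c.rfam_family or "",
                "transcript_stress_de": c.transcript_stress_de or "",
                "protein_stress_de": c.protein_stress_de or "",
                "gfp_stress_response": gfp,
                "strand": c.strand,
                "tss": c.tss,
                "utr_start": c.utr_start,
                "utr_end": c.utr_end,
                "length": c.length,
                "mean_utr_depth": c.mean_utr_depth,
                "mean_cds_depth": c.mean_cds_depth,
                "expression_ratio": c.expression_ratio,
                "flags": ";".join(sorted(c.flags)),
            }
        )
    return pd.DataFrame(rows, columns=list(TABLE1_COLUMNS) + [
        "strand", "tss", "utr_start", "utr_end", "length",
        "mean_utr_depth", "mean_cds_depth", "expression_ratio", "flags",
    ])


def summarize_candidate_table(table) -> dict:
    """Summary counts over a candidate table.

    ``table`` is a DataFrame with the :data:`TABLE1_COLUMNS` columns (extra
    columns are ignored) or a sequence of :class:`UtrCandidate`. Returns
    total rows, rows with a non-empty Rfam prediction, rows differentially
    expressed under stress at the transcript and protein level, and rows
    whose reporter responded to each stress.
    """
    if not isinstance(table, pd.DataFrame):
        table = candidates_to_table(table)
    if table.empty:
        counts = {"total": 0, "rfam": 0, "transcript_stress_de": 0, "protein_stress_de": 0}
        counts.update({f"gfp_{s}": 0 for s in STRESSES})
        return counts

    def nonempty(col: str):
        return int((table[col].fillna("").astype(str).str.strip() != "").sum())

    gfp = table["gfp_stress_response"].fillna("").astype(str).str.lower()
    counts = {
        "total": int(len(table)),
        "rfam": nonempty("rfam_prediction"),
        "transcript_stress_de": nonempty("transcript_stress_de"),
        "protein_stress_de": nonempty("protein_stress_de"),
    }
    for stress in STRESSES:
        counts[f"gfp_{stress}"] = int(
            gfp.apply(lambda v: stress in [t.strip() for t in v.split(";")]).sum()
        )
    return counts


def load_table1() -> pd.DataFrame:
    """The published 36-row candidate table shipped with the package."""
    from importlib.resources import files

    path = files("utrscout") / "fixtures" / "table1.tsv"
    with path.open() as handle:
        return pd.read_csv(handle, sep="\t", dtype=str).fillna("")
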