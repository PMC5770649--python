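"""Coverage-based 5'UTR calling and the candidate filters.

The discovery engine scans strand-specific read depth outward from each
gene's translation start: contiguous coverage immediately upstream of a CDS,
at depth comparable to the CDS itself, is the signature of a transcribed
5'UTR. Candidates then pass through three filters — comparable expression
with the adjacent gene, a 35 nt minimum length (the shortest known UTR
regulatory element), and keyword-based prioritization of metabolic enzymes —
and finally through the exclusion rules applied after wet-lab follow-up
(overlap with the upstream gene, <30 nt after RACE refinement, no RT-PCR
confirmation).
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np

from .models import CoverageTrack, GeneModel, UtrCandidate

logger = logging.getLogger(__name__)

#: Product keywords marking well-characterized metabolic enzymes, which are
#: moved to the front of the candidate list.
DEFAULT_PRIORITY_KEYWORDS = (
    "synthase",
    "reductase",
    "transferase",
    "dehydrogenase",
    "kinase",
    "phosphatase",
    "transporter",
)

#: CDS depth is averaged over at most this many nt from the translation
#: start, to dodge 3'-decay artifacts in long genes.
CDS_DEPTH_WINDOW = 300


def _upstream_limit(gene: GeneModel, genes: Sequence[GeneModel], genome_length: int) -> int:
    """How many bases upstream of the translation start may be scanned before
    hitting the genome edge or the nearest same-strand annotated gene."""
    if gene.strand == "+":
        limit = gene.cds_start
        for other in genes:
            if other is gene or other.strand != gene.strand:
                continue
            if other.cds_end <= gene.cds_start:
                limit = min(limit, gene.cds_start - other.cds_end)
            elif other.cds_start < gene.cds_start:  # overlapping annotation
                limit = 0
        return limit
    limit = genome_length - gene.cds_end
    for other in genes:
        if other is gene or other.strand != gene.strand:
            continue
        if other.cds_start >= gene.cds_end:
            limit = min(limit, other.cds_start - gene.cds_end)
        elif other.cds_end > gene.cds_end:
            limit = 0
    return limit


def _mean_cds_depth(track: np.ndarray, gene: GeneModel) -> float:
    w = min(gene.length, CDS_DEPTH_WINDOW)
    if gene.strand == "+":
        return float(track[gene.cds_start : gene.cds_start + w].mean())
    return float(track[gene.cds_end - w : gene.cds_end].mean())


def call_upstream_transcription(
    coverage: CoverageTrack,
    genes: Sequence[GeneModel],
    *,
    min_depth: float = 5,
    max_gap: int = 10,
    max_scan: int = 600,
) -> list:
    """Call one putative 5'UTR per gene with covered upstream transcription.

    From the base immediately 5' of each gene's translation start, the scan
    extends outward on the gene's strand while depth >= ``min_depth``,
    tolerating sub-threshold runs of at most ``max_gap`` nt. It stops at the
    first longer gap, after ``max_scan`` nt, or at the boundary of the
    nearest same-strand annotated gene (opposite-strand genes do not stop
    it: coverage is strand-specific). The TSS is the most distal retained
    covered base; a gene with no retained covered base yields no candidate.

    Each candidate carries mean depths over the UTR interval and over the
    first ``min(CDS length, 300)`` nt of CDS, and their ratio.
    """
    if max_scan < 1:
        raise ValueError("max_scan must be >= 1")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    genome_length = coverage.genome_length
    for gene in genes:
        if gene.cds_start < 0 or gene.cds_end > genome_length:
            raise ValueError(
                f"{gene.gene_id}: gene interval [{gene.cds_start}, {gene.cds_end}) "
                f"outside genome of length {genome_length}"
            )

    candidates = []
    for gene in genes:
        track = coverage.strand(gene.strand)
        limit = min(_upstream_limit(gene, genes, genome_length), max_scan)
        step = -1 if gene.strand == "+" else 1
        origin = gene.cds_start - 1 if gene.strand == "+" else gene.cds_end

        most_distal = None
        gap_run = 0
        for offset in range(limit):
            pos = origin + step * offset
            if track[pos] >= min_depth:
                most_distal = pos
                gap_run = 0
            else:
                gap_run += 1
                if gap_run > max_gap:
                    break
        if most_distal is None:
            continue

        if gene.strand == "+":
            utr_start, utr_end = most_distal, gene.cds_start
        else:
            utr_start, utr_end = gene.cds_end, most_distal + 1
        mean_utr = float(track[utr_start:utr_end].mean())
        mean_cds = _mean_cds_depth(track, gene)
        if mean_cds > 0:
            ratio = mean_utr / mean_cds
        else:
            logger.warning(
                "%s: mean CDS depth is 0; expression ratio set to 0", gene.gene_id
            )
            ratio = 0.0
        candidates.append(
            UtrCandidate(
                gene_id=gene.gene_id,
                strand=gene.strand,
                tss=most_distal,
                utr_start=utr_start,
                utr_end=utr_end,
                mean_utr_depth=mean_utr,
                mean_cds_depth=mean_cds,
                expression_ratio=ratio,
                product=gene.product,
            )
        )
    return candidates


def filter_comparable_expression(
    candidates: Sequence[UtrCandidate], *, min_ratio: float = 0.25
) -> list:
    """Keep candidates whose UTR carries expression comparable to the CDS.

    "Comparable" is operationalized as mean UTR depth / mean CDS depth >=
    ``min_ratio`` (inclusive). Passing candidates get the
    ``passed_comparable`` flag; order is preserved.
    """
    kept = []
    for cand in candidates:
        if cand.expression_ratio >= min_ratio:
            cand.flags.add("passed_comparable")
            kept.append(cand)
    return kept


def filter_min_length(
    candidates: Sequence[UtrCandidate], *, min_length: int = 35
) -> list:
    """Drop candidates shorter than ``min_length`` nt (default 35, the
    shortest known UTR regulatory element); keepers get ``passed_length``."""
    kept = []
    for cand in candidates:
        if cand.length >= min_length:
            cand.flags.add("passed_length")
            kept.append(cand)
    return kept


def prioritize_candidates(
    candidates: Sequence[UtrCandidate],
    keywords: Sequence[str] = DEFAULT_PRIORITY_KEYWORDS,
) -> list:
    """Stable partition: metabolic-enzyme candidates first, nothing dropped.

    A candidate is prioritized when its product text contains any keyword,
    case-insensitively. Relative order within each block is preserved.
    """
    lowered = [k.lower() for k in keywords]
    front, back = [], []
    for cand in candidates:
        product = cand.product.lower()
        if any(k in product for k in lowered):
            cand.flags.add("prioritized")
            front.append(cand)
        else:
            back.append(cand)
    return front + back


def refined_length(gene: GeneModel, race_tss: int) -> int:
    """UTR length implied by a RACE-refined TSS (nt from TSS to CDS start)."""
    if gene.strand == "+":
        return gene.cds_start - race_tss
    return race_tss - gene.cds_end + 1


def apply_exclusion_rules(
    candidates: Sequence[UtrCandidate],
    genes: Sequence[GeneModel],
    *,
    race_tss: Optional[Mapping[str, int]] = None,
    min_final_length: int = 30,
) -> tuple:
    """Partition candidates into (kept, excluded) by the follow-up rules.

    A candidate is excluded when (a) its UTR interval overlaps the annotated
    extent of another same-strand gene — its transcription runs into the
    neighbour (flag ``excluded_overlap``); (b) its RACE-refined length,
    where ``race_tss`` provides one, is below ``min_final_length`` (default
    30 nt; flag ``excluded_short_after_race``); or (c) it lacks the
    ``confirmed_rtpcr`` flag. All three checks run so an excluded candidate
    carries every applicable flag.
    """
    by_id = {g.gene_id: g for g in genes}
    race_tss = race_tss or {}
    kept, excluded = [], []
    for cand in candidates:
        gene = by_id.get(cand.gene_id)
        if gene is None:
            raise ValueError(f"candidate references unknown gene {cand.gene_id}")
        drop = False
        for other in genes:
            if other.gene_id == cand.gene_id or other.strand != cand.strand:
                continue
            if cand.utr_start < other.cds_end and other.cds_start < cand.utr_end:
                cand.flags.add("excluded_overlap")
                drop = True
                break
        if cand.gene_id in race_tss:
            if refined_length(gene, race_tss[cand.gene_id]) < min_final_length:
                cand.flags.add("excluded_short_after_race")
                drop = True
        if "confirmed_rtpcr" not in cand.flags:
            drop = True
        (excluded if drop else kept).append(cand)
    return kept, excluded


def discover(
    coverage: CoverageTrack,
    genes: Sequence[GeneModel],
    *,
    min_depth: float = 5,
    max_gap: int = 10,
    max_scan: int = 600,
    min_ratio: float = 0.25,
    min_length: int = 35,
    keywords: Sequence[str] = DEFAULT_PRIORITY_KEYWORDS,
) -> list:
    """Full discovery pass: call, filter, prioritize."""
    candidates = call_upstream_transcription(
        coverage, genes, min_depth=min_depth, max_gap=max_gap, max_scan=max_scan
    )
    candidates = filter_comparable_expression(candidates, min_ratio=min_ratio)
    candidates = filter_min_length(candidates, min_length=min_length)
    return prioritize_candidates(candidates, keywords)
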