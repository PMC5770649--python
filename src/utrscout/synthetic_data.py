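"""Simulation of every input the pipeline consumes, with planted ground truth.

The generators emulate the study design end to end: strand-specific RNA-seq
coverage plateaus over transcripts whose 5' ends extend past the annotated
CDS, adapter-bearing 5'RACE reads starting exactly at the planted TSS,
log-normal per-cell reporter fluorescence with condition-dependent median
shifts, and qPCR Ct tables encoding known fold changes.

Every generator is deterministic for a fixed seed. A single global seed fans
out to independent per-stage child streams (via :func:`child_rng`) so each
stage can be regenerated on its own without disturbing the others.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .models import CoverageTrack, GeneModel, PlantedUtr, RaceRead, SyntheticTruth

DNA = np.array(list("ACGT"))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Stage labels used to spawn independent child RNG streams from one seed.
_STAGES = ("genome", "utrs", "coverage", "race", "screen", "qpcr")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage RNG derived from the global seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STAGES.index(stage),))
    )


# ---------------------------------------------------------------------------
# genome + annotation


def generate_genome(
    n_genes: int,
    genome_length: int,
    seed: int,
    *,
    min_gap: int = 300,
    cds_length_range: tuple = (300, 1500),
    max_attempts: int = 2000,
) -> tuple:
    """Random genome sequence plus ``n_genes`` non-overlapping genes.

    Genes land on both strands with at least ``min_gap`` nt between CDS
    intervals and between the outermost genes and the genome ends, leaving
    room to plant 5'UTRs upstream of every gene.

    Returns ``(sequence, genes)`` where ``sequence`` is an upper-case DNA
    string of length ``genome_length`` and ``genes`` is a list of
    :class:`GeneModel` sorted by start coordinate.
    """
    if n_genes < 1:
        raise ValueError("at least one gene is required (n_genes >= 1)")
    lo, hi = cds_length_range
    if lo < 3 or hi < lo:
        raise ValueError("cds_length_range must satisfy 3 <= lo <= hi")
    rng = child_rng(seed, "genome")
    sequence = "".join(rng.choice(DNA, size=genome_length))

    # feasibility check before the rejection loop so the error names the
    # constraint rather than timing out
    needed = n_genes * (hi + min_gap) + min_gap
    if genome_length < needed:
        raise ValueError(
            f"genome_length={genome_length} too small to place {n_genes} genes of "
            f"up to {hi} nt with {min_gap} nt gaps (need >= {needed})"
        )

    placed: list = []
    for _ in range(max_attempts):
        length = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
        start = int(rng.integers(min_gap, genome_length - min_gap - length + 1))
        end = start + length
        ok = all(not (start < e + min_gap and s < end + min_gap) for s, e in placed)
        if ok:
            placed.append((start, end))
            if len(placed) == n_genes:
                break
    else:
        raise ValueError(
            f"could not place {n_genes} non-overlapping genes with {min_gap} nt "
            f"gaps in {genome_length} nt after {max_attempts} attempts"
        )

    placed.sort()
    genes = []
    for i, (start, end) in enumerate(placed):
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"SYN{i:04d}",
                strand=strand,
                cds_start=start,
                cds_end=end,
                product=f"synthetic protein {i}",
            )
        )
    return sequence, genes


_ValueSpec = Union[float, int, Mapping[str, float], Sequence[float], None]


def _resolve(spec: _ValueSpec, genes: Sequence[GeneModel], draw) -> dict:
    """Expand a scalar / mapping / sequence spec into per-gene values."""
    if spec is None:
        return {g.gene_id: draw() for g in genes}
    if isinstance(spec, Mapping):
        return dict(spec)
    if isinstance(spec, (int, float)):
        return {g.gene_id: spec for g in genes}
    values = list(spec)
    if len(values) != len(genes):
        raise ValueError("per-gene sequence length must match number of genes")
    return {g.gene_id: v for g, v in zip(genes, values)}


def plant_utrs(
    genes: Sequence[GeneModel],
    genome_length: int,
    *,
    lengths: _ValueSpec = None,
    ratios: _ValueSpec = None,
    seed: int = 0,
    length_range: tuple = (35, 150),
    ratio_range: tuple = (0.3, 1.0),
) -> list:
    """Plant one 5'UTR abutting the CDS start of each selected gene.

    ``lengths`` / ``ratios`` may be a scalar (same value for every gene), a
    mapping ``gene_id -> value`` (only those genes get a UTR), a sequence
    aligned with ``genes``, or ``None`` (drawn uniformly from the ranges).
    """
    rng = child_rng(seed, "utrs")
    length_map = _resolve(
        lengths, genes, lambda: int(rng.integers(length_range[0], length_range[1] + 1))
    )
    ratio_map = _resolve(ratios, genes, lambda: float(rng.uniform(*ratio_range)))

    by_id = {g.gene_id: g for g in genes}
    utrs = []
    for gene_id, length in length_map.items():
        gene = by_id[gene_id]
        length = int(length)
        if gene.strand == "+":
            tss = gene.cds_start - length
            if tss < 0:
                raise ValueError(f"{gene_id}: planted UTR extends past genome start")
        else:
            tss = gene.cds_end + length - 1
            if tss >= genome_length:
                raise ValueError(f"{gene_id}: planted UTR extends past genome end")
        utrs.append(
            PlantedUtr(
                gene_id=gene_id,
                tss=tss,
                length=length,
                expression_ratio=float(ratio_map.get(gene_id, 1.0)),
            )
        )
    return utrs


# ---------------------------------------------------------------------------
# coverage


def _draw_depth(rng, mean: float, size: int, noise_model: str, dispersion: float):
    if mean <= 0:
        return np.zeros(size)
    if noise_model == "poisson":
        return rng.poisson(mean, size=size).astype(float)
    if noise_model == "negative_binomial":
        # var = mu + mu^2 / k
        k = dispersion
        p = k / (k + mean)
        return rng.negative_binomial(k, p, size=size).astype(float)
    if noise_model == "none":
        return np.full(size, float(mean))
    raise ValueError(f"unknown noise_model {noise_model!r}")


def generate_coverage(
    truth: SyntheticTruth,
    genome_length: int,
    *,
    mean_depth: float = 100.0,
    noise_model: str = "poisson",
    background_depth: float = 0.0,
    dispersion: float = 10.0,
    seed: Optional[int] = None,
) -> CoverageTrack:
    """Strand-specific coverage with a plateau over each transcript.

    Depth over the CDS of every gene is drawn around ``mean_depth``; over a
    planted UTR it is drawn around ``mean_depth * expression_ratio``; the
    rest of each strand sits at ``background_depth``. Minus-strand
    transcripts put their UTR plateau at coordinates *above* the CDS on the
    minus track. ``noise_model`` may be ``poisson``, ``negative_binomial``
    (gamma-shape ``dispersion``) or ``none`` (exact plateaus, for oracle
    tests).
    """
    if not mean_depth > background_depth >= 0:
        raise ValueError("require mean_depth > background_depth >= 0")
    rng = child_rng(truth.seed if seed is None else seed, "coverage")

    tracks = {
        "+": _draw_depth(rng, background_depth, genome_length, noise_model, dispersion),
        "-": _draw_depth(rng, background_depth, genome_length, noise_model, dispersion),
    }
    utr_by_gene = {u.gene_id: u for u in truth.utrs}
    for gene in truth.genes:
        if gene.cds_end > genome_length:
            raise ValueError(f"{gene.gene_id}: gene extends past genome boundary")
        track = tracks[gene.strand]
        track[gene.cds_start : gene.cds_end] = _draw_depth(
            rng, mean_depth, gene.length, noise_model, dispersion
        )
        utr = utr_by_gene.get(gene.gene_id)
        if utr is None:
            continue
        start, end = truth.utr_interval(utr)
        if start < 0 or end > genome_length:
            raise ValueError(f"{gene.gene_id}: planted UTR extends past genome boundary")
        track[start:end] = _draw_depth(
            rng, mean_depth * utr.expression_ratio, end - start, noise_model, dispersion
        )
    return CoverageTrack(plus=tracks["+"], minus=tracks["-"])


# ---------------------------------------------------------------------------
# 5'RACE reads

#: The ligated RACE adapter, as printed (RNA) and as sequenced (DNA).
RACE_ADAPTER_RNA = "GCUGAUGGCGAUGAAUGAACACUGCGUUUGCUGGCUUUGAUGAAA"
RACE_ADAPTER = RACE_ADAPTER_RNA.replace("U", "T")

#: The generator never mutates the first bases after the adapter; TSS
#: refinement anchors its genomic search on this error-free zone.
RACE_ERROR_FREE_ZONE = 10


def generate_race_reads(
    truth: SyntheticTruth,
    genome: str,
    *,
    n_reads_per_utr: int = 10,
    error_rate: float = 0.0,
    read_length: int = 60,
    adapter: str = RACE_ADAPTER,
    seed: Optional[int] = None,
) -> list:
    """Adapter-ligated reads whose transcript part starts exactly at the TSS.

    Each read is ``adapter`` + ``read_length`` nt of transcript sequence
    (genome slice from the planted TSS, reverse-complemented for minus-strand
    genes, truncated at the genome edge). Substitution errors at
    ``error_rate`` are applied only beyond the first
    :data:`RACE_ERROR_FREE_ZONE` transcript bases.
    """
    if n_reads_per_utr < 0:
        raise ValueError("n_reads_per_utr must be >= 0")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    rng = child_rng(truth.seed if seed is None else seed, "race")
    reads = []
    for utr in truth.utrs:
        gene = truth.gene(utr.gene_id)
        if gene.strand == "+":
            frag = genome[utr.tss : utr.tss + read_length]
        else:
            frag = reverse_complement(genome[max(0, utr.tss - read_length + 1) : utr.tss + 1])
        for i in range(n_reads_per_utr):
            bases = list(frag)
            if error_rate > 0:
                for j in range(RACE_ERROR_FREE_ZONE, len(bases)):
                    if rng.random() < error_rate:
                        bases[j] = str(rng.choice(DNA[DNA != bases[j]]))
            reads.append(
                RaceRead(
                    read_id=f"{utr.gene_id}_race_{i}",
                    sequence=adapter + "".join(bases),
                )
            )
    return reads


# ---------------------------------------------------------------------------
# reporter screen events


def generate_screen_events(
    truth: SyntheticTruth,
    *,
    n_events: int = 50_000,
    cv: float = 0.4,
    n_replicates: int = 3,
    replicate_sd: float = 0.05,
    seed: Optional[int] = None,
):
    """Per-event fluorescence tables for every strain x condition in the truth.

    Events are log-normal with the sample's true median and per-event
    coefficient of variation ``cv`` (``sigma = sqrt(ln(1 + cv^2))``, so the
    distribution's median is exactly the truth value). Biological replicates
    get log-normal median jitter with log-sd ``replicate_sd``.

    Returns a :class:`pandas.DataFrame` with one column per sample, named
    ``strain|condition|replicate``.
    """
    import pandas as pd

    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not truth.screen_truth:
        raise ValueError("truth.screen_truth is empty")
    rng = child_rng(truth.seed if seed is None else seed, "screen")
    sigma = math.sqrt(math.log1p(cv * cv))
    columns = {}
    for (strain, condition), median in truth.screen_truth.items():
        for rep in range(1, n_replicates + 1):
            rep_median = median * math.exp(rng.normal(0.0, replicate_sd)) if replicate_sd else median
            if sigma > 0:
                events = rep_median * np.exp(rng.normal(0.0, sigma, size=n_events))
            else:
                events = np.full(n_events, rep_median)
            columns[f"{strain}|{condition}|{rep}"] = events
    return pd.DataFrame(columns)


# ---------------------------------------------------------------------------
# qPCR Ct tables


def generate_qpcr(
    truth: SyntheticTruth,
    *,
    ct_noise_sd: float = 0.0,
    n_replicates: int = 3,
    target_gene: str = "hfq",
    reference_gene: str = "reference",
    control_condition: str = "control",
    base_ct: float = 20.0,
    reference_ct: float = 15.0,
    seed: Optional[int] = None,
):
    """Ct table encoding ``truth.qpcr_truth`` fold changes vs the control.

    Target Ct under a treated condition is ``base_ct - log2(fold) + noise``
    (one extra template doubling removes one cycle); the reference gene is
    constant across conditions up to noise. Returns a tidy DataFrame with
    columns ``gene, condition, replicate, ct``.
    """
    import pandas as pd

    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    rng = child_rng(truth.seed if seed is None else seed, "qpcr")
    conditions = [control_condition] + [
        c for c in truth.qpcr_truth if c != control_condition
    ]
    rows = []
    for condition in conditions:
        fold = 1.0 if condition == control_condition else truth.qpcr_truth[condition]
        if fold <= 0:
            raise ValueError(f"fold change for {condition!r} must be > 0")
        for rep in range(1, n_replicates + 1):
            noise_t = rng.normal(0.0, ct_noise_sd) if ct_noise_sd else 0.0
            noise_r = rng.normal(0.0, ct_noise_sd) if ct_noise_sd else 0.0
            rows.append(
                dict(
                    gene=target_gene,
                    condition=condition,
                    replicate=rep,
                    ct=base_ct - math.log2(fold) + noise_t,
                )
            )
            rows.append(
                dict(
                    gene=reference_gene,
                    condition=condition,
                    replicate=rep,
                    ct=reference_ct + noise_r,
                )
            )
    return pd.DataFrame(rows)
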