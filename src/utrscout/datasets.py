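"""One-call simulation of a complete synthetic study with planted truth."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from . import io as _io
from .models import SyntheticTruth
from .synthetic_data import (
    generate_coverage,
    generate_genome,
    generate_qpcr,
    generate_race_reads,
    generate_screen_events,
    plant_utrs,
)

#: Study-scale defaults: a 10-gene / 50 kb genome, depth-100 Poisson
#: coverage, 10 error-free RACE reads per UTR, a reporter screen of 50,000
#: events per sample with 40% per-cell CV and a planted 2x down-shift under
#: 5% ethanol, and a qPCR table encoding a 2-fold induction.
DEFAULT_CONFIG: dict = {
    "n_genes": 10,
    "genome_length": 50_000,
    "mean_depth": 100.0,
    "noise_model": "poisson",
    "background_depth": 0.0,
    "utr_lengths": None,
    "utr_ratios": None,
    "n_reads_per_utr": 10,
    "race_error_rate": 0.0,
    "n_events": 50_000,
    "cv": 0.4,
    "screen_truth": {
        ("Control-GFP", "RMG"): 100.0,
        ("Control-GFP", "ethanol_5"): 100.0,
        ("UTR_demo", "RMG"): 100.0,
        ("UTR_demo", "ethanol_5"): 50.0,
    },
    "qpcr_truth": {"ethanol_5": 2.0},
}


def build_truth(seed: int, config: Optional[dict] = None) -> tuple:
    """Generate genome + genes + planted UTRs, returning (sequence, truth)."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    sequence, genes = generate_genome(cfg["n_genes"], cfg["genome_length"], seed)
    utrs = plant_utrs(
        genes,
        cfg["genome_length"],
        lengths=cfg["utr_lengths"],
        ratios=cfg["utr_ratios"],
        seed=seed,
    )
    truth = SyntheticTruth(
        genes=genes,
        utrs=utrs,
        screen_truth=dict(cfg["screen_truth"]),
        qpcr_truth=dict(cfg["qpcr_truth"]),
        seed=seed,
    )
    return sequence, truth


def simulate_dataset(outdir, seed: int, config: Optional[dict] = None) -> dict:
    """Write every pipeline input to ``outdir``; returns the file map."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sequence, truth = build_truth(seed, cfg)
    coverage = generate_coverage(
        truth,
        cfg["genome_length"],
        mean_depth=cfg["mean_depth"],
        noise_model=cfg["noise_model"],
        background_depth=cfg["background_depth"],
    )
    reads = generate_race_reads(
        truth,
        sequence,
        n_reads_per_utr=cfg["n_reads_per_utr"],
        error_rate=cfg["race_error_rate"],
    )
    events = generate_screen_events(truth, n_events=cfg["n_events"], cv=cfg["cv"])
    qpcr = generate_qpcr(truth)

    paths = {
        "genome": outdir / "genome.fasta",
        "gff": outdir / "genes.gff3",
        "coverage_plus": outdir / "coverage_plus.bedgraph",
        "coverage_minus": outdir / "coverage_minus.bedgraph",
        "race_reads": outdir / "race_reads.fasta",
        "screen_events": outdir / "screen_events.csv",
        "qpcr": outdir / "qpcr_ct.tsv",
        "truth": outdir / "truth.json",
    }
    _io.write_fasta(sequence, paths["genome"])
    _io.write_gff3(truth.genes, paths["gff"])
    _io.write_bedgraph(coverage.plus, paths["coverage_plus"])
    _io.write_bedgraph(coverage.minus, paths["coverage_minus"])
    _io.write_reads_fasta(reads, paths["race_reads"])
    events.to_csv(paths["screen_events"], index=False)
    qpcr.to_csv(paths["qpcr"], sep="\t", index=False)
    _io.write_truth_json(truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}
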