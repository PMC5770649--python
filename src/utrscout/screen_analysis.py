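"""Analytics for the reporter screen, qPCR and western read-outs, plus
Golden-Gate insert design for the GFP fusion constructs.

The screen compares per-cell GFP fluorescence of each 5'UTR construct under
stress against the unstressed rich-medium (RMG) control: per sample the
median over >= 50,000 events, per strain x condition the ratio of replicate
medians to the control, and a replicate-aware test decides whether a
construct is stress-responsive.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import QpcrMeasurement, ReporterInsert, ScreenSample, WesternLane

#: BsmBI (Type IIS) recognition site and its reverse complement. The enzyme
#: cuts outside its site, so flanking sites in the right orientation leave a
#: scarless insert — but the insert itself must not contain the site.
BSMBI_SITE = "CGTCTC"
BSMBI_SITE_RC = "GAGACG"

#: Length of coding sequence carried along with each UTR so the native RNA
#: structure around the start codon is preserved; a multiple of 3 keeps the
#: downstream reporter in frame.
CDS_PREFIX_LENGTH = 90


# ---------------------------------------------------------------------------
# fluorescence


def sample_median(sample) -> float:
    """Median fluorescence of one sample (order statistic; mean of the
    central pair for even event counts)."""
    events = sample.events if isinstance(sample, ScreenSample) else np.asarray(sample, float)
    if events.size < 1:
        raise ValueError("sample has no events")
    return float(np.median(events))


def gate_events(events: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Minimal optional gate: drop events below ``floor``."""
    events = np.asarray(events, float)
    kept = events[events >= floor]
    if kept.size == 0:
        raise ValueError("gating removed every event")
    return kept


def fold_change(
    treated_medians: Sequence[float], control_medians: Sequence[float]
) -> tuple:
    """Fluorescence ratio of a treated sample to its control.

    ratio = mean(treated replicate medians) / mean(control replicate
    medians); dispersion = standard deviation (ddof=1) of per-replicate
    ratios — paired treated_i/control_i when replicate counts match,
    treated_i/mean(control) otherwise. Returns ``(ratio, dispersion)``;
    dispersion is 0.0 with a single replicate.
    """
    treated = np.asarray(treated_medians, float)
    control = np.asarray(control_medians, float)
    if treated.size < 1 or control.size < 1:
        raise ValueError("need >= 1 replicate on each side")
    if (treated <= 0).any() or (control <= 0).any():
        raise ValueError("replicate medians must be > 0")
    control_mean = control.mean()
    ratio = float(treated.mean() / control_mean)
    if treated.size == control.size:
        per_rep = treated / control
    else:
        per_rep = treated / control_mean
    dispersion = float(per_rep.std(ddof=1)) if per_rep.size > 1 else 0.0
    return ratio, dispersion


def call_responsive(
    replicate_ratios: Sequence[float],
    *,
    alpha: float = 0.05,
    min_effect: float = 0.5,
) -> dict:
    """Decide whether a strain x condition is stress-responsive.

    A two-sided one-sample t-test on log2 per-replicate ratios against 0
    must give p < ``alpha`` AND the mean |log2 ratio| must reach
    ``min_effect`` (default 0.5, i.e. a 1.4-fold shift). Returns a dict
    with ``responsive``, ``direction`` ("up"/"down"/"none"), ``p_value``
    and ``mean_log2_ratio``.
    """
    ratios = np.asarray(replicate_ratios, float)
    if ratios.size < 2:
        raise ValueError("need >= 2 replicate ratios for a location test")
    if (ratios <= 0).any():
        raise ValueError("replicate ratios must be > 0")
    log2r = np.log2(ratios)
    mean = float(log2r.mean())
    if np.allclose(log2r.std(ddof=1), 0.0):
        # degenerate: identical replicates; responsive only if exactly 0 shift
        # is impossible to test — treat a zero mean as flat, otherwise the
        # t statistic is infinite and the shift is unambiguous
        p = 1.0 if math.isclose(mean, 0.0, abs_tol=1e-12) else 0.0
    else:
        p = float(stats.ttest_1samp(log2r, 0.0).pvalue)
    responsive = bool(p < alpha and abs(mean) >= min_effect)
    direction = "none" if not responsive else ("up" if mean > 0 else "down")
    return {
        "responsive": responsive,
        "direction": direction,
        "p_value": p,
        "mean_log2_ratio": mean,
    }


def parse_sample_column(name: str) -> tuple:
    """Split a ``strain|condition|replicate`` event-table column name."""
    parts = name.split("|")
    if len(parts) != 3:
        raise ValueError(f"malformed sample column {name!r}; expected strain|condition|replicate")
    return parts[0], parts[1], int(parts[2])


def screen_ratio_table(
    events: pd.DataFrame, *, control_condition: str = "RMG"
) -> pd.DataFrame:
    """Per-replicate fluorescence ratios vs the control condition.

    ``events`` has one column per sample (``strain|condition|replicate``).
    Medians are paired replicate-by-replicate against the same strain's
    control. Returns a tidy frame: strain, condition, replicate, median,
    control_median, ratio.
    """
    medians: dict = {}
    for col in events.columns:
        strain, condition, rep = parse_sample_column(col)
        medians[(strain, condition, rep)] = float(np.median(events[col].dropna().to_numpy()))
    rows = []
    for (strain, condition, rep), med in sorted(medians.items()):
        if condition == control_condition:
            continue
        control = medians.get((strain, control_condition, rep))
        if control is None:
            raise ValueError(
                f"no {control_condition} replicate {rep} for strain {strain}"
            )
        rows.append(
            dict(
                strain=strain,
                condition=condition,
                replicate=rep,
                median=med,
                control_median=control,
                ratio=med / control,
            )
        )
    return pd.DataFrame(rows)


def screen_hits(
    ratio_table: pd.DataFrame,
    *,
    alpha: float = 0.05,
    min_effect: float = 0.5,
    fdr: bool = False,
) -> pd.DataFrame:
    """Hit calling over every strain x condition in a ratio table.

    With ``fdr=True``, Benjamini–Hochberg adjusts p-values across the
    conditions within the screen before applying ``alpha`` (off by default
    to match per-candidate reporting).
    """
    rows = []
    for (strain, condition), grp in ratio_table.groupby(["strain", "condition"], sort=True):
        res = call_responsive(grp["ratio"].to_numpy(), alpha=alpha, min_effect=min_effect)
        ratio, disp = fold_change(grp["median"].to_numpy(), grp["control_median"].to_numpy())
        rows.append(
            dict(
                strain=strain,
                condition=condition,
                ratio=ratio,
                ratio_sd=disp,
                mean_log2_ratio=res["mean_log2_ratio"],
                p_value=res["p_value"],
                responsive=res["responsive"],
                direction=res["direction"],
            )
        )
    hits = pd.DataFrame(rows)
    if fdr and not hits.empty:
        adj = stats.false_discovery_control(hits["p_value"].to_numpy())
        hits["p_adjusted"] = adj
        hits["responsive"] = (adj < alpha) & (hits["mean_log2_ratio"].abs() >= min_effect)
        hits["direction"] = np.where(
            ~hits["responsive"], "none", np.where(hits["mean_log2_ratio"] > 0, "up", "down")
        )
    return hits


# ---------------------------------------------------------------------------
# qPCR


def ddct_fold(meas: QpcrMeasurement) -> dict:
    """Relative expression by the comparative ΔΔCt method.

    ΔCt = Ct(target) − Ct(reference) per replicate; ΔΔCt = mean ΔCt(treated)
    − mean ΔCt(control); fold = 2^(−ΔΔCt). Per-replicate folds (each treated
    ΔCt against the mean control ΔCt) and their standard deviation are also
    returned.
    """
    dct_treated = meas.target_ct_treated - meas.reference_ct_treated
    dct_control = meas.target_ct_control - meas.reference_ct_control
    ddct = float(dct_treated.mean() - dct_control.mean())
    per_rep = 2.0 ** -(dct_treated - dct_control.mean())
    sd = float(per_rep.std(ddof=1)) if per_rep.size > 1 else 0.0
    return {
        "ddct": ddct,
        "fold": float(2.0 ** -ddct),
        "replicate_folds": per_rep,
        "fold_sd": sd,
    }


def ddct_from_table(
    table: pd.DataFrame,
    *,
    target_gene: str,
    reference_gene: str,
    treated_condition: str,
    control_condition: str,
) -> dict:
    """ΔΔCt from a tidy Ct table (columns gene, condition, replicate, ct)."""

    def cts(gene: str, condition: str) -> np.ndarray:
        sel = table[(table["gene"] == gene) & (table["condition"] == condition)]
        if sel.empty:
            raise ValueError(f"no Ct rows for gene={gene!r}, condition={condition!r}")
        return sel.sort_values("replicate")["ct"].to_numpy(float)

    meas = QpcrMeasurement(
        target_ct_treated=cts(target_gene, treated_condition),
        reference_ct_treated=cts(reference_gene, treated_condition),
        target_ct_control=cts(target_gene, control_condition),
        reference_ct_control=cts(reference_gene, control_condition),
    )
    return ddct_fold(meas)


# ---------------------------------------------------------------------------
# western blots


def normalize_western(lanes: Sequence[WesternLane]) -> pd.DataFrame:
    """Target band intensity normalized to the internal-control band.

    Each lane's normalized value is target/normalizer (e.g. GFP/RecA, or
    target/total-protein when loading is normalized by total mass); returns
    per-condition mean and standard deviation over replicates.
    """
    if not lanes:
        raise ValueError("no lanes")
    df = pd.DataFrame(
        dict(
            condition=[l.condition for l in lanes],
            replicate=[l.replicate for l in lanes],
            normalized=[l.target_intensity / l.normalizer_intensity for l in lanes],
        )
    )
    out = (
        df.groupby("condition", sort=False)["normalized"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="count")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# reporter insert design


def _find_sites(seq: str) -> list:
    """Offsets of BsmBI recognition sites (either orientation) in ``seq``."""
    hits = []
    for site in (BSMBI_SITE, BSMBI_SITE_RC):
        at = seq.find(site)
        while at != -1:
            hits.append(at)
            at = seq.find(site, at + 1)
    return sorted(set(hits))


def design_reporter_insert(utr: str, cds: str) -> ReporterInsert:
    """Build the UTR + first-90-nt-of-CDS insert for Golden Gate cloning.

    The insert is flanked by outward-cutting BsmBI recognition contexts so
    digestion releases it with its own terminal overhangs (scarless,
    directional). Fails with the offending offset if the UTR or CDS prefix
    contains an internal BsmBI site on either strand, and if the CDS is
    shorter than 90 nt.
    """
    utr = utr.upper()
    cds = cds.upper()
    for name, seq in (("utr", utr), ("cds", cds)):
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(f"{name} contains non-ACGT characters: {sorted(bad)}")
    if len(cds) < CDS_PREFIX_LENGTH:
        raise ValueError(
            f"cds is {len(cds)} nt; need >= {CDS_PREFIX_LENGTH} nt to preserve "
            "the native context in frame"
        )
    prefix = cds[:CDS_PREFIX_LENGTH]
    insert = utr + prefix
    sites = _find_sites(insert)
    if sites:
        raise ValueError(
            f"internal BsmBI site at offset {sites[0]} of the insert; "
            "the construct cannot be assembled by Golden Gate"
        )
    # recognition site + 1-nt spacer upstream; mirrored downstream, so both
    # cuts fall inside the insert's own terminal 4-mers
    return ReporterInsert(
        utr_sequence=utr,
        cds_prefix=prefix,
        flank_left=BSMBI_SITE + "A",
        flank_right="A" + BSMBI_SITE_RC,
    )
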