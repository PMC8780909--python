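"""First-order mRNA decay kinetics from metabolic-labeling ratios.

Under first-order decay with rate k, the fraction of a gene's steady-state
mRNA pool synthesized during a 4SU labeling pulse of length tL is

    R = 1 - exp(-k * tL),

so the half-life follows from the spike-in-normalized nascent/total count
ratio as

    t1/2 = ln(2) / k = -tL * ln(2) / ln(1 - R).

R outside (0, 1) has no kinetic interpretation and is flagged, never
clamped: clamping at 1 - eps would fabricate arbitrarily short half-lives.

The module also classifies half-life changes between two conditions at a
fold threshold (default 1.5x, boundary inclusive) and fits single-rate
exponential decay curves from transcription-inhibition (actinomycin D)
time courses by ordinary least squares on log abundance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .counttable import CountTable
from .errors import KineticsError, ValidationError

QC_OK = "ok"
QC_LOW_COUNT = "low_count"
QC_RATIO_RANGE = "ratio_out_of_range"

LABEL_PROLONGED = "prolonged"
LABEL_SHORTENED = "shortened"
LABEL_UNCHANGED = "unchanged"


@dataclass(frozen=True)
class LabelingDesign:
    """4SU pulse length (minutes) and the pair of conditions compared."""

    label_time: float = 60.0
    reference: str = "WT"
    perturbed: str = "KO"

    def __post_init__(self) -> None:
        if not self.label_time > 0:
            raise ValidationError("label_time must be > 0")


def half_life_from_ratio(ratio, label_time: float = 60.0):
    """Half-life (min) from the labeling ratio R = nascent/total.

    Accepts scalars or arrays; raises on R outside the open interval (0, 1).
    Strictly decreasing in R: a larger labeled fraction means faster
    turnover.
    """
    r = np.asarray(ratio, dtype=float)
    if not label_time > 0:
        raise ValidationError("label_time must be > 0")
    if np.any(r <= 0) or np.any(r >= 1):
        raise ValidationError("labeling ratio must satisfy 0 < R < 1")
    t = -label_time * math.log(2) / np.log1p(-r)
    return float(t) if np.isscalar(ratio) else t


def ratio_from_half_life(t_half, label_time: float = 60.0):
    """Labeling ratio R expected for a half-life; exact inverse of
    :func:`half_life_from_ratio`."""
    t = np.asarray(t_half, dtype=float)
    if not label_time > 0:
        raise ValidationError("label_time must be > 0")
    if np.any(t <= 0):
        raise ValidationError("half-life must be > 0")
    r = -np.expm1(-label_time * math.log(2) / t)
    return float(r) if np.isscalar(t_half) else r


def estimate_half_lives(
    norm: CountTable,
    design: LabelingDesign,
    min_count: float = 10.0,
    raw: CountTable | None = None,
    include_spikeins: bool = False,
) -> pd.DataFrame:
    """Per-gene, per-condition labeling ratios and half-lives with QC flags.

    For each condition, R = (mean normalized nascent count across
    replicates) / (mean normalized total count).  Genes whose mean *raw*
    total count (from ``raw`` if given, else the normalized table) falls
    below ``min_count`` are flagged ``low_count``; genes with R outside
    (0, 1) are flagged ``ratio_out_of_range``.  Flagged genes carry no
    half-life.

    Returns a tidy DataFrame: gene_id, condition, ratio, t_half, qc,
    mean_total_raw.
    """
    frames = []
    for cond in norm.conditions:
        nas = norm.sample_ids(condition=cond, assay="nascent")
        tot = norm.sample_ids(condition=cond, assay="total")
        if not nas or not tot:
            raise KineticsError(f"condition {cond!r} lacks a nascent or total assay")
        nas_mean = norm.counts[nas].mean(axis=1)
        tot_mean = norm.counts[tot].mean(axis=1)
        raw_tot = (raw or norm).counts[tot].mean(axis=1)

        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = nas_mean / tot_mean
        qc = pd.Series(QC_OK, index=norm.counts.index)
        qc[~((ratio > 0) & (ratio < 1))] = QC_RATIO_RANGE
        qc[raw_tot < min_count] = QC_LOW_COUNT

        t_half = pd.Series(np.nan, index=norm.counts.index)
        ok = qc == QC_OK
        if ok.any():
            t_half[ok] = half_life_from_ratio(ratio[ok].to_numpy(), design.label_time)

        frames.append(
            pd.DataFrame(
                {
                    "gene_id": norm.counts.index,
                    "condition": cond,
                    "ratio": ratio.to_numpy(),
                    "t_half": t_half.to_numpy(),
                    "qc": qc.to_numpy(),
                    "mean_total_raw": raw_tot.to_numpy(),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    if not include_spikeins:
        keep = ~out["gene_id"].map(norm.spikein).to_numpy()
        out = out.loc[keep].reset_index(drop=True)
    return out


def replicate_ratios(norm: CountTable, condition: str) -> pd.DataFrame:
    """Diagnostic: per-replicate nascent/total ratios (replicates paired by
    index), for judging how stable the pooled R is."""
    sub = norm.samples[norm.samples["condition"] == condition]
    cols = {}
    for rep in sorted(sub["replicate"].unique()):
        nas = sub[(sub["assay"] == "nascent") & (sub["replicate"] == rep)].index
        tot = sub[(sub["assay"] == "total") & (sub["replicate"] == rep)].index
        if len(nas) == 1 and len(tot) == 1:
            with np.errstate(divide="ignore", invalid="ignore"):
                cols[f"rep{rep}"] = (
                    norm.counts[nas[0]] / norm.counts[tot[0]]
                ).to_numpy()
    return pd.DataFrame(cols, index=norm.counts.index)


def classify_pair(
    t_half_ref: float, t_half_perturbed: float, fold_threshold: float = 1.5
) -> tuple[float, str]:
    """(ratio, label) for one gene's half-life pair.

    ratio = perturbed / reference; 'prolonged' when ratio >= threshold
    (boundary inclusive), 'shortened' when ratio <= 1/threshold, else
    'unchanged'.
    """
    if not fold_threshold > 1:
        raise ValidationError("fold_threshold must be > 1")
    if not (t_half_ref > 0 and t_half_perturbed > 0) or not (
        np.isfinite(t_half_ref) and np.isfinite(t_half_perturbed)
    ):
        raise ValidationError("half-lives must be positive finite")
    ratio = t_half_perturbed / t_half_ref
    if ratio >= fold_threshold:
        return ratio, LABEL_PROLONGED
    if ratio <= 1.0 / fold_threshold:
        return ratio, LABEL_SHORTENED
    return ratio, LABEL_UNCHANGED


def classify_changes(
    halflives: pd.DataFrame,
    design: LabelingDesign,
    fold_threshold: float = 1.5,
) -> pd.DataFrame:
    """Classify each gene's perturbed/reference half-life ratio.

    Only genes with qc == ok in both conditions receive a call; others are
    dropped (a flagged estimate cannot support a fold change).  Returns
    gene_id, t_half_<ref>, t_half_<perturbed>, halflife_ratio, label.
    """
    ref = halflives[
        (halflives["condition"] == design.reference) & (halflives["qc"] == QC_OK)
    ].set_index("gene_id")["t_half"]
    per = halflives[
        (halflives["condition"] == design.perturbed) & (halflives["qc"] == QC_OK)
    ].set_index("gene_id")["t_half"]
    genes = ref.index.intersection(per.index)
    ratio = (per[genes] / ref[genes]).to_numpy()
    label = np.where(
        ratio >= fold_threshold,
        LABEL_PROLONGED,
        np.where(ratio <= 1.0 / fold_threshold, LABEL_SHORTENED, LABEL_UNCHANGED),
    )
    return pd.DataFrame(
        {
            "gene_id": genes,
            f"t_half_{design.reference}": ref[genes].to_numpy(),
            f"t_half_{design.perturbed}": per[genes].to_numpy(),
            "halflife_ratio": ratio,
            "label": label,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# transcription-inhibition (actinomycin D) decay curves
# ---------------------------------------------------------------------------

@dataclass
class DecayTimeCourse:
    """Relative abundance over time after transcription shutoff.

    Times in minutes, strictly increasing, starting at 0; values are
    abundances relative to t=0 (positive).
    """

    gene_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValidationError("times and values must be 1-D and equal length")
        if len(self.times) and self.times[0] != 0:
            raise ValidationError("time course must start at t=0")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.values <= 0) or not np.all(np.isfinite(self.values)):
            raise ValidationError("abundances must be positive finite")


@dataclass
class DecayFit:
    """Result of a log-linear exponential-decay fit."""

    t_half: float  # minutes; NaN when non-decaying
    decay_rate: float  # -slope, min^-1
    log_intercept: float
    r_squared: float
    decaying: bool
    n_points: int


def fit_exponential_decay(tc: DecayTimeCourse) -> DecayFit:
    """Single-rate exponential fit: OLS of ln(abundance) on time.

    t1/2 = -ln(2)/slope.  A non-negative slope means no measurable decay
    over the course; the fit is returned flagged with t_half = NaN rather
    than a negative half-life.
    """
    if len(tc.times) < 3:
        raise ValidationError("need at least 3 timepoints to fit a decay rate")
    res = sps.linregress(tc.times, np.log(tc.values))
    slope = float(res.slope)
    decaying = slope < 0
    t_half = -math.log(2) / slope if decaying else float("nan")
    return DecayFit(
        t_half=t_half,
        decay_rate=-slope,
        log_intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2 if np.isfinite(res.rvalue) else 0.0,
        decaying=decaying,
        n_points=len(tc.times),
    )
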