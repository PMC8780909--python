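"""Synthetic 4SU/TT-seq experiment generator with known ground truth.

The generative model mirrors the measurement process the kinetic analysis
assumes:

* each endogenous gene transcribes at a constant synthesis rate s and decays
  first-order with rate k (condition-specific), so its steady-state total
  abundance is s/k;
* a 4SU pulse of length tL labels the newly made fraction, so the nascent
  (pull-down) abundance is total * (1 - exp(-k*tL)) * capture efficiency;
* a designated target-gene subset decays ``ko_halflife_fold`` times slower
  in the KO condition (the reader-knockout effect); all other genes and all
  spike-ins are condition-invariant;
* spike-in RNA is added in a fixed amount per sample and is itself
  4SU-labeled, hence present in both assays at the same expected level;
* every sample's expected depth is ``library_size`` times a log-normal
  depth distortion, giving normalization something real to correct; the
  exact per-sample expected scale is recorded in the ground truth;
* counts are marginally negative binomial with the stated dispersion:
  a per-(gene, condition, replicate) gamma factor — shared between the
  nascent and total libraries of that replicate, because both are prepared
  from one RNA extraction — multiplies the expectation, and Poisson
  counting noise is drawn on top.  Spike-ins receive counting noise only
  (the spiked pool is identical in every sample).

Alongside counts the generator emits transcript models (5'UTR/CDS/3'UTR on
a synthetic chromosome) and m6A / YTHDF1 / AGO2 peak sets: m6A and YTHDF1
peaks sit in the 3'UTRs of target genes, AGO2 peaks cover a configurable
fraction of those targets plus background non-targets, so peak→gene
overlap logic can be validated against the planted truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .counttable import CountTable, make_sample_sheet
from .errors import ValidationError
from .genomics import GenomicInterval, PeakSet, TranscriptModel, write_transcript_models
from .kinetics import DecayTimeCourse

CONDITIONS = ("WT", "KO")
ASSAYS = ("total", "nascent")
PEAK_FACTORS = ("m6A", "YTHDF1", "AGO2")


@dataclass(frozen=True)
class SimulationParams:
    """Study-design knobs for one synthetic TT-seq experiment.

    Defaults describe a desk-scale two-condition experiment: 2,000 genes,
    50 spike-ins, a 60-minute 4SU pulse, two replicates per condition and
    assay at 2e6 expected reads, WT half-lives log-uniform on 10–600 min,
    25% target genes whose half-life doubles in the KO.
    """

    n_genes: int = 2000
    n_spikeins: int = 50
    halflife_range_wt: tuple[float, float] = (10.0, 600.0)
    target_fraction: float = 0.25
    ko_halflife_fold: float = 2.0
    label_time: float = 60.0
    library_size: float = 2e6
    n_replicates: int = 2
    dispersion: float = 0.05
    capture_efficiency: float = 1.0
    depth_sd: float = 0.2
    spikein_fraction: float = 0.01
    ago2_cobinding_fraction: float = 0.92
    ago2_background_fraction: float = 0.10
    peak_width: int = 60
    seed: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.halflife_range_wt
        if not (0 < lo <= hi):
            raise ValidationError("halflife_range_wt must be positive and ordered")
        if self.n_genes < 1 or self.n_spikeins < 0 or self.n_replicates < 1:
            raise ValidationError("n_genes, n_spikeins, n_replicates out of range")
        if not 0 <= self.target_fraction <= 1:
            raise ValidationError("target_fraction must be in [0, 1]")
        if not self.ko_halflife_fold > 0:
            raise ValidationError("ko_halflife_fold must be > 0")
        if not self.library_size > 0:
            raise ValidationError("library_size must be > 0")
        if not self.label_time > 0:
            raise ValidationError("label_time must be > 0")
        if self.dispersion < 0 or self.depth_sd < 0:
            raise ValidationError("dispersion and depth_sd must be >= 0")
        if not 0 < self.capture_efficiency <= 1:
            raise ValidationError("capture_efficiency must be in (0, 1]")
        if not 0 < self.spikein_fraction < 1:
            raise ValidationError("spikein_fraction must be in (0, 1)")
        if not 0 <= self.ago2_cobinding_fraction <= 1:
            raise ValidationError("ago2_cobinding_fraction must be in [0, 1]")


@dataclass
class SimulationResult:
    """Everything one simulated experiment produced, truth included."""

    counts: CountTable
    kinetics: pd.DataFrame  # per-gene ground truth
    peaks: dict[str, PeakSet]
    transcripts: list[TranscriptModel]
    sample_info: pd.DataFrame  # per-sample depth_distortion + expected_scale
    params: SimulationParams = field(repr=False)

    @property
    def target_gene_ids(self) -> set[str]:
        k = self.kinetics
        return set(k.loc[k["is_target"], "gene_id"])

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all tables/BEDs to a directory; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": outdir / "counts.tsv",
            "samples": outdir / "samples.tsv",
            "kinetics": outdir / "kinetics_truth.tsv",
            "transcripts": outdir / "transcripts.tsv",
            "sample_info": outdir / "sample_scales.tsv",
        }
        self.counts.to_tsv(paths["counts"], paths["samples"])
        self.kinetics.to_csv(paths["kinetics"], sep="\t", index=False)
        write_transcript_models(self.transcripts, paths["transcripts"])
        self.sample_info.to_csv(paths["sample_info"], sep="\t", index=False)
        for factor, ps in self.peaks.items():
            p = outdir / f"peaks_{factor}.bed"
            ps.to_bed(p)
            paths[f"peaks_{factor}"] = p
        return paths


def _expected_base_abundances(kin: pd.DataFrame, params: SimulationParams) -> dict:
    """Expected relative abundance per gene for each (condition, assay)."""
    base: dict[tuple[str, str], np.ndarray] = {}
    spike = kin["is_spikein"].to_numpy()
    spike_abund = kin["spikein_abundance"].to_numpy()
    for cond in CONDITIONS:
        k = kin[f"decay_rate_{cond.lower()}"].to_numpy()
        total = np.where(spike, spike_abund, kin["synthesis_rate"].to_numpy() / k)
        labeled_frac = -np.expm1(-k * params.label_time)
        nascent = np.where(spike, spike_abund, total * labeled_frac)
        nascent = nascent * params.capture_efficiency
        base[(cond, "total")] = total
        base[(cond, "nascent")] = nascent
    return base


def _make_transcripts(
    gene_ids: list[str], rng: np.random.Generator
) -> list[TranscriptModel]:
    """One single-block-per-region transcript per gene on a synthetic
    chromosome, random strand, genes separated by fixed gaps."""
    models = []
    offset = 1000
    for gid in gene_ids:
        l5 = int(rng.integers(100, 301))
        lc = int(rng.integers(600, 3001))
        l3 = int(rng.integers(200, 1201))
        strand = str(rng.choice(["+", "-"]))
        total = l5 + lc + l3
        g0 = offset
        if strand == "+":
            utr5 = (GenomicInterval("chrS", g0, g0 + l5, strand),)
            cds = (GenomicInterval("chrS", g0 + l5, g0 + l5 + lc, strand),)
            utr3 = (GenomicInterval("chrS", g0 + l5 + lc, g0 + total, strand),)
        else:
            utr5 = (GenomicInterval("chrS", g0 + total - l5, g0 + total, strand),)
            cds = (GenomicInterval("chrS", g0 + l3, g0 + total - l5, strand),)
            utr3 = (GenomicInterval("chrS", g0, g0 + l3, strand),)
        models.append(
            TranscriptModel(gene_id=gid, chrom="chrS", strand=strand,
                            utr5=utr5, cds=cds, utr3=utr3)
        )
        offset = g0 + total + 1000
    return models


def _place_peak_in_region(
    tx: TranscriptModel, region: str, width: int, rng: np.random.Generator,
    name: str,
) -> GenomicInterval:
    """Uniformly placed peak fully inside one block of the region."""
    blocks = tx.blocks(region)
    lengths = np.array([len(b) for b in blocks], dtype=float)
    b = blocks[int(rng.choice(len(blocks), p=lengths / lengths.sum()))]
    w = min(width, len(b))
    start = int(rng.integers(b.start, b.end - w + 1))
    return GenomicInterval(tx.chrom, start, start + w, tx.strand, name=name)


def simulate_experiment(params: SimulationParams) -> SimulationResult:
    """Generate one complete synthetic experiment; deterministic given
    ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    n, n_spike = params.n_genes, params.n_spikeins
    gene_ids = [f"G{i:05d}" for i in range(1, n + 1)]
    spike_ids = [f"SPIKE{i:03d}" for i in range(1, n_spike + 1)]

    # --- ground-truth kinetics -------------------------------------------
    lo, hi = params.halflife_range_wt
    t_half_wt = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    synthesis = np.exp(rng.normal(0.0, 1.0, size=n))
    n_targets = int(round(params.target_fraction * n))
    target_idx = rng.choice(n, size=n_targets, replace=False)
    is_target = np.zeros(n, dtype=bool)
    is_target[target_idx] = True
    t_half_ko = np.where(is_target, t_half_wt * params.ko_halflife_fold, t_half_wt)

    spike_abund_raw = np.exp(rng.normal(0.0, 0.5, size=n_spike))
    # spike-in pool scaled to a fixed fraction of the WT total-assay mass
    gene_total_mass = float(np.sum(synthesis * t_half_wt / math.log(2)))
    if n_spike:
        spike_abund = spike_abund_raw * (
            params.spikein_fraction * gene_total_mass / spike_abund_raw.sum()
        )
    else:
        spike_abund = spike_abund_raw

    kin = pd.DataFrame(
        {
            "gene_id": gene_ids + spike_ids,
            "synthesis_rate": np.concatenate([synthesis, np.zeros(n_spike)]),
            "decay_rate_wt": np.concatenate(
                [math.log(2) / t_half_wt, np.full(n_spike, math.log(2) / 60.0)]
            ),
            "decay_rate_ko": np.concatenate(
                [math.log(2) / t_half_ko, np.full(n_spike, math.log(2) / 60.0)]
            ),
            "t_half_wt": np.concatenate([t_half_wt, np.full(n_spike, 60.0)]),
            "t_half_ko": np.concatenate([t_half_ko, np.full(n_spike, 60.0)]),
            "is_target": np.concatenate([is_target, np.zeros(n_spike, dtype=bool)]),
            "is_spikein": np.concatenate(
                [np.zeros(n, dtype=bool), np.ones(n_spike, dtype=bool)]
            ),
            "spikein_abundance": np.concatenate([np.zeros(n), spike_abund]),
        }
    )
    base = _expected_base_abundances(kin, params)
    for key, vals in base.items():
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValidationError(f"non-finite expected abundance in {key}")

    # --- transcript models + peak sets -----------------------------------
    transcripts = _make_transcripts(gene_ids, rng)
    tx_by_gene = {t.gene_id: t for t in transcripts}
    target_ids = [gene_ids[i] for i in sorted(target_idx)]
    peaks: dict[str, PeakSet] = {f: PeakSet(name=f) for f in PEAK_FACTORS}
    for gid in target_ids:
        tx = tx_by_gene[gid]
        for factor in ("m6A", "YTHDF1"):
            peaks[factor].intervals.append(
                _place_peak_in_region(tx, "utr3", params.peak_width, rng,
                                      name=f"{factor}_{gid}")
            )
    n_cobound = int(round(params.ago2_cobinding_fraction * len(target_ids)))
    cobound = sorted(
        rng.choice(len(target_ids), size=n_cobound, replace=False).tolist()
    )
    ago2_genes = [target_ids[i] for i in cobound]
    nontargets = [g for g in gene_ids if g not in set(target_ids)]
    n_bg = int(round(params.ago2_background_fraction * len(nontargets)))
    if n_bg:
        bg_idx = sorted(rng.choice(len(nontargets), size=n_bg, replace=False).tolist())
        ago2_genes = ago2_genes + [nontargets[i] for i in bg_idx]
    for gid in ago2_genes:
        peaks["AGO2"].intervals.append(
            _place_peak_in_region(tx_by_gene[gid], "utr3", params.peak_width,
                                  rng, name=f"AGO2_{gid}")
        )

    # --- counts ----------------------------------------------------------
    samples = make_sample_sheet(list(CONDITIONS), list(ASSAYS), params.n_replicates)
    distortions = pd.Series(
        np.exp(rng.normal(0.0, params.depth_sd, size=len(samples))),
        index=samples.index,
    )
    # biological factor shared between the two assays of one (condition,
    # replicate); spike-ins always 1
    eps: dict[tuple[str, int], np.ndarray] = {}
    for cond in CONDITIONS:
        for rep in range(1, params.n_replicates + 1):
            if params.dispersion > 0:
                e = rng.gamma(1.0 / params.dispersion, params.dispersion, size=n)
            else:
                e = np.ones(n)
            eps[(cond, rep)] = np.concatenate([e, np.ones(n_spike)])

    counts = {}
    scales = pd.Series(0.0, index=samples.index)
    for sid, row in samples.iterrows():
        b = base[(row["condition"], row["assay"])]
        scale = params.library_size * distortions[sid] / b.sum()
        scales[sid] = scale
        lam = b * scale * eps[(row["condition"], int(row["replicate"]))]
        counts[sid] = rng.poisson(lam)
    count_df = pd.DataFrame(counts, index=kin["gene_id"].to_numpy())

    table = CountTable(
        counts=count_df,
        samples=samples,
        spikein=pd.Series(kin["is_spikein"].to_numpy(), index=count_df.index),
    )
    sample_info = samples.reset_index()
    sample_info["depth_distortion"] = distortions.to_numpy()
    sample_info["expected_scale"] = scales.to_numpy()
    return SimulationResult(
        counts=table,
        kinetics=kin,
        peaks=peaks,
        transcripts=transcripts,
        sample_info=sample_info,
        params=params,
    )


def simulate_decay_timecourse(
    t_half: float,
    times,
    noise_sd: float = 0.0,
    seed: int | None = None,
    gene_id: str = "gene",
) -> DecayTimeCourse:
    """Exponential decay time course with multiplicative log-normal noise.

    Values are 2^(-t/t_half) perturbed by lognormal(0, noise_sd) noise and
    renormalized to the (noisy) t=0 measurement, as a real shutoff
    experiment reports fractions of the first timepoint.
    """
    if not t_half > 0:
        raise ValidationError("t_half must be > 0")
    t = np.asarray(times, dtype=float)
    if len(t) == 0 or t[0] != 0:
        raise ValidationError("times must start at 0")
    values = np.exp2(-t / t_half)
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values * rng.lognormal(0.0, noise_sd, size=len(t))
    values = values / values[0]
    return DecayTimeCourse(gene_id=gene_id, times=t, values=values)


def params_to_dict(params: SimulationParams) -> dict:
    d = asdict(params)
    d["halflife_range_wt"] = list(d["halflife_range_wt"])
    return d
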