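"""Synthetic data with known ground truth for every pipeline stage.

Calcium traces are generated as an event train convolved with a
difference-of-exponentials kernel: each responder cell receives a Poisson
train of transient events after the stimulus (amino-acid withdrawal), split
into an initiation window (first 240 s post-stimulus) and a maintenance
window (the remainder of the recording), whose rate can be scaled or zeroed
independently to emulate maintenance-specific perturbations. Per-event peak
amplitudes are log-normal in ΔF/F units. Raw fluorescence is

    F_i(t) = F0_i * (1 + sum_k A_k K(t - t_k)) * exp(-bleach_rate * t) + noise,

with log-normal per-cell baselines F0_i and Gaussian noise proportional to
the baseline. Non-responders carry baseline plus noise only, so a noise-only
("mock withdrawal") condition yields no cell crossing the ΔF/F = 1.5
responder threshold.

Release traces (vesicular-cargo fluorescence loss), differential-expression
tables with planted up/down genes, and qPCR Ct tables with planted fold
changes are generated analogously, each with its ground truth recorded.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import (HEMISEGMENT_ORDER, SEGMENTS, SIDES, SchemaError,
                         TraceMatrix, validate_cell_table)

#: Duration of the initiation phase after the stimulus, seconds. With the
#: default 60 s stimulus this makes the initiation window 60-300 s and the
#: maintenance window 300-600 s of a 600 s recording.
INITIATION_SPAN_S = 240.0


class PresetError(ValueError):
    """A generative parameter is out of its valid range."""


@dataclass(frozen=True)
class ConditionPreset:
    """Generative parameters of one simulated experimental condition.

    Amplitude defaults put the median event peak at ΔF/F = 3 with a log-sd
    of 0.25, so >99% of event peaks clear the 1.5 responder threshold and
    the classified responder fraction tracks ``responder_prob``.
    """

    name: str
    responder_prob: float
    init_event_rate: float = 0.02     # events/s during initiation
    maint_event_rate: float = 0.015   # events/s during maintenance
    maint_multiplier: float = 1.0     # scales maintenance event rate
    amp_log_mean: float = math.log(3.0)
    amp_log_sd: float = 0.25
    tau_rise_s: float = 4.0
    tau_decay_s: float = 30.0
    noise_sd: float = 0.05            # fraction of baseline fluorescence
    bleach_rate: float = 0.0          # per-second exponential fading

    def validate(self) -> "ConditionPreset":
        if not 0.0 <= self.responder_prob <= 1.0:
            raise PresetError(f"responder_prob={self.responder_prob} not in [0, 1]")
        for fname in ("init_event_rate", "maint_event_rate", "maint_multiplier",
                      "amp_log_sd", "noise_sd", "bleach_rate"):
            if getattr(self, fname) < 0:
                raise PresetError(f"{fname}={getattr(self, fname)} must be >= 0")
        if self.tau_rise_s <= 0 or self.tau_decay_s <= 0:
            raise PresetError("tau_rise_s and tau_decay_s must be > 0")
        if self.tau_rise_s >= self.tau_decay_s:
            raise PresetError(
                f"tau_rise_s={self.tau_rise_s} must be < tau_decay_s={self.tau_decay_s}"
            )
        return self


#: Presets emulating the study conditions. Responder probabilities encode the
#: reported responder fractions (~50% EAA withdrawal, 42% arginine withdrawal,
#: 27% EAA-minus-arginine, 0% mock withdrawal); "maintenance-block" zeroes the
#: maintenance-phase event rate of an all-responder control, the shape of a
#: peptide-signaling block that spares initiation.
PRESETS: dict[str, ConditionPreset] = {
    "mock": ConditionPreset("mock", responder_prob=0.0,
                            init_event_rate=0.0, maint_event_rate=0.0),
    "eaa-withdrawal": ConditionPreset("eaa-withdrawal", responder_prob=0.5),
    "arginine-withdrawal": ConditionPreset("arginine-withdrawal", responder_prob=0.42),
    "eaa-minus-arginine": ConditionPreset("eaa-minus-arginine", responder_prob=0.27),
    "control": ConditionPreset("control", responder_prob=1.0),
    "maintenance-block": ConditionPreset("maintenance-block", responder_prob=1.0,
                                         maint_multiplier=0.0),
}


@dataclass(frozen=True)
class SimConfig:
    """One simulated recording: geometry, clock, baseline model, preset, seed.

    ``seed`` is mandatory; an unseeded simulation is an error so that every
    generated dataset is reproducible by construction.
    """

    n_cells: int
    preset: ConditionPreset
    seed: int
    n_preps: int = 5
    frame_interval_s: float = 4.0
    duration_s: float = 600.0
    stim_time_s: float = 60.0
    baseline_log_mean: float = math.log(100.0)
    baseline_log_sd: float = 0.25
    hemisegment_probs: Sequence[float] | None = None

    def validate(self) -> "SimConfig":
        if self.seed is None:
            raise PresetError("seed is required: unseeded simulations are an error")
        if self.n_cells < 1:
            raise PresetError(f"n_cells={self.n_cells} must be >= 1")
        if self.n_preps < 1:
            raise PresetError(f"n_preps={self.n_preps} must be >= 1")
        if self.frame_interval_s <= 0:
            raise PresetError(f"frame_interval_s={self.frame_interval_s} must be > 0")
        if not self.stim_time_s < self.duration_s:
            raise PresetError(
                f"stim_time_s={self.stim_time_s} must be < duration_s={self.duration_s}"
            )
        if self.hemisegment_probs is not None:
            p = np.asarray(self.hemisegment_probs, dtype=float)
            if p.shape != (len(HEMISEGMENT_ORDER),) or p.min() < 0 or not math.isclose(p.sum(), 1.0):
                raise PresetError(
                    "hemisegment_probs must be 12 non-negative values summing to 1"
                )
        self.preset.validate()
        return self


@dataclass
class SimulatedDataset:
    """Traces plus cell metadata plus per-cell ground truth."""

    traces: TraceMatrix
    cells: pd.DataFrame
    truth: pd.DataFrame
    event_times: dict[str, np.ndarray] = field(default_factory=dict)


def kernel_peak_time(tau_rise_s: float, tau_decay_s: float) -> float:
    """Time of the kernel maximum for a difference of exponentials."""
    return (math.log(tau_decay_s / tau_rise_s)
            * tau_rise_s * tau_decay_s / (tau_decay_s - tau_rise_s))


def transient_kernel(t: np.ndarray, tau_rise_s: float, tau_decay_s: float) -> np.ndarray:
    """Unit-peak transient kernel K(t) = (e^(-t/τd) - e^(-t/τr)) / peak, 0 for t <= 0."""
    tt = np.maximum(np.asarray(t, dtype=float), 0.0)  # K(0)=0, so clipping zeroes t<0
    raw = np.exp(-tt / tau_decay_s) - np.exp(-tt / tau_rise_s)
    tpk = kernel_peak_time(tau_rise_s, tau_decay_s)
    peak = math.exp(-tpk / tau_decay_s) - math.exp(-tpk / tau_rise_s)
    return raw / peak


def _frame_times(config: SimConfig) -> np.ndarray:
    n_frames = int(round(config.duration_s / config.frame_interval_s)) + 1
    return np.arange(n_frames) * config.frame_interval_s


def _make_cells(config: SimConfig, rng: np.random.Generator,
                condition: str, genotype: str) -> pd.DataFrame:
    n = config.n_cells
    if config.hemisegment_probs is not None:
        hs_idx = rng.choice(len(HEMISEGMENT_ORDER), size=n,
                            p=np.asarray(config.hemisegment_probs, dtype=float))
    else:
        # Uniform at random: responders showed no anatomical bias across T3-A5.
        hs_idx = rng.integers(0, len(HEMISEGMENT_ORDER), size=n)
    segments = [SEGMENTS[i // 2] for i in hs_idx]
    sides = [SIDES[i % 2] for i in hs_idx]
    cells = pd.DataFrame({
        "cell_id": [f"c{i:04d}" for i in range(n)],
        "prep_id": [f"prep{(i % config.n_preps) + 1}" for i in range(n)],
        "segment": segments,
        "hemisegment": sides,
        "condition": condition,
        "genotype": genotype,
    })
    return validate_cell_table(cells)


def simulate_traces(config: SimConfig, genotype: str = "control") -> SimulatedDataset:
    """Simulate a population recording under one condition preset.

    Responders receive a Poisson event train confined to t >= stimulus; no
    cell carries any evoked signal before the stimulus. Identical config and
    seed reproduce the dataset bit for bit.
    """
    config.validate()
    p = config.preset
    rng = np.random.default_rng(config.seed)
    times = _frame_times(config)
    n = config.n_cells

    F0 = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    is_resp = rng.random(n) < p.responder_prob

    init_lo = config.stim_time_s
    init_hi = min(config.stim_time_s + INITIATION_SPAN_S, config.duration_s)
    maint_lo, maint_hi = init_hi, config.duration_s

    F = np.empty((n, times.size))
    event_times: dict[str, np.ndarray] = {}
    n_events = np.zeros(n, dtype=int)
    cell_ids = [f"c{i:04d}" for i in range(n)]
    for i in range(n):
        signal = np.zeros_like(times)
        ev = np.empty(0)
        if is_resp[i]:
            k_init = rng.poisson(p.init_event_rate * (init_hi - init_lo))
            t_init = rng.uniform(init_lo, init_hi, size=k_init)
            k_maint = rng.poisson(
                p.maint_event_rate * p.maint_multiplier * max(maint_hi - maint_lo, 0.0))
            t_maint = rng.uniform(maint_lo, maint_hi, size=k_maint) if k_maint else np.empty(0)
            ev = np.sort(np.concatenate([t_init, t_maint]))
            if ev.size:
                amps = rng.lognormal(p.amp_log_mean, p.amp_log_sd, size=ev.size)
                signal = (amps[:, None]
                          * transient_kernel(times[None, :] - ev[:, None],
                                             p.tau_rise_s, p.tau_decay_s)).sum(axis=0)
        noise = rng.normal(0.0, p.noise_sd * F0[i], size=times.size)
        F[i] = F0[i] * (1.0 + signal) * np.exp(-p.bleach_rate * times) + noise
        event_times[cell_ids[i]] = ev
        n_events[i] = ev.size

    traces = TraceMatrix(cell_ids=cell_ids, times_s=times, F=F,
                         stim_time_s=config.stim_time_s)
    cells = _make_cells(config, rng, condition=p.name, genotype=genotype)
    truth = pd.DataFrame({"cell_id": cell_ids,
                          "is_responder": is_resp,
                          "n_events": n_events})
    return SimulatedDataset(traces=traces, cells=cells, truth=truth,
                            event_times=event_times)


def simulate_release_traces(config: SimConfig, release_fraction: float,
                            drop_magnitude: float, tau_release_s: float = 120.0,
                            genotype: str = "control") -> SimulatedDataset:
    """Simulate vesicular-release recordings: monotone post-stimulus decline.

    Releasing cells fall smoothly toward F0 * (1 - drop_magnitude) with time
    constant ``tau_release_s``; non-releasing cells fluctuate around baseline.
    Under the release transform (F0 - Ft)/F0 the asymptote is drop_magnitude.
    """
    config.validate()
    if not 0.0 <= release_fraction <= 1.0:
        raise PresetError(f"release_fraction={release_fraction} not in [0, 1]")
    if not 0.0 <= drop_magnitude < 1.0:
        raise PresetError(f"drop_magnitude={drop_magnitude} not in [0, 1)")
    p = config.preset
    rng = np.random.default_rng(config.seed)
    times = _frame_times(config)
    n = config.n_cells

    F0 = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    releasing = rng.random(n) < release_fraction
    dt_post = np.maximum(times - config.stim_time_s, 0.0)
    decline = drop_magnitude * (1.0 - np.exp(-dt_post / tau_release_s))

    F = np.empty((n, times.size))
    cell_ids = [f"c{i:04d}" for i in range(n)]
    for i in range(n):
        shape = 1.0 - (decline if releasing[i] else 0.0)
        noise = rng.normal(0.0, p.noise_sd * F0[i], size=times.size)
        F[i] = F0[i] * shape + noise

    traces = TraceMatrix(cell_ids=cell_ids, times_s=times, F=F,
                         stim_time_s=config.stim_time_s)
    cells = _make_cells(config, rng, condition=p.name, genotype=genotype)
    truth = pd.DataFrame({"cell_id": cell_ids,
                          "is_responder": releasing,
                          "n_events": releasing.astype(int)})
    return SimulatedDataset(traces=traces, cells=cells, truth=truth)


DE_METHODS = ("cuffdiff2", "deseq", "edger")


def simulate_de_tables(n_genes: int, n_down: int, n_up: int,
                       fc_down: float, fc_up: float, seed: int,
                       sig_jitter: float = 0.0,
                       miss: Mapping[str, Sequence[str]] | None = None,
                       ) -> dict[str, pd.DataFrame]:
    """Three per-method differential-expression tables with planted genes.

    Genes g0000..g{n_down-1} are planted down at fc_down, the next n_up up
    at fc_up; remaining genes are nulls (fold change near 1, non-significant).
    ``sig_jitter`` is the per-method probability that a planted gene is
    missed (significance pushed above any sensible cutoff); ``miss`` names
    specific (method -> genes) misses deterministically.
    """
    if n_down < 0 or n_up < 0 or n_down + n_up > n_genes:
        raise PresetError(
            f"n_down={n_down} + n_up={n_up} must be <= n_genes={n_genes}")
    if not fc_down < 1.0 < fc_up:
        raise PresetError(f"need fc_down < 1 < fc_up, got {fc_down}, {fc_up}")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    planted_fc = np.ones(n_genes)
    planted_fc[:n_down] = fc_down
    planted_fc[n_down:n_down + n_up] = fc_up
    is_planted = np.zeros(n_genes, dtype=bool)
    is_planted[:n_down + n_up] = True

    expr_a = rng.lognormal(math.log(100.0), 0.5, size=n_genes)
    tables: dict[str, pd.DataFrame] = {}
    for method in DE_METHODS:
        fc = planted_fc.copy()
        null_idx = ~is_planted
        fc[null_idx] = rng.uniform(0.85, 1.15, size=int(null_idx.sum()))
        sig = np.where(is_planted,
                       rng.uniform(1e-6, 0.01, size=n_genes),
                       rng.uniform(0.2, 0.95, size=n_genes))
        if sig_jitter > 0:
            missed = is_planted & (rng.random(n_genes) < sig_jitter)
            sig[missed] = 0.5
        if miss and method in miss:
            for g in miss[method]:
                sig[genes.index(g)] = 0.5
        tables[method] = pd.DataFrame({
            "method": method,
            "gene": genes,
            "expr_a": expr_a,
            "expr_b": expr_a * fc,
            "fold_change": fc,
            "significance": sig,
        })
    return tables


def simulate_ct_table(genes: Sequence[str], true_fold_changes: Mapping[str, float],
                      housekeeping: Sequence[str], ct_noise_sd: float, seed: int,
                      n_bio_replicates: int = 1, n_technical: int = 2,
                      base_ct: float = 25.0, housekeeping_ct: float = 18.0,
                      ) -> pd.DataFrame:
    """qPCR Ct table with planted fold changes and technical duplicates.

    The experimental-sample Ct of a target gene is shifted by -log2(fold)
    relative to control while housekeeping genes stay put, so the expected
    2^-ΔΔCt recovers the planted fold exactly at zero noise. Samples are
    named control/expt (suffixed _r<i> when n_bio_replicates > 1).
    """
    for g, fc in true_fold_changes.items():
        if fc <= 0:
            raise PresetError(f"fold change for {g} must be > 0, got {fc}")
    for hk in housekeeping:
        if not math.isclose(true_fold_changes.get(hk, 1.0), 1.0):
            raise PresetError(f"housekeeping gene {hk} must have fold change 1")
    if ct_noise_sd < 0:
        raise PresetError("ct_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    all_genes = list(genes) + [g for g in housekeeping if g not in genes]
    base = {g: (housekeeping_ct if g in housekeeping else base_ct + 0.5 * i)
            for i, g in enumerate(all_genes)}
    rows = []
    for r in range(n_bio_replicates):
        suffix = "" if n_bio_replicates == 1 else f"_r{r + 1}"
        for sample_kind in ("control", "expt"):
            for g in all_genes:
                fold = true_fold_changes.get(g, 1.0)
                shift = -math.log2(fold) if (sample_kind == "expt"
                                             and g not in housekeeping) else 0.0
                for tech in range(1, n_technical + 1):
                    ct = base[g] + shift + rng.normal(0.0, ct_noise_sd)
                    rows.append((f"{sample_kind}{suffix}", g, tech, ct))
    table = pd.DataFrame(rows, columns=["sample", "gene", "replicate", "Ct"])
    if (table["Ct"] <= 0).any():
        raise PresetError("simulated Ct values must be positive; lower ct_noise_sd")
    return table


def load_sim_config(path) -> SimConfig:
    """Read a SimConfig from a YAML file; preset by name or inline mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    preset = raw.pop("preset")
    if isinstance(preset, str):
        preset_obj = PRESETS[preset]
    else:
        preset_obj = ConditionPreset(**preset)
    return SimConfig(preset=preset_obj, **raw).validate()
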