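"""Synthetic single-cell ERK datasets with known ground truth.

Emulates the statistical structure of a live-cell ERK biosensor experiment
followed by endpoint multiplexed immunofluorescence: 19 h of activity per
cell at 6-minute sampling, EGF dose-dependent sustained and pulsatile
responses, MEK-inhibitor interruptions, delayed stimulation, spatially
clustered late activity bursts in small groups of neighboring cells, and an
endpoint stain panel produced by the delay-ODE gene-expression model with
multiplicative measurement noise and replicate-specific batch factors.

The trace model is: Ornstein-Uhlenbeck baseline jitter + a dose-scaled
initial transient relaxing to a sustained plateau + a Poisson pulse train
with per-cell lognormal amplitude and duration draws.  MEK inhibition is an
exponential relaxation to an inhibited floor.  Cell-to-cell heterogeneity
enters through per-cell lognormal response multipliers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simetg import SimEtgParams, run_survey

HORIZON_SAMPLES = 190
SAMPLE_DT_MIN = 6.0

CLASS_NAMES = {
    1: "moderate-then-off",
    2: "low",
    3: "recent-on",
    4: "mid-term",
    5: "long-high",
}


@dataclass(frozen=True)
class TreatmentSpec:
    """One treatment: EGF dose/time and optional MEK-inhibitor addition time."""

    egf_dose: float              # ng/ml
    egf_time_min: float = 0.0
    meki_time_min: float | None = None
    label: str = ""

    def __post_init__(self):
        if self.egf_dose < 0:
            raise ValueError("egf_dose must be >= 0")
        if self.egf_time_min < 0:
            raise ValueError("egf_time_min must be >= 0")
        if self.meki_time_min is not None and self.meki_time_min < 0:
            raise ValueError("meki_time_min must be >= 0")
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        s = f"EGF{self.egf_dose:g}@{self.egf_time_min:g}"
        if self.meki_time_min is not None:
            s += f"_MEKi@{self.meki_time_min:g}"
        return s


@dataclass(frozen=True)
class WellSpec:
    well_id: str
    treatment: TreatmentSpec
    replicate_id: int
    n_cells: int

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass
class PlateLayout:
    wells: list[WellSpec]
    field_size_um: tuple[float, float] = (702.0, 785.0)

    def __post_init__(self):
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValueError("well_ids must be unique")
        if min(self.field_size_um) <= 0:
            raise ValueError("field dimensions must be > 0")


@dataclass
class TraceParams:
    """Trace-shape settings; archetype parameters are free defaults."""

    baseline: float = 0.10            # resting activity level
    baseline_sd: float = 0.02         # OU stationary standard deviation
    baseline_tau_min: float = 30.0    # OU correlation time
    dose_k: float = 2.0               # EGF half-max dose, ng/ml
    transient_amp: float = 1.0        # initial transient peak scale
    transient_rise_min: float = 6.0
    transient_decay_min: float = 60.0
    sustained_max: float = 0.45       # dose-saturated plateau above baseline
    pulse_rate_per_h: float = 1.5     # dose-saturated Poisson pulse rate
    pulse_amp: float = 0.35
    pulse_fwhm_min: float = 30.0
    media_amp: float = 0.15           # acute transient at media/treatment addition
    media_tau_min: float = 90.0       # decay of the media-addition transient
    meki_tau_min: float = 6.0         # exponential relaxation after MEKi
    meki_floor_frac: float = 0.3      # inhibited floor as fraction of baseline
    het_sigma: float = 0.3            # per-cell lognormal heterogeneity (log-sd)
    burst_amp: float = 0.5            # synchronized late-burst amplitude
    burst_window_min: float = 120.0   # bursts land in the final window


def archetype_of(treatment: TreatmentSpec, horizon_min: float = 1134.0) -> int:
    """Ground-truth signaling-history class of a treatment.

    Five regimes: 1 moderate-then-off, 2 low, 3 recent-on, 4 mid-term,
    5 long-high.
    """
    t = treatment
    if t.egf_dose < 1.0:
        return 2
    if t.meki_time_min is not None and t.meki_time_min - t.egf_time_min <= 60.0:
        return 2
    if t.egf_time_min >= horizon_min - 300.0:
        return 3
    if t.egf_time_min > 240.0:
        return 4
    if t.meki_time_min is not None and t.meki_time_min < horizon_min - 120.0:
        return 1
    return 5


def generate_erk_trace(
    treatment: TreatmentSpec,
    params: TraceParams,
    rng: np.random.Generator,
    n_samples: int = HORIZON_SAMPLES,
    dt_min: float = SAMPLE_DT_MIN,
) -> np.ndarray:
    """One cell's ERK activity trace under a treatment.

    Activity is non-negative; before EGF addition it fluctuates around the
    baseline; after MEK inhibition it relaxes exponentially to the inhibited
    floor; pulse rate and the sustained component saturate with dose.
    """
    if dt_min <= 0:
        raise ValueError("sampling interval must be > 0")
    t = np.arange(n_samples) * dt_min
    horizon = t[-1]
    p = params

    # Ornstein-Uhlenbeck baseline jitter (exact AR(1) discretization)
    a = np.exp(-dt_min / p.baseline_tau_min)
    innov = rng.normal(0.0, p.baseline_sd * np.sqrt(1 - a * a), n_samples)
    ou = np.empty(n_samples)
    ou[0] = p.baseline + rng.normal(0.0, p.baseline_sd)
    for i in range(1, n_samples):
        ou[i] = p.baseline + a * (ou[i - 1] - p.baseline) + innov[i]

    hill = treatment.egf_dose / (treatment.egf_dose + p.dose_k) if treatment.egf_dose > 0 else 0.0
    het = rng.lognormal(0.0, p.het_sigma, 5)  # transient, sustained, pulse amp/dur, media

    stim = np.zeros(n_samples)
    te = treatment.egf_time_min
    if te <= horizon:
        # acute ERK transient at media/treatment addition, present in every
        # well (including dose-0 controls); gives the "low" history class its
        # shared shape
        rel = np.clip(t - te, 0.0, None)
        stim += (t >= te) * het[4] * p.media_amp * np.exp(-rel / p.media_tau_min) * (
            1.0 - np.exp(-rel / p.transient_rise_min))
    if hill > 0 and te <= horizon:
        rel = np.clip(t - te, 0.0, None)
        on = t >= te
        rise = 1.0 - np.exp(-rel / p.transient_rise_min)
        stim += on * hill * (
            het[0] * p.transient_amp * rise * np.exp(-rel / p.transient_decay_min)
            + het[1] * p.sustained_max * rise
        )
        # Poisson pulse train after stimulation
        pulse_stop = treatment.meki_time_min if treatment.meki_time_min is not None else horizon
        span_h = max(pulse_stop - te, 0.0) / 60.0
        n_pulses = rng.poisson(p.pulse_rate_per_h * hill * span_h)
        if n_pulses:
            centers = rng.uniform(te, te + span_h * 60.0, n_pulses)
            amps = het[2] * p.pulse_amp * rng.lognormal(0.0, 0.35, n_pulses)
            sigmas = het[3] * (p.pulse_fwhm_min / 2.355) * rng.lognormal(0.0, 0.25, n_pulses)
            for c, amp, s in zip(centers, amps, sigmas):
                stim += amp * np.exp(-0.5 * ((t - c) / s) ** 2)

    activity = ou + stim
    ti = treatment.meki_time_min
    if ti is not None and ti <= horizon:
        floor = p.baseline * p.meki_floor_frac
        at_ti = float(np.interp(ti, t, activity))
        post = t >= ti
        decay = floor + (max(at_ti, floor) - floor) * np.exp(-(t - ti) / p.meki_tau_min)
        jitter = rng.normal(0.0, 0.3 * p.baseline_sd, n_samples)
        activity = np.where(post, decay + jitter, activity)

    return np.clip(activity, 0.0, None)


def assign_coordinates(
    n_cells: int,
    field_size_um: tuple[float, float],
    rng: np.random.Generator,
    clustered_fraction: float = 0.25,
    cluster_size_range: tuple[int, int] = (5, 30),
    cluster_sigma_um: float = 25.0,
) -> pd.DataFrame:
    """Uniform cell coordinates with a fraction grouped into spatial clusters.

    Cluster sizes are uniform within ``cluster_size_range``; members are
    Gaussian around a cluster center and clipped to the field.  Returns a
    table with columns x_um, y_um, burst_cluster (-1 for unclustered).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    w, h = field_size_um
    if w <= 0 or h <= 0:
        raise ValueError("field dimensions must be > 0")
    lo, hi = cluster_size_range
    x = rng.uniform(0, w, n_cells)
    y = rng.uniform(0, h, n_cells)
    cluster = np.full(n_cells, -1, dtype=int)

    target = int(round(clustered_fraction * n_cells))
    placed, cid = 0, 0
    while target - placed >= lo:
        size = min(int(rng.integers(lo, hi + 1)), target - placed)
        if size < lo:
            break
        cx, cy = rng.uniform(0.1 * w, 0.9 * w), rng.uniform(0.1 * h, 0.9 * h)
        sl = slice(placed, placed + size)
        x[sl] = np.clip(cx + rng.normal(0, cluster_sigma_um, size), 0, w)
        y[sl] = np.clip(cy + rng.normal(0, cluster_sigma_um, size), 0, h)
        cluster[sl] = cid
        placed += size
        cid += 1

    df = pd.DataFrame({"x_um": x, "y_um": y, "burst_cluster": cluster})
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)


def inject_bursts(
    traces: np.ndarray,
    t_min: np.ndarray,
    cluster_ids: np.ndarray,
    eligible: np.ndarray,
    params: TraceParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add a synchronized late-window activity burst per spatial cluster.

    All eligible members of one cluster share the burst center and duration;
    amplitudes vary lognormally per cell.  Cells under MEK inhibition are
    not eligible.
    """
    traces = traces.copy()
    t_end = t_min[-1]
    for cid in np.unique(cluster_ids[cluster_ids >= 0]):
        members = np.flatnonzero((cluster_ids == cid) & eligible)
        if members.size == 0:
            continue
        center = rng.uniform(t_end - params.burst_window_min, t_end - 20.0)
        sigma = (params.pulse_fwhm_min / 2.355) * rng.lognormal(0.0, 0.2)
        shape = np.exp(-0.5 * ((t_min - center) / sigma) ** 2)
        amps = params.burst_amp * rng.lognormal(0.0, 0.25, members.size)
        traces[members] += amps[:, None] * shape[None, :]
    return traces


# Default stain panel: named targets spanning fast trackers to slow
# integrators, all generated through the delay-ODE model.  Parameter choices
# encode the qualitative kinetics of each target (e.g. a long-lived
# integrator for Fra-1, a fast immediate-early responder for Egr-1, a
# rapidly reversible phospho-epitope for pERK).
DEFAULT_STAIN_PANEL: dict[str, SimEtgParams] = {
    "Fra-1": SimEtgParams(k_dm=5e-3, k_dp_prot=3e-4, k_dpp=3e-4, k_deph=5e-3,
                          k_d=500.0).with_baseline_fraction(0.10),
    "Egr-1": SimEtgParams(k_dm=5e-2, k_dp_prot=5e-3, k_dpp=5e-3, k_deph=2e-2,
                          k_d=200.0).with_baseline_fraction(0.05),
    "c-Fos": SimEtgParams(k_dm=3e-2, k_dp_prot=3e-3, k_dpp=3e-3, k_deph=2e-2,
                          k_d=300.0).with_baseline_fraction(0.08),
    "pc-Fos": SimEtgParams(k_dm=3e-2, k_dp_prot=3e-3, k_dpp=8e-3, k_deph=5e-3,
                           k_d=300.0, k_pp=0.05).with_baseline_fraction(0.08),
    "c-Myc": SimEtgParams(k_dm=2e-2, k_dp_prot=2e-3, k_dpp=2e-3, k_deph=1e-2,
                          k_d=400.0).with_baseline_fraction(0.20),
    "c-Jun": SimEtgParams(k_dm=1e-2, k_dp_prot=1e-3, k_dpp=1e-3, k_deph=1e-2,
                          k_d=400.0).with_baseline_fraction(0.15),
    "pERK": SimEtgParams(k_dm=1e-1, k_dp_prot=1e-2, k_dpp=1e-2, k_deph=1e-1,
                         k_d=1000.0, k_pp=0.1).with_baseline_fraction(0.02),
    "pRb": SimEtgParams(k_dm=8e-3, k_dp_prot=8e-4, k_dpp=8e-4, k_deph=8e-3,
                        k_d=800.0).with_baseline_fraction(0.40),
}


def generate_etg_panel(
    traces: np.ndarray,
    t_min: np.ndarray,
    genes: Mapping[str, SimEtgParams],
    noise_cv: float,
    batch_factors: pd.DataFrame,
    replicates: np.ndarray,
    rng: np.random.Generator,
    ode_dt: float = 1.0,
) -> pd.DataFrame:
    """Endpoint stain panel: ODE endpoint x lognormal noise x batch factor.

    ``batch_factors`` is indexed by replicate with one column per target;
    the lognormal noise has unit mean and coefficient of variation
    ``noise_cv``.
    """
    if not genes:
        raise ValueError("gene panel must not be empty")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if (batch_factors.to_numpy() <= 0).any():
        raise ValueError("batch factors must be > 0")
    names = list(genes)
    endpoints = run_survey(list(genes.values()), traces, t_min, dt=ode_dt)  # (G, C)
    panel = pd.DataFrame(endpoints.T, columns=names)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        noise = rng.lognormal(-sigma**2 / 2.0, sigma, panel.shape)
        panel *= noise
    factors = batch_factors.loc[replicates, names].to_numpy()
    panel *= factors
    return panel


@dataclass
class Dataset:
    """A coherent synthetic plate: traces, coordinates, stains, ground truth."""

    t_min: np.ndarray
    traces: np.ndarray          # (n_cells, n_timepoints)
    cells: pd.DataFrame         # cell_id, well, condition, replicate, x_um, y_um
    stains: pd.DataFrame        # cell_id-indexed, one column per target
    truth: dict                 # class ids, burst clusters, batch factors, panel params

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    def to_dir(self, outdir: str | Path) -> None:
        """Write traces.csv (long), stains.csv, cells.csv, truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        n, T = self.traces.shape
        long = pd.DataFrame({
            "cell_id": np.repeat(self.cells["cell_id"].to_numpy(), T),
            "t_min": np.tile(self.t_min, n),
            "activity": self.traces.ravel(),
        })
        long.to_csv(outdir / "traces.csv", index=False)
        self.stains.to_csv(outdir / "stains.csv")
        self.cells.to_csv(outdir / "cells.csv", index=False)
        truth = dict(self.truth)
        truth["true_class"] = {str(k): int(v) for k, v in truth["true_class"].items()}
        truth["burst_cluster"] = {str(k): int(v) for k, v in truth["burst_cluster"].items()}
        truth["batch_factors"] = json.loads(truth["batch_factors"].to_json())
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1, default=str))


@dataclass
class SimConfig:
    """Study-condition settings for dataset generation."""

    n_samples: int = HORIZON_SAMPLES
    dt_min: float = SAMPLE_DT_MIN
    noise_cv: float = 0.10
    clustered_fraction: float = 0.25
    batch_log10_sd: float = 0.15     # spread of replicate batch factors (log10)
    ode_dt: float = 1.0
    trace_params: TraceParams = field(default_factory=TraceParams)
    stain_panel: Mapping[str, SimEtgParams] = field(
        default_factory=lambda: dict(DEFAULT_STAIN_PANEL))


def default_layout(
    n_cells_per_well: int = 100,
    replicates: int = 3,
    horizon_min: float = (HORIZON_SAMPLES - 1) * SAMPLE_DT_MIN,
) -> PlateLayout:
    """A treatment design covering the five signaling-history archetypes.

    EGF dose series at t=0, MEK-inhibitor interruptions at varying times, and
    delayed EGF additions, replicated ``replicates`` times.
    """
    if replicates < 1:
        raise ValueError("replicate count must be >= 1")
    treatments = [
        TreatmentSpec(0.0),
        TreatmentSpec(0.5),
        TreatmentSpec(20.0),
        TreatmentSpec(100.0),
        TreatmentSpec(20.0, meki_time_min=570.0),
        TreatmentSpec(100.0, meki_time_min=570.0),
        TreatmentSpec(20.0, meki_time_min=30.0),
        TreatmentSpec(20.0, egf_time_min=420.0, meki_time_min=900.0),
        TreatmentSpec(20.0, egf_time_min=960.0),
        TreatmentSpec(100.0, egf_time_min=960.0),
    ]
    wells = []
    rows = "ABCDEFGH"
    for r in range(1, replicates + 1):
        for i, tr in enumerate(treatments):
            wells.append(WellSpec(
                well_id=f"{rows[(r - 1) % 8]}{i + 1:02d}",
                treatment=tr, replicate_id=r, n_cells=n_cells_per_well))
    return PlateLayout(wells=wells)


def generate_dataset(layout: PlateLayout, config: SimConfig, seed: int) -> Dataset:
    """Generate a full synthetic dataset bundle from a plate layout.

    Every cell appears exactly once in the trace matrix, the coordinate and
    condition table, the stain panel, and the ground-truth record; identical
    seed and config reproduce the dataset bit-for-bit.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(config.n_samples) * config.dt_min
    horizon = t[-1]

    trace_rows, cell_rows, cluster_ids, eligible = [], [], [], []
    offset = 0
    for well in layout.wells:
        coords = assign_coordinates(
            well.n_cells, layout.field_size_um, rng,
            clustered_fraction=config.clustered_fraction)
        for i in range(well.n_cells):
            trace_rows.append(generate_erk_trace(
                well.treatment, config.trace_params, rng,
                n_samples=config.n_samples, dt_min=config.dt_min))
        cls = archetype_of(well.treatment, horizon)
        local = coords["burst_cluster"].to_numpy()
        cluster_ids.append(np.where(local >= 0, local + offset, -1))
        offset += int(local.max()) + 1 if (local >= 0).any() else 0
        eligible.append(np.full(well.n_cells, well.treatment.meki_time_min is None))
        for i in range(well.n_cells):
            cell_rows.append({
                "well": well.well_id,
                "condition": well.treatment.label,
                "replicate": well.replicate_id,
                "x_um": coords.at[i, "x_um"],
                "y_um": coords.at[i, "y_um"],
                "true_class": cls,
            })

    traces = np.vstack(trace_rows)
    cells = pd.DataFrame(cell_rows)
    cells.insert(0, "cell_id", np.arange(len(cells)))
    cluster_ids = np.concatenate(cluster_ids)
    eligible = np.concatenate(eligible)
    traces = inject_bursts(traces, t, cluster_ids, eligible, config.trace_params, rng)

    # replicate-specific batch scale factors (reference replicate = 1.0)
    targets = list(config.stain_panel)
    reps = sorted(cells["replicate"].unique())
    factors = pd.DataFrame(1.0, index=reps, columns=targets)
    for r in reps[1:]:
        factors.loc[r] = 10.0 ** rng.normal(0.0, config.batch_log10_sd, len(targets))

    stains = generate_etg_panel(
        traces, t, config.stain_panel, config.noise_cv, factors,
        cells["replicate"].to_numpy(), rng, ode_dt=config.ode_dt)
    stains.index = pd.Index(cells["cell_id"], name="cell_id")

    truth = {
        "true_class": dict(zip(cells["cell_id"], cells["true_class"])),
        "burst_cluster": dict(zip(cells["cell_id"], cluster_ids)),
        "batch_factors": factors,
        "class_names": CLASS_NAMES,
        "seed": seed,
    }
    cells = cells.drop(columns="true_class")
    return Dataset(t_min=t, traces=traces, cells=cells, stains=stains, truth=truth)
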