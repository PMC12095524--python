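"""Delay-ODE model of ERK-driven target-gene expression.

A hypothetical ERK target gene (sim-ETG) is modeled in four steps driven by
an ERK activity input E(t):

    dTFP/dt  = k_ptf * E(t) * (TF_T - TFP) - k_dtf * TFP
    dmRNA/dt = (k_b + k_m * TFP(t - tau_m)) / ((Q(t - tau_m)/K_D)^v + 1)
               - k_dm * mRNA
    dP/dt    = k_p * mRNA(t - tau_p) + k_deph * PP
               - k_dp_prot * P - k_pp * E(t) * P
    dPP/dt   = k_pp * E(t) * P - (k_dpp + k_deph) * PP

where TFP is phosphorylated transcription factor, Q = P + PP is total
protein, and the Hill term implements negative feedback of the protein onto
its own transcription.  The phosphorylation flux k_pp*E*P leaves the
unphosphorylated pool and enters the phosphorylated pool, so protein mass is
conserved when degradation is off.  Transcription and translation delays are
handled by linear interpolation into the stored solution history; the
pre-stimulus history is the steady state under the initial ERK level.

Integration is classical fixed-step RK4 (default 1-minute step), vectorized
over a batch axis (cells, or genes with per-gene parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "SimEtgParams",
    "SimEtgTrajectory",
    "simulate_gene",
    "simulate_gene_batch",
    "steady_state",
    "sample_params",
    "run_survey",
    "regulation_sign",
    "screen_predictivity",
    "survey_timepoint_profile",
    "DEFAULT_VARIED_RANGES",
    "DEFAULT_FIXED",
]


@dataclass(frozen=True)
class SimEtgParams:
    """Rate constants of one sim-ETG.  Units: per-minute rates, minutes for delays.

    ``k_b``/``k_m`` (basal and TF-driven transcription) are usually set
    through :meth:`with_baseline_fraction`, which fixes ``k_b + k_m`` and
    samples the fractional expression at baseline ``k_b/(k_b+k_m)``.
    """

    k_ptf: float = 0.05     # TF phosphorylation rate per ERK activity unit
    k_dtf: float = 0.05     # TF dephosphorylation rate
    tf_total: float = 1.0   # total transcription factor
    k_b: float = 0.5        # basal transcription rate
    k_m: float = 0.5        # TF-driven transcription rate
    tau_m: float = 10.0     # transcription delay (min)
    k_dm: float = 0.01      # mRNA degradation rate
    k_d: float = 100.0      # feedback half-max concentration (K_D)
    v: float = 2.0          # feedback Hill exponent
    k_p: float = 0.05       # translation rate
    tau_p: float = 10.0     # translation delay (min)
    k_dp_prot: float = 1e-3  # unphosphorylated protein degradation
    k_pp: float = 0.02      # protein phosphorylation rate per ERK unit
    k_deph: float = 0.01    # protein dephosphorylation
    k_dpp: float = 1e-3     # phosphoprotein degradation

    def __post_init__(self):
        for f in dc_fields(self):
            val = getattr(self, f.name)
            if val < 0:
                raise ValueError(f"{f.name} must be >= 0, got {val}")
        if self.tf_total <= 0:
            raise ValueError("tf_total must be > 0")
        if self.v < 1:
            raise ValueError("Hill exponent v must be >= 1")

    @property
    def baseline_fraction(self) -> float:
        tot = self.k_b + self.k_m
        return self.k_b / tot if tot > 0 else 0.0

    def with_baseline_fraction(self, frac: float, total: float = 1.0) -> "SimEtgParams":
        if not 0.0 <= frac <= 1.0:
            raise ValueError("baseline fraction must lie in [0, 1]")
        return replace(self, k_b=frac * total, k_m=(1.0 - frac) * total)


@dataclass
class SimEtgTrajectory:
    """Simulated species of one sim-ETG for one cell."""

    t: np.ndarray
    tfp: np.ndarray
    mrna: np.ndarray
    p: np.ndarray
    pp: np.ndarray

    @property
    def readout(self) -> float:
        """Endpoint total protein P + P^P (total-protein antibody analog)."""
        return float(self.p[-1] + self.pp[-1])

    @property
    def readout_phospho(self) -> float:
        """Endpoint phospho-protein only (phospho-antibody analog)."""
        return float(self.pp[-1])


def _as_batch(params) -> dict:
    """Parameter dict of arrays broadcastable over the batch axis."""
    if isinstance(params, SimEtgParams):
        params = [params]
    keys = [f.name for f in dc_fields(SimEtgParams)]
    return {k: np.array([getattr(p, k) for p in params], dtype=float) for k in keys}


class _ErkInterp:
    """Linear interpolation of per-batch ERK traces; flat beyond the ends."""

    def __init__(self, erk: np.ndarray, t_min: np.ndarray):
        self.y = np.atleast_2d(np.asarray(erk, dtype=float))
        self.t = np.asarray(t_min, dtype=float)
        self.dt = self.t[1] - self.t[0] if self.t.size > 1 else 1.0

    def __call__(self, s: float) -> np.ndarray:
        if s <= self.t[0]:
            return self.y[:, 0]
        if s >= self.t[-1]:
            return self.y[:, -1]
        f = (s - self.t[0]) / self.dt
        i = int(f)
        w = f - i
        return (1.0 - w) * self.y[:, i] + w * self.y[:, i + 1]


def _integrate(
    P: dict,
    erk: _ErkInterp,
    horizon: float,
    dt: float,
    y0: tuple | None,
    n_batch: int,
    keep_path: bool,
):
    """Vectorized RK4 with interpolated delayed states.

    History of (TFP, Q, mRNA) is stored on the dt grid; delayed lookups at
    times <= 0 return the pre-history (initial state), and lookups beyond
    the filled history (possible only when a delay is shorter than the step)
    clamp to the latest computed value.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n_steps = int(round(horizon / dt))
    t_grid = np.arange(n_steps + 1) * dt

    if y0 is None:
        y0 = steady_state_batch(P, erk(0.0))
    tfp, m, p, pp = (np.broadcast_to(np.asarray(v, float), (n_batch,)).copy() for v in y0)

    # delayed-state history on the grid
    H_tfp = np.empty((n_steps + 1, n_batch))
    H_q = np.empty((n_steps + 1, n_batch))
    H_m = np.empty((n_steps + 1, n_batch))
    H_tfp[0], H_q[0], H_m[0] = tfp, p + pp, m
    filled = 0

    def look(H, s):
        if s <= 0:
            return H[0]
        f = s / dt
        i = int(f)
        if i >= filled:
            return H[filled]
        w = f - i
        return (1.0 - w) * H[i] + w * H[i + 1]

    if keep_path:
        path = np.empty((n_steps + 1, 4, n_batch))
        path[0] = [tfp, m, p, pp]

    k_ptf, k_dtf, tf_t = P["k_ptf"], P["k_dtf"], P["tf_total"]
    k_b, k_m_, k_dm = P["k_b"], P["k_m"], P["k_dm"]
    k_d, v_, k_p = P["k_d"], P["v"], P["k_p"]
    k_dp, k_pp_, k_deph, k_dpp = P["k_dp_prot"], P["k_pp"], P["k_deph"], P["k_dpp"]
    tau_m = float(np.asarray(P["tau_m"]).ravel()[0])
    tau_p = float(np.asarray(P["tau_p"]).ravel()[0])

    def deriv(s, tfp, m, p, pp, tfp_d, q_d, m_d):
        E = erk(s)
        fb = 1.0 / ((q_d / k_d) ** v_ + 1.0)
        flux = k_pp_ * E * p
        return (
            k_ptf * E * (tf_t - tfp) - k_dtf * tfp,
            (k_b + k_m_ * tfp_d) * fb - k_dm * m,
            k_p * m_d + k_deph * pp - k_dp * p - flux,
            flux - (k_dpp + k_deph) * pp,
        )

    for i in range(n_steps):
        t0 = i * dt
        # delayed quantities are functions of time only, shared by the stages
        dl = {}
        for s in (t0, t0 + dt / 2.0, t0 + dt):
            dl[s] = (look(H_tfp, s - tau_m), look(H_q, s - tau_m), look(H_m, s - tau_p))

        k1 = deriv(t0, tfp, m, p, pp, *dl[t0])
        k2 = deriv(t0 + dt / 2, tfp + dt / 2 * k1[0], m + dt / 2 * k1[1],
                   p + dt / 2 * k1[2], pp + dt / 2 * k1[3], *dl[t0 + dt / 2.0])
        k3 = deriv(t0 + dt / 2, tfp + dt / 2 * k2[0], m + dt / 2 * k2[1],
                   p + dt / 2 * k2[2], pp + dt / 2 * k2[3], *dl[t0 + dt / 2.0])
        k4 = deriv(t0 + dt, tfp + dt * k3[0], m + dt * k3[1],
                   p + dt * k3[2], pp + dt * k3[3], *dl[t0 + dt])

        tfp = tfp + dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        m = m + dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        p = p + dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        pp = pp + dt / 6 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        np.maximum(tfp, 0.0, out=tfp)
        np.maximum(m, 0.0, out=m)
        np.maximum(p, 0.0, out=p)
        np.maximum(pp, 0.0, out=pp)

        H_tfp[i + 1], H_q[i + 1], H_m[i + 1] = tfp, p + pp, m
        filled = i + 1
        if keep_path:
            path[i + 1] = [tfp, m, p, pp]

    if keep_path:
        return t_grid, path
    return t_grid, np.stack([tfp, m, p, pp])


def steady_state_batch(P: dict, erk_const) -> tuple:
    """Steady state of the model at constant ERK, vectorized over the batch.

    Without feedback the fixed point is closed-form; with feedback the total
    protein solves a scalar monotone fixed-point equation by bracketed root
    finding on [0, no-feedback total].
    """
    E = np.asarray(erk_const, dtype=float)
    k_ptf, k_dtf, tf_t = P["k_ptf"], P["k_dtf"], P["tf_total"]
    denom = k_ptf * E + k_dtf
    tfp = np.where(denom > 0, k_ptf * E * tf_t / np.where(denom > 0, denom, 1.0), 0.0)
    prod = P["k_b"] + P["k_m"] * tfp

    k_dm = P["k_dm"]
    if np.any((k_dm == 0) & (prod > 0)):
        raise ValueError("no steady state: k_dm = 0 with nonzero transcription")
    with np.errstate(divide="ignore", invalid="ignore"):
        m_nf = np.where(prod > 0, prod / np.where(k_dm > 0, k_dm, 1.0), 0.0)

    k_p, k_dp, k_pp, k_deph, k_dpp = (
        P["k_p"], P["k_dp_prot"], P["k_pp"], P["k_deph"], P["k_dpp"])
    b = k_pp * E
    c = k_dpp + k_deph
    if np.any((c == 0) & (b > 0) & (m_nf > 0)):
        raise ValueError("no steady state: phospho pool has influx but no outflux")
    c_safe = np.where(c > 0, c, 1.0)
    p_denom = k_dp + b * np.where(c > 0, k_dpp / c_safe, 0.0)
    if np.any((p_denom == 0) & (k_p * m_nf > 0)):
        raise ValueError("no steady state: protein has influx but no outflux")
    p_nf = np.where(k_p * m_nf > 0, k_p * m_nf / np.where(p_denom > 0, p_denom, 1.0), 0.0)
    pp_ratio = np.where(c > 0, b / c_safe, 0.0)

    # feedback: total protein Q solves Q*((Q/K_D)^v + 1) = Q_nofeedback
    q_nf = p_nf * (1.0 + pp_ratio)
    shape = np.broadcast_shapes(q_nf.shape, np.shape(P["k_d"]), np.shape(P["v"]))
    q_nf_b = np.broadcast_to(q_nf, shape).astype(float)
    pp_ratio = np.broadcast_to(pp_ratio, shape)
    m_nf = np.broadcast_to(m_nf, shape)
    p_nf = np.broadcast_to(p_nf, shape)
    tfp = np.broadcast_to(tfp, shape)
    kd_b = np.broadcast_to(P["k_d"], shape)
    v_b = np.broadcast_to(P["v"], shape)
    q = np.empty(shape, dtype=float)
    for ix in np.ndindex(shape):
        C, kd, vv = q_nf_b[ix], float(kd_b[ix]), float(v_b[ix])
        if C == 0 or not np.isfinite(kd):
            q[ix] = C  # no protein, or feedback effectively off
        elif kd == 0:
            q[ix] = 0.0  # infinitely strong feedback
        else:
            q[ix] = brentq(lambda Q: Q * ((Q / kd) ** vv + 1) - C, 0.0, C)

    scale = np.where(q_nf_b > 0, q / np.where(q_nf_b > 0, q_nf_b, 1.0), 1.0)
    m = m_nf * scale
    p = p_nf * scale
    pp = p * pp_ratio
    return tfp, m, p, pp


def steady_state(params: SimEtgParams, erk_const: float) -> tuple[float, float, float, float]:
    """Steady state (TFP, mRNA, P, PP) at constant ERK activity."""
    if erk_const < 0:
        raise ValueError("erk_const must be >= 0")
    P = _as_batch(params)
    tfp, m, p, pp = steady_state_batch(P, np.array([erk_const]))
    return float(tfp[0]), float(m[0]), float(p[0]), float(pp[0])


def simulate_gene(
    params: SimEtgParams,
    erk: np.ndarray,
    t_min: np.ndarray,
    dt: float = 1.0,
    y0: tuple | None = None,
) -> SimEtgTrajectory:
    """Simulate one sim-ETG driven by one cell's ERK trace.

    ``y0`` overrides the default initial condition (steady state under the
    pre-stimulus ERK level); useful for conservation checks.
    """
    erk = np.asarray(erk, dtype=float)
    t = np.asarray(t_min, dtype=float)
    P = _as_batch(params)
    interp = _ErkInterp(erk[None, :], t)
    t_grid, path = _integrate(P, interp, t[-1] - t[0], dt, y0, 1, keep_path=True)
    return SimEtgTrajectory(
        t=t_grid + t[0], tfp=path[:, 0, 0], mrna=path[:, 1, 0],
        p=path[:, 2, 0], pp=path[:, 3, 0])


def simulate_gene_batch(
    params_list: Sequence[SimEtgParams],
    erk: np.ndarray,
    t_min: np.ndarray,
    dt: float = 1.0,
    horizon: float | None = None,
    y0: tuple | None = None,
) -> np.ndarray:
    """Endpoint states for a batch of (gene_i, trace_i) pairs.

    ``erk`` has one row per gene; delays must be shared across the batch.
    Returns array (4, n_batch) of endpoint (TFP, mRNA, P, PP).
    """
    erk = np.atleast_2d(np.asarray(erk, dtype=float))
    t = np.asarray(t_min, dtype=float)
    P = _as_batch(params_list)
    if horizon is None:
        horizon = t[-1] - t[0]
    interp = _ErkInterp(erk, t)
    _, final = _integrate(P, interp, horizon, dt, y0, erk.shape[0], keep_path=False)
    return final


DEFAULT_VARIED_RANGES = {
    "k_dm": (1e-3, 1e-1),        # mRNA half-life ~7 min .. ~11.5 h
    "k_dp_prot": (1e-4, 1e-2),   # protein half-life ~1.2 h .. ~115 h
    "k_dpp": (1e-4, 1e-2),
    "k_deph": (1e-3, 1e-1),
    "k_d": (10.0, 1000.0),
}

DEFAULT_FIXED = dict(
    k_ptf=0.05, k_dtf=0.05, tf_total=1.0, tau_m=10.0, tau_p=10.0,
    k_p=0.05, k_pp=0.02, v=2.0,
)

TRANSCRIPTION_TOTAL = 1.0  # k_b + k_m, fixed so baseline_fraction is the sampled quantity


def sample_params(
    n: int,
    rng: np.random.Generator,
    ranges: dict | None = None,
    fixed: dict | None = None,
) -> list[SimEtgParams]:
    """Draw ``n`` sim-ETG parameterizations.

    The varied parameters (mRNA and protein degradation rates, protein
    dephosphorylation, feedback half-max) are log-uniform within ``ranges``;
    the fractional expression at baseline is uniform in [0, 1] with
    ``k_b + k_m`` held fixed.
    """
    ranges = {**DEFAULT_VARIED_RANGES, **(ranges or {})}
    fixed = {**DEFAULT_FIXED, **(fixed or {})}
    for k, (lo, hi) in ranges.items():
        if not (0 < lo < hi):
            raise ValueError(f"invalid bounds for {k}: ({lo}, {hi})")
    draws = {k: np.exp(rng.uniform(np.log(lo), np.log(hi), n))
             for k, (lo, hi) in ranges.items()}
    frac = rng.uniform(0.0, 1.0, n)
    out = []
    for i in range(n):
        p = SimEtgParams(**fixed, **{k: draws[k][i] for k in draws})
        out.append(p.with_baseline_fraction(frac[i], total=TRANSCRIPTION_TOTAL))
    return out


def run_survey(
    genes: Sequence[SimEtgParams],
    traces: np.ndarray,
    t_min: np.ndarray,
    dt: float = 1.0,
    readout: str = "total",
) -> np.ndarray:
    """Endpoint readout matrix (n_genes, n_cells).

    For each gene, all cells are integrated simultaneously.  ``readout`` is
    ``"total"`` (P + P^P) or ``"phospho"`` (P^P only).
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    t = np.asarray(t_min, dtype=float)
    out = np.empty((len(genes), traces.shape[0]))
    for gi, g in enumerate(genes):
        try:
            final = simulate_gene_batch([g] * traces.shape[0], traces, t, dt=dt)
        except Exception as exc:  # noqa: BLE001 - annotate failing gene
            raise RuntimeError(f"simulation failed for gene index {gi}") from exc
        out[gi] = final[2] + final[3] if readout == "total" else final[3]
    return out


def regulation_sign(
    params: SimEtgParams,
    horizon_min: float = 1134.0,
    erk_high: float = 1.0,
    dt: float = 1.0,
    rel_tol: float = 1e-9,
) -> tuple[str, bool]:
    """Classify a gene as positively or negatively ERK-regulated.

    Compares endpoint readouts under a sustained high-ERK step versus zero
    ERK over the standard horizon.  Ties within tolerance are labeled
    positive with a degeneracy flag.
    """
    t = np.array([0.0, horizon_min])
    hi = simulate_gene_batch([params], np.array([[erk_high, erk_high]]), t, dt=dt)
    lo = simulate_gene_batch([params], np.array([[0.0, 0.0]]), t, dt=dt)
    r_hi = float(hi[2][0] + hi[3][0])
    r_lo = float(lo[2][0] + lo[3][0])
    scale = max(abs(r_hi), abs(r_lo), 1e-300)
    if abs(r_hi - r_lo) <= rel_tol * scale:
        return "positive", True
    return ("positive", False) if r_hi > r_lo else ("negative", False)


def screen_predictivity(
    endpoint_matrix: np.ndarray,
    features: pd.DataFrame,
    thresholds: Sequence[float] = (0.5, 0.8),
) -> tuple[pd.DataFrame, dict]:
    """Single-variable R-squared of each dynamic feature on each gene's endpoint.

    Returns the (genes x features) R² table and, per threshold, the fraction
    of genes whose best feature R² exceeds it.  Zero-variance endpoints
    yield missing values.
    """
    E = np.atleast_2d(np.asarray(endpoint_matrix, dtype=float))
    F = features[_numeric_feature_cols(features)]
    if E.shape[1] < 10:
        raise ValueError("need >= 10 cells to screen predictivity")
    X = F.to_numpy(dtype=float)
    Ec = E - E.mean(axis=1, keepdims=True)
    Xc = X - X.mean(axis=0)
    se = np.sqrt((Ec ** 2).sum(axis=1))
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Ec @ Xc) / np.outer(se, sx)
    r[se == 0, :] = np.nan
    r[:, sx == 0] = np.nan
    r2 = pd.DataFrame(r ** 2, columns=F.columns)
    best = r2.max(axis=1)
    fractions = {thr: float((best > thr).mean()) for thr in thresholds}
    return r2, fractions


def _numeric_feature_cols(features: pd.DataFrame) -> list[str]:
    from .features import FEATURE_NAMES

    return [c for c in FEATURE_NAMES if c in features.columns] or [
        c for c in features.columns if np.issubdtype(features[c].dtype, np.number)]


def survey_timepoint_profile(endpoint_matrix: np.ndarray, traces: np.ndarray) -> pd.DataFrame:
    """Pearson r between each gene's endpoint and activity at each timepoint."""
    from .features import timepoint_correlation

    E = np.atleast_2d(np.asarray(endpoint_matrix, dtype=float))
    panel = pd.DataFrame(E.T, columns=[f"gene_{i}" for i in range(E.shape[0])])
    return timepoint_correlation(panel, traces)
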