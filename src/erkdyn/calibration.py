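"""FRET biosensor calibration and cross-replicate batch correction.

The EKAR-family biosensor reports the balance between ERK kinase activity and
competing phosphatases.  Raw donor/acceptor intensities are first reduced to
the *associated fraction* ``f_A`` (the fraction of reporter molecules in the
high-FRET conformation), then mapped through a two-point calibration —
anchored by Phos-tag measurements of the phosphorylated reporter fraction —
onto a dimensionless ERK activity ``x = ERK_active / phosphatase_active``:

    f_A = 1 - (I_CFP / I_YFP) / R_P
    f_A = K_AU + (K_AP - K_AU) * p          (calibration line, p = phospho fraction)
    x   = (f_A - K_AU) / (K_AP - f_A)

``K_AU`` and ``K_AP`` are the associated fractions of the fully
unphosphorylated and fully phosphorylated reporter; ``R_P`` is the imaging
power ratio between the two channels.

Endpoint immunofluorescence intensities from different experimental
replicates are aligned by an affine fit of log10 matched-condition medians
(replicate batch correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


class CalibrationError(ValueError):
    """Raised when a biosensor calibration is invalid or cannot be fit."""


@dataclass(frozen=True)
class CalibrationParams:
    """Two-point biosensor calibration.

    Parameters
    ----------
    k_au : associated fraction of the fully unphosphorylated reporter.
    k_ap : associated fraction of the fully phosphorylated reporter.
    r_p : imaging power ratio between donor and acceptor channels.
    """

    k_au: float
    k_ap: float
    r_p: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.k_au < self.k_ap <= 1.0):
            raise CalibrationError(
                f"require 0 <= k_au < k_ap <= 1, got k_au={self.k_au}, k_ap={self.k_ap}"
            )
        if self.r_p <= 0:
            raise CalibrationError(f"r_p must be > 0, got {self.r_p}")

    @property
    def span(self) -> float:
        return self.k_ap - self.k_au


@dataclass(frozen=True)
class PhosTagPoint:
    """One calibration anchor: phosphorylated reporter fraction vs mean f_A."""

    phospho_fraction: float
    mean_fa: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.phospho_fraction <= 1.0 and 0.0 <= self.mean_fa <= 1.0):
            raise CalibrationError("phospho_fraction and mean_fa must lie in [0, 1]")


@dataclass
class BatchScaling:
    """Affine log10 scaling aligning one replicate's stain to the reference."""

    target: str
    beta0: float
    beta1: float
    source_replicate: object
    reference_replicate: object


def compute_fa(i_cfp, i_yfp, r_p: float):
    """Associated fraction f_A = 1 - (I_CFP/I_YFP)/R_P.

    Values may fall slightly outside [0, 1] under measurement noise; they are
    propagated as-is (clamping is the caller's choice).
    """
    i_cfp = np.asarray(i_cfp, dtype=float)
    i_yfp = np.asarray(i_yfp, dtype=float)
    if r_p <= 0:
        raise CalibrationError(f"r_p must be > 0, got {r_p}")
    if np.any(i_yfp <= 0):
        raise CalibrationError("acceptor intensity i_yfp must be > 0 to form the ratio")
    out = 1.0 - (i_cfp / i_yfp) / r_p
    return out if out.ndim else float(out)


def fit_calibration(points: Sequence[PhosTagPoint], r_p: float = 1.0) -> CalibrationParams:
    """Fit the calibration line f_A = K_AU + (K_AP - K_AU)·p by OLS.

    Requires at least two points with distinct phospho fractions. The
    intercept is K_AU and intercept + slope is K_AP.
    """
    p = np.array([pt.phospho_fraction for pt in points], dtype=float)
    fa = np.array([pt.mean_fa for pt in points], dtype=float)
    if p.size < 2 or np.ptp(p) == 0.0:
        raise CalibrationError("need >= 2 calibration points with distinct phospho fractions")
    design = np.column_stack([np.ones_like(p), p])
    (k_au, slope), *_ = np.linalg.lstsq(design, fa, rcond=None)
    k_ap = k_au + slope
    if k_ap <= k_au:
        raise CalibrationError(
            f"invalid calibration: fitted K_AP ({k_ap:.4f}) <= K_AU ({k_au:.4f})"
        )
    return CalibrationParams(k_au=float(k_au), k_ap=float(k_ap), r_p=r_p)


# fraction of the calibration span used as the clamp margin below K_AP
CLAMP_EPS = 1e-6


def clamp_fa(fa, cal: CalibrationParams):
    """Clamp f_A into [K_AU, K_AP - eps·span]; returns (clamped, was_clamped)."""
    fa = np.asarray(fa, dtype=float)
    hi = cal.k_ap - CLAMP_EPS * cal.span
    clamped = np.clip(fa, cal.k_au, hi)
    return clamped, (clamped != fa)


def fa_to_activity(fa, cal: CalibrationParams, clamp: bool = True):
    """ERK activity x = (f_A - K_AU)/(K_AP - f_A).

    With ``clamp=True`` (default) out-of-range f_A values are clamped into
    the calibrated range first; with ``clamp=False`` they raise.
    """
    fa = np.asarray(fa, dtype=float)
    if clamp:
        fa, _ = clamp_fa(fa, cal)
    else:
        if np.any(fa >= cal.k_ap):
            raise CalibrationError("f_A >= K_AP implies unbounded activity")
        if np.any(fa < cal.k_au):
            raise CalibrationError("f_A < K_AU implies negative activity")
    out = (fa - cal.k_au) / (cal.k_ap - fa)
    return out if out.ndim else float(out)


def activity_to_fa(x, cal: CalibrationParams):
    """Inverse map: f_A = (K_AU + x·K_AP)/(1 + x), monotone onto [K_AU, K_AP)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise CalibrationError("activity must be >= 0")
    out = (cal.k_au + x * cal.k_ap) / (1.0 + x)
    return out if out.ndim else float(out)


class BatchCorrector(BaseEstimator, TransformerMixin):
    """Align stain intensities across replicates by log10 median scaling.

    For each target, matched-condition medians are computed per replicate in
    log10 space and the reference medians are regressed on each source
    replicate's medians (reference = beta1·source + beta0).  Every
    single-cell log10 value of the source replicate is then mapped through
    the fit and exponentiated back.  The reference replicate is unchanged.

    Parameters
    ----------
    reference_replicate : label of the replicate others are scaled onto.
    pool_groups : if True, medians are pooled over the ``group`` column
        (e.g. multiple cell lines plated in tandem) so each replicate gets a
        single scaling per target that preserves between-group differences.

    Fitted attributes
    -----------------
    scalings_ : list of BatchScaling, one per (target, source replicate).
    """

    def __init__(self, reference_replicate=None, pool_groups: bool = False):
        self.reference_replicate = reference_replicate
        self.pool_groups = pool_groups

    def fit(self, stains: pd.DataFrame, meta: pd.DataFrame):
        targets = [c for c in stains.columns]
        if (stains.to_numpy() <= 0).any():
            raise ValueError("batch correction requires strictly positive intensities")
        rep = np.asarray(meta["replicate"])
        cond = np.asarray(meta["condition"])
        reps = pd.unique(rep)
        ref = self.reference_replicate if self.reference_replicate is not None else reps[0]
        if ref not in set(reps):
            raise ValueError(f"reference replicate {ref!r} not present")

        log = np.log10(stains.to_numpy(dtype=float))
        med = pd.DataFrame(log, columns=targets).assign(_rep=rep, _cond=cond)
        if self.pool_groups and "group" in meta.columns:
            # pooled medians over groups: one scaling per (target, replicate)
            pass  # condition labels already shared across groups
        medians = med.groupby(["_rep", "_cond"], sort=True)[targets].median()

        self.scalings_ = []
        for src in reps:
            if src == ref:
                continue
            shared = medians.loc[src].index.intersection(medians.loc[ref].index)
            if len(shared) < 2:
                raise ValueError(
                    f"replicates {src!r} and {ref!r} share fewer than 2 matched conditions"
                )
            for tgt in targets:
                x = medians.loc[src].loc[shared, tgt].to_numpy()
                y = medians.loc[ref].loc[shared, tgt].to_numpy()
                beta1, beta0 = np.polyfit(x, y, 1)
                self.scalings_.append(
                    BatchScaling(target=tgt, beta0=float(beta0), beta1=float(beta1),
                                 source_replicate=src, reference_replicate=ref)
                )
        self.reference_ = ref
        self.targets_ = targets
        return self

    def transform(self, stains: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
        out = stains.copy().astype(float)
        rep = np.asarray(meta["replicate"])
        for s in self.scalings_:
            mask = rep == s.source_replicate
            if not mask.any():
                continue
            vals = np.log10(out.loc[mask, s.target].to_numpy())
            out.loc[mask, s.target] = 10.0 ** (s.beta1 * vals + s.beta0)
        return out

    def fit_transform(self, stains, meta, **kw):  # noqa: D102 - sklearn signature differs
        return self.fit(stains, meta).transform(stains, meta)


def batch_correct(
    stains: pd.DataFrame,
    meta: pd.DataFrame,
    reference_replicate=None,
    pool_groups: bool = False,
):
    """Functional wrapper over :class:`BatchCorrector`.

    Returns (corrected stain table, list of BatchScaling).
    """
    bc = BatchCorrector(reference_replicate=reference_replicate, pool_groups=pool_groups)
    corrected = bc.fit_transform(stains, meta)
    return corrected, bc.scalings_
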