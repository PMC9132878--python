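"""Posterior push-forward to uni-axial stress-stretch behaviour.

Each posterior draw of the reduced material parameters defines a virtual
uni-axial stretch test of a myocardial strip along the myocyte or sheet
direction (homogeneous deformation, stretch lambda = l/L).  Pushing every
draw through the constitutive law yields a posterior distribution of
stress-stretch curves; its spread at a stretch level is summarized by the
inverse interquartile range of the stress (identifiability in stress space)
and its accuracy against the known ground-truth curve by the median inverse
absolute error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constitutive import (MaterialParameters, NumericRangeError,
                           UniaxialSolveError, uniaxial_stress)
from .inference import PosteriorSamples

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_STRETCH_GRID",
    "StressStretchCurve",
    "CurveDistribution",
    "curve",
    "posterior_curves",
    "stress_iiqr",
    "median_inverse_abs_error",
    "battery_stress_summary",
]

#: Stretch levels at which posterior stress distributions are summarized.
DEFAULT_STRETCH_GRID: tuple[float, ...] = (1.02, 1.05, 1.10, 1.15, 1.20,
                                           1.25, 1.30)

#: Cap applied to infinite inverse-absolute-error draws.
_INV_ERR_CAP = 1e6


@dataclass(frozen=True)
class StressStretchCurve:
    """Axial Cauchy stress (kPa) on a strictly increasing stretch grid."""

    stretch: np.ndarray
    stress: np.ndarray
    direction: str

    def __post_init__(self):
        lam = np.asarray(self.stretch, dtype=float)
        sig = np.asarray(self.stress, dtype=float)
        if lam.ndim != 1 or lam.shape != sig.shape:
            raise ValueError("stretch and stress must be matching 1-D arrays")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("stretch grid must be strictly increasing")
        object.__setattr__(self, "stretch", lam)
        object.__setattr__(self, "stress", sig)

    def at(self, lam: float) -> float:
        idx = np.where(np.isclose(self.stretch, lam))[0]
        if idx.size == 0:
            raise KeyError(f"stretch {lam} not on the curve grid")
        return float(self.stress[idx[0]])


@dataclass
class CurveDistribution:
    """Per-stretch arrays of stress draws, one row per posterior sample."""

    stretch: np.ndarray
    stresses: np.ndarray  # (n_draws, n_stretch)
    direction: str
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.stresses.shape[0]

    def at(self, lam: float) -> np.ndarray:
        idx = np.where(np.isclose(self.stretch, lam))[0]
        if idx.size == 0:
            raise KeyError(f"stretch {lam} not on the grid")
        return self.stresses[:, idx[0]]

    def median_curve(self) -> StressStretchCurve:
        return StressStretchCurve(self.stretch,
                                  np.median(self.stresses, axis=0),
                                  self.direction)


def curve(params: MaterialParameters, direction: str = "fibre",
          grid=DEFAULT_STRETCH_GRID) -> StressStretchCurve:
    """Uni-axial stress-stretch curve for one parameter set."""
    lam = np.asarray(grid, dtype=float)
    stress = np.array([uniaxial_stress(params, l, direction) for l in lam])
    return StressStretchCurve(stretch=lam, stress=stress, direction=direction)


def posterior_curves(samples: PosteriorSamples, direction: str = "fibre",
                     grid=DEFAULT_STRETCH_GRID, thin_to: int = 500,
                     warn_unconverged: bool = True) -> CurveDistribution:
    """One stress-stretch curve per (thinned) posterior draw.

    Draws whose lateral-stretch solve fails are logged and dropped.
    """
    if warn_unconverged:
        rep = samples.convergence()
        if not rep.converged:
            logger.warning("pushing forward an unconverged posterior "
                           "(max PSRF %.3f)", rep.max_psrf)
    theta = samples.theta()
    n = theta.shape[0]
    if thin_to is not None and n > thin_to:
        idx = np.linspace(0, n - 1, thin_to).astype(int)
        theta = theta[idx]
    lam = np.asarray(grid, dtype=float)
    rows = []
    n_failed = 0
    for t in theta:
        try:
            params = MaterialParameters.reduced(*t)
            rows.append([uniaxial_stress(params, l, direction) for l in lam])
        except (UniaxialSolveError, NumericRangeError) as err:
            n_failed += 1
            logger.debug("dropped posterior draw: %s", err)
    if n_failed:
        logger.warning("dropped %d/%d posterior draws in stress push-forward",
                       n_failed, theta.shape[0])
    return CurveDistribution(stretch=lam, stresses=np.asarray(rows),
                             direction=direction,
                             meta={"n_failed": n_failed, "edp": samples.edp})


def stress_iiqr(dist: CurveDistribution, lam: float) -> float:
    """Inverse interquartile range (kPa^-1) of the stress draws at a
    stretch level; raises on a degenerate (zero-spread) distribution."""
    draws = dist.at(lam)
    if draws.size < 4:
        raise ValueError("need at least 4 draws")
    q25, q75 = np.percentile(draws, [25, 75])
    if q75 - q25 <= 0.0:
        raise ValueError(f"degenerate stress distribution at stretch {lam}: "
                         "zero interquartile range")
    return float(1.0 / (q75 - q25))


def median_inverse_abs_error(dist: CurveDistribution,
                             truth: StressStretchCurve, lam: float) -> float:
    """Median over draws of 1/|stress_draw - stress_true| at a stretch level.

    Exact-zero errors are capped at 1e6 kPa^-1 (flagged via the return cap)
    rather than propagating infinities into the median.
    """
    draws = dist.at(lam)
    err = np.abs(draws - truth.at(lam))
    with np.errstate(divide="ignore"):
        inv = np.where(err > 0, 1.0 / np.maximum(err, 1e-300), np.inf)
    inv = np.minimum(inv, _INV_ERR_CAP)
    return float(np.median(inv))


def battery_stress_summary(battery_samples: dict, battery: list,
                           direction: str = "fibre",
                           grid=DEFAULT_STRETCH_GRID,
                           thin_to: int = 200) -> pd.DataFrame:
    """Stress-space identifiability and accuracy table for a battery run.

    ``battery_samples`` maps (case_id, EDP) -> PosteriorSamples (e.g. the
    ``samples`` attrs of :func:`lvuq.inference.run_iuq_battery` with
    ``keep_samples=True``).  Returns one row per (case, EDP, stretch) with
    the stress I-IQR and median inverse absolute error against the case's
    true curve.
    """
    truth_curves = {c["case_id"]: curve(c["params"], direction, grid)
                    for c in battery}
    rows = []
    for (case_id, edp), samples in battery_samples.items():
        if case_id not in truth_curves:
            continue
        dist = posterior_curves(samples, direction, grid, thin_to=thin_to,
                                warn_unconverged=False)
        if dist.n_draws < 4:
            logger.warning("case %s EDP %s: too few surviving draws", case_id,
                           edp)
            continue
        for lam in dist.stretch:
            rows.append({
                "case_id": case_id, "EDP": float(edp), "stretch": float(lam),
                "stress_iiqr": stress_iiqr(dist, lam),
                "median_inv_abs_err": median_inverse_abs_error(
                    dist, truth_curves[case_id], lam),
            })
    return pd.DataFrame(rows)
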