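"""Desk-scale forward model of passive left-ventricular inflation.

The image-derived finite-element LV is emulated by the semi-analytic
inflation of an incompressible thick-walled cylinder with rule-based
transmural fibre rotation.  The deformation family is

    r(R) = sqrt(r_i^2 + (R^2 - R_i^2) / lambda_z),   theta = Theta,
    z = lambda_z Z,

which is exactly isochoric.  The two unknowns (r_i, lambda_z) are found
from radial equilibrium (the cavity pressure equals the transmural
integral of (tau_thth - tau_rr)/r) and the closed-tube reduced axial force
balance.  Because the material is hyperelastic and the loading quasi-static,
the response is path independent and only the final end-diastolic pressure
needs to be solved, which is equivalent to a linear pressure ramp.

Quantities of interest are the cavity volume (ml) and 24 segmental
circumferential / longitudinal / radial Green-Lagrange strains (4 short-axis
slices x 6 AHA-style sectors), referenced to the end-diastolic state:
E = (C - I)/2 with C = Ft^T Ft and Ft = F^{-1} the deformation from
end-diastole back to the reference.  Under that clinical convention all
strains vanish at zero pressure, circumferential strains are negative and
radial strains positive on inflation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .constitutive import (MMHG_TO_KPA, InvariantSet, MaterialParameters,
                           NumericRangeError, _dpsi)
from .design import INPUT_NAMES, MATERIAL_NAMES, DESIGN_BOUNDS

logger = logging.getLogger(__name__)

__all__ = [
    "GeometryFibreSpec",
    "SegmentLayout",
    "InputVector",
    "DeformedConfiguration",
    "QoIVector",
    "SimulationFailure",
    "solve_inflation",
    "compute_qois",
    "simulate",
    "generate_training_set",
    "add_observation_noise",
    "generate_test_battery",
    "N_SEGMENTS",
    "STAR_SEGMENT",
]

N_SLICES = 4
N_SECTORS = 6
N_SEGMENTS = N_SLICES * N_SECTORS
#: Index of the pre-selected segment used for the SA strain outputs: the
#: inferior-lateral sector of the second short-axis slice.
STAR_SEGMENT = 1 * N_SECTORS + 4


class SimulationFailure(RuntimeError):
    """The inflation solve diverged (e.g. near-zero stiffness at high
    pressure).  Recorded and skipped by dataset generators, not fatal."""


@dataclass(frozen=True)
class GeometryFibreSpec:
    """Reference cylinder geometry and rule-based fibre/sheet angles.

    Radii and length in mm; angles in degrees.  The fibre helix angle varies
    linearly in the normalized transmural coordinate from ``alpha_endo`` at
    the endocardium to ``alpha_epi`` at the epicardium; the sheet angle
    likewise between ``sheet_endo`` and ``sheet_epi``.  Defaults give a
    reference cavity volume of ~157 ml, sized so that simulated volumes span
    the clinically reported binning range.
    """

    R_i: float = 25.0
    R_o: float = 35.0
    L: float = 80.0
    alpha_endo: float = 60.0
    alpha_epi: float = -90.0
    sheet_endo: float = 45.0
    sheet_epi: float = -45.0
    n_quad: int = 16

    def __post_init__(self):
        if not (0 < self.R_i < self.R_o):
            raise ValueError("need 0 < R_i < R_o")
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.n_quad < 2:
            raise ValueError("n_quad must be >= 2")

    @property
    def reference_volume_ml(self) -> float:
        return np.pi * self.R_i ** 2 * self.L / 1000.0

    def with_angles(self, alpha_endo: float, alpha_epi: float) -> "GeometryFibreSpec":
        return replace(self, alpha_endo=alpha_endo, alpha_epi=alpha_epi)


@dataclass(frozen=True)
class SegmentLayout:
    """Deterministic seeded segmental heterogeneity.

    Per-segment wall-thickness multipliers (mean 1, +/-10%) move the
    mid-wall sampling radius, and per-slice axial factors (mean 1, +/-5%)
    modulate the local axial stretch, so the 24 strains of each type are
    non-degenerate.  Fixed by ``seed``.
    """

    seed: int = 0
    thickness_multipliers: np.ndarray = field(default=None, repr=False)
    slice_axial_factors: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        rng = np.random.default_rng(self.seed)
        if self.thickness_multipliers is None:
            w = 1.0 + 0.10 * (2.0 * rng.random(N_SEGMENTS) - 1.0)
            w = w / w.mean()
            object.__setattr__(self, "thickness_multipliers", w)
        if self.slice_axial_factors is None:
            g = 1.0 + 0.05 * (2.0 * rng.random(N_SLICES) - 1.0)
            g = g / g.mean()
            object.__setattr__(self, "slice_axial_factors", g)
        if np.any(self.thickness_multipliers <= 0):
            raise ValueError("thickness multipliers must be positive")


@dataclass(frozen=True)
class InputVector:
    """One forward-model input: material constants + EDP (mmHg) + angles."""

    params: MaterialParameters
    EDP: float
    alpha_endo: float = 60.0
    alpha_epi: float = -90.0

    def __post_init__(self):
        if self.EDP < 0:
            raise ValueError("EDP must be non-negative")

    @classmethod
    def from_array(cls, row) -> "InputVector":
        row = np.asarray(row, dtype=float)
        if row.shape != (11,):
            raise ValueError("expected 11 inputs "
                             "(8 material + EDP + 2 fibre angles)")
        return cls(params=MaterialParameters.from_array(row[:8]),
                   EDP=row[8], alpha_endo=row[9], alpha_epi=row[10])

    def to_array(self) -> np.ndarray:
        return np.concatenate([self.params.to_array(),
                               [self.EDP, self.alpha_endo, self.alpha_epi]])


@dataclass(frozen=True)
class DeformedConfiguration:
    """Solved inflation state: deformed inner radius (mm), axial stretch,
    and the geometry it was solved on."""

    r_i: float
    lambda_z: float
    spec: GeometryFibreSpec
    residual: float

    def radius(self, R) -> np.ndarray:
        """Deformed radius r(R) from incompressibility."""
        R = np.asarray(R, dtype=float)
        return np.sqrt(self.r_i ** 2 + (R ** 2 - self.spec.R_i ** 2) / self.lambda_z)


@dataclass(frozen=True)
class QoIVector:
    """Cavity volume (ml) and 24 segmental strains of each type."""

    LVV: float
    eps_cc: np.ndarray
    eps_ll: np.ndarray
    eps_rr: np.ndarray

    def __post_init__(self):
        for name in ("eps_cc", "eps_ll", "eps_rr"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_SEGMENTS,):
                raise ValueError(f"{name} must have {N_SEGMENTS} entries")
            object.__setattr__(self, name, arr)

    def to_array(self) -> np.ndarray:
        """Concatenated (73,) vector: LVV, eps_cc[24], eps_ll[24], eps_rr[24]."""
        return np.concatenate([[self.LVV], self.eps_cc, self.eps_ll, self.eps_rr])

    @staticmethod
    def array_names() -> list[str]:
        return (["LVV"]
                + [f"eps_cc_{i}" for i in range(N_SEGMENTS)]
                + [f"eps_ll_{i}" for i in range(N_SEGMENTS)]
                + [f"eps_rr_{i}" for i in range(N_SEGMENTS)])


# -- local stress state across the wall -------------------------------------

def _wall_stress_differences(params: MaterialParameters, spec: GeometryFibreSpec,
                             R: np.ndarray, r_i: float, lam_z: float):
    """Vectorized deviatoric Cauchy stress differences at radii ``R``.

    Returns (t_qq - t_rr, t_zz - t_rr, lam_r) where t is the p-free part of
    the Cauchy stress in the local (r, theta, z) frame.  The fibre lies in
    the circumferential-axial tangent plane at helix angle alpha(R); the
    sheet is rotated by the sheet angle beta(R) out of the tangent plane
    towards the radial direction.
    """
    r = np.sqrt(r_i ** 2 + (R ** 2 - spec.R_i ** 2) / lam_z)
    lam_t = r / R
    lam_r = 1.0 / (lam_t * lam_z)

    t = (R - spec.R_i) / (spec.R_o - spec.R_i)
    alpha = np.deg2rad(spec.alpha_endo + (spec.alpha_epi - spec.alpha_endo) * t)
    beta = np.deg2rad(spec.sheet_endo + (spec.sheet_epi - spec.sheet_endo) * t)

    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    # reference directions in the (r, theta, z) frame
    # m0 = (0, ca, sa); c0 = in-plane fibre normal (0, -sa, ca);
    # s0 = sb * e_r + cb * c0  (unit, orthogonal to m0)
    m_r = np.zeros_like(R)
    m_t = lam_t * ca
    m_z = lam_z * sa
    s_r = lam_r * sb
    s_t = -lam_t * cb * sa
    s_z = lam_z * cb * ca

    I1 = lam_r ** 2 + lam_t ** 2 + lam_z ** 2
    I4f = m_t ** 2 + m_z ** 2
    I4s = s_r ** 2 + s_t ** 2 + s_z ** 2
    I8 = m_t * s_t + m_z * s_z

    p = params
    with np.errstate(over="raise"):
        try:
            e1 = np.exp(p.b * (I1 - 3.0))
            d1 = 0.5 * p.a * e1
            ext_f = np.maximum(I4f - 1.0, 0.0)
            d4f = p.a_f * ext_f * np.exp(p.b_f * ext_f ** 2)
            ext_s = np.maximum(I4s - 1.0, 0.0)
            d4s = p.a_s * ext_s * np.exp(p.b_s * ext_s ** 2)
            d8 = p.a_fs * I8 * np.exp(p.b_fs * I8 ** 2)
        except FloatingPointError as err:
            raise NumericRangeError("isotropic/anisotropic (wall quadrature)",
                                    float(np.max(I1))) from err

    t_rr = 2 * d1 * lam_r ** 2 + 2 * d4f * m_r ** 2 + 2 * d4s * s_r ** 2 \
        + 2 * d8 * m_r * s_r
    t_tt = 2 * d1 * lam_t ** 2 + 2 * d4f * m_t ** 2 + 2 * d4s * s_t ** 2 \
        + 2 * d8 * m_t * s_t
    t_zz = 2 * d1 * lam_z ** 2 + 2 * d4f * m_z ** 2 + 2 * d4s * s_z ** 2 \
        + 2 * d8 * m_z * s_z
    return t_tt - t_rr, t_zz - t_rr, lam_r, r


def solve_inflation(x: InputVector, spec: GeometryFibreSpec | None = None) -> DeformedConfiguration:
    """Inflate the cylinder to the input's EDP.

    Solves for (r_i, lambda_z) such that the radial-equilibrium quadrature
    equals the cavity pressure and the closed-tube reduced axial force
    vanishes.  Raises :class:`SimulationFailure` on divergence.
    """
    if spec is None:
        spec = GeometryFibreSpec()
    spec = spec.with_angles(x.alpha_endo, x.alpha_epi)
    P = x.EDP * MMHG_TO_KPA

    if x.EDP == 0.0:
        return DeformedConfiguration(r_i=spec.R_i, lambda_z=1.0, spec=spec,
                                     residual=0.0)

    # Gauss-Legendre quadrature in the reference radial coordinate.
    xq, wq = np.polynomial.legendre.leggauss(spec.n_quad)
    Rq = 0.5 * (spec.R_o - spec.R_i) * xq + 0.5 * (spec.R_o + spec.R_i)
    Wq = 0.5 * (spec.R_o - spec.R_i) * wq

    def residual(u: np.ndarray, P_target: float = P) -> np.ndarray:
        r_i, lam_z = u
        if r_i <= 0 or lam_z <= 0:
            return np.array([1e6, 1e6])
        try:
            dtt, dzz, lam_r, r = _wall_stress_differences(
                x.params, spec, Rq, r_i, lam_z)
        except NumericRangeError:
            return np.array([1e6, 1e6])
        with np.errstate(over="ignore", invalid="ignore"):
            # pressure balance: int (t_tt - t_rr)/r dr, dr = lam_r dR
            p_quad = np.sum(Wq * dtt / r * lam_r)
            # closed-tube reduced axial force, normalized to a stress (kPa)
            n_quad = np.pi * np.sum(Wq * (2 * dzz - dtt) * r * lam_r)
            out = np.array([p_quad - P_target, n_quad / (np.pi * r_i ** 2)])
        if not np.all(np.isfinite(out)):
            return np.array([1e6, 1e6])
        return out

    sol = optimize.root(residual, np.array([spec.R_i * 1.05, 1.01]),
                        method="hybr", tol=1e-12)
    res = residual(sol.x)
    if (not sol.success) or np.abs(res).max() > 1e-8:
        # continuation fallback: ramp the pressure, re-using each solution
        # as the next initial guess (helps very soft configurations)
        u = np.array([spec.R_i * 1.02, 1.005])
        converged = False
        for frac in np.linspace(0.1, 1.0, 10):
            sol = optimize.root(residual, u, args=(P * frac,),
                                method="hybr", tol=1e-12)
            if not sol.success:
                break
            u = sol.x
            converged = bool(frac == 1.0)
        res = residual(sol.x)
        if not (converged and np.abs(res).max() <= 1e-8):
            raise SimulationFailure(
                f"inflation solve diverged at EDP={x.EDP:g} mmHg "
                f"(residual {np.abs(res).max():.3g} kPa)")
    r_i, lam_z = sol.x
    if not (r_i > spec.R_i * 0.999 and lam_z > 0):
        raise SimulationFailure("non-physical inflation solution")
    return DeformedConfiguration(r_i=float(r_i), lambda_z=float(lam_z),
                                 spec=spec, residual=float(np.abs(res).max()))


def compute_qois(config: DeformedConfiguration,
                 layout: SegmentLayout | None = None) -> QoIVector:
    """Extract cavity volume and 24 segmental strains from a solved state.

    Strains are end-diastole-referenced Green-Lagrange components: with
    principal stretches (lam_r, lam_t, lam_z) of the loading deformation at
    a segment's mid-wall radius, eps_cc = (lam_t^-2 - 1)/2, etc.
    """
    if layout is None:
        layout = SegmentLayout()
    spec = config.spec
    lvv = np.pi * config.r_i ** 2 * (config.lambda_z * spec.L) / 1000.0

    w = layout.thickness_multipliers
    R_seg = spec.R_i + 0.5 * w * (spec.R_o - spec.R_i)
    R_seg = np.clip(R_seg, spec.R_i, spec.R_o)
    lam_t = config.radius(R_seg) / R_seg
    g = np.repeat(layout.slice_axial_factors, N_SECTORS)
    lam_z = 1.0 + g * (config.lambda_z - 1.0)
    lam_r = 1.0 / (lam_t * lam_z)

    def gl_strain(lam):
        return 0.5 * (1.0 / lam ** 2 - 1.0)

    return QoIVector(LVV=float(lvv), eps_cc=gl_strain(lam_t),
                     eps_ll=gl_strain(lam_z), eps_rr=gl_strain(lam_r))


def simulate(x: InputVector, spec: GeometryFibreSpec | None = None,
             layout: SegmentLayout | None = None) -> QoIVector:
    """Convenience: solve inflation then extract QoIs."""
    return compute_qois(solve_inflation(x, spec), layout)


def generate_training_set(design: np.ndarray,
                          spec: GeometryFibreSpec | None = None,
                          layout: SegmentLayout | None = None,
                          input_names: tuple[str, ...] = INPUT_NAMES,
                          max_failure_rate: float = 0.10):
    """Run the forward surrogate over every design row.

    ``design`` has one column per name in ``input_names`` (subsets allowed:
    missing material constants default to the reduced-form fixed values,
    missing angles to 60/-90 deg).  Failed solves are dropped and logged.
    Returns ``(X, Y, ok)``: the retained inputs, the (n_ok, 73) QoI matrix
    and the boolean success mask over the original design.
    """
    design = np.asarray(design, dtype=float)
    n = design.shape[0]
    ok = np.ones(n, dtype=bool)
    rows = []
    for i in range(n):
        x = _row_to_input(design[i], input_names)
        try:
            rows.append(simulate(x, spec, layout).to_array())
        except (SimulationFailure, NumericRangeError) as err:
            ok[i] = False
            logger.warning("simulation %d/%d failed: %s", i, n, err)
    n_fail = int((~ok).sum())
    if n_fail > max_failure_rate * n:
        raise SimulationFailure(
            f"{n_fail}/{n} simulations failed (> {max_failure_rate:.0%}); "
            "check design bounds / geometry")
    if n_fail:
        logger.info("dropped %d failed simulations of %d", n_fail, n)
    Y = np.array(rows) if rows else np.empty((0, 73))
    return design[ok], Y, ok


def _row_to_input(row: np.ndarray, input_names) -> InputVector:
    vals = dict(zip(input_names, row))
    mat = {k: vals[k] for k in MATERIAL_NAMES if k in vals}
    missing = [k for k in MATERIAL_NAMES if k not in mat]
    if missing:
        fixed = MaterialParameters.reduced(1, 1, 1, 1).to_dict()
        mat.update({k: fixed[k] for k in missing})
    return InputVector(params=MaterialParameters(**mat),
                       EDP=vals.get("EDP", 10.0),
                       alpha_endo=vals.get("alpha_endo", 60.0),
                       alpha_epi=vals.get("alpha_epi", -90.0))


def add_observation_noise(q: QoIVector, sigma0: float = 5.0,
                          sigma_strain: float = 0.03,
                          seed: int | np.random.Generator = 0) -> np.ndarray:
    """Noisy observation (25,): volume + 24 circumferential strains.

    The volume is corrupted with N(0, sigma0^2) (sigma0 in ml, default 5)
    and each circumferential strain with iid N(0, sigma_strain^2) (default
    0.03).  Longitudinal and radial strains are not observed: they cannot
    currently be extracted at high precision from CMR images.
    """
    if sigma0 < 0 or sigma_strain < 0:
        raise ValueError("noise SDs must be non-negative")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    y = np.empty(1 + N_SEGMENTS)
    y[0] = q.LVV + sigma0 * rng.standard_normal()
    y[1:] = q.eps_cc + sigma_strain * rng.standard_normal(N_SEGMENTS)
    return y


def generate_test_battery(n_cases: int = 100,
                          edp_list=(5.0, 10.0, 15.0, 20.0, 25.0),
                          bounds=(0.1, 10.0),
                          seed: int = 0,
                          sigma0: float = 5.0,
                          sigma_strain: float = 0.03,
                          spec: GeometryFibreSpec | None = None,
                          layout: SegmentLayout | None = None) -> list[dict]:
    """Synthetic I-UQ test battery.

    ``n_cases`` reduced material-parameter configurations are drawn
    log-uniformly on ``bounds`` and re-used at every EDP in ``edp_list``
    (fibre angles fixed at 60/-90 deg).  Each case record carries the true
    parameters, and per EDP the noise-free QoIs and a noisy observation.
    Cases whose simulation fails at any EDP are dropped and logged,
    mirroring mesh-distortion failures of the finite-element original.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = bounds
    theta = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n_cases, 4)))
    battery = []
    for c in range(n_cases):
        params = MaterialParameters.reduced(*theta[c])
        case = {"case_id": c, "params": params, "observations": {},
                "qois": {}}
        try:
            for edp in edp_list:
                x = InputVector(params=params, EDP=float(edp))
                q = simulate(x, spec, layout)
                case["qois"][float(edp)] = q
                case["observations"][float(edp)] = add_observation_noise(
                    q, sigma0, sigma_strain, seed=rng)
        except (SimulationFailure, NumericRangeError) as err:
            logger.warning("battery case %d failed: %s", c, err)
            continue
        battery.append(case)
    return battery
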