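"""Holzapfel-Ogden orthotropic hyperelasticity for passive myocardium.

The strain-energy density is

    Psi = a/(2b) [exp(b (I1 - 3)) - 1]
        + sum_{i in {f,s}} a_i/(2 b_i) [exp(b_i (max(I4i, 1) - 1)^2) - 1]
        + a_fs/(2 b_fs) [exp(b_fs I8fs^2) - 1]

with invariants of the right Cauchy-Green tensor C = F^T F:
I1 = tr C, I4f = m0.(C m0), I4s = s0.(C s0), I8fs = m0.(C s0), where m0 and
s0 are the unit fibre and sheet directions in the reference configuration.
The max() switch means fibres and sheets only resist extension; the
derivative at exactly I4 = 1 is taken on the compression branch (zero).

Stresses are Cauchy stresses for an incompressible material,
tau = tau_bar(F) - p I, with p the Lagrange multiplier.  All stresses and
stiffness-like parameters are in kPa; exponents are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy import optimize

__all__ = [
    "MaterialParameters",
    "DeformationState",
    "InvariantSet",
    "StressTensor",
    "NumericRangeError",
    "UniaxialSolveError",
    "compute_invariants",
    "strain_energy",
    "cauchy_stress",
    "uniaxial_stress",
    "MMHG_TO_KPA",
]

#: Conversion constant: 1 mmHg in kPa.  Applied only at the boundary where
#: cavity pressures (mmHg) enter the mechanics (kPa).
MMHG_TO_KPA = 0.133322

# Largest exponent fed to exp() before a structured overflow error is raised.
_EXP_GUARD = 500.0

# Reduced-parameterization fixed values (sheet and fibre-sheet shear terms),
# from the biaxial-test literature used for personalised LV models.
_REDUCED_FIXED = {"a_s": 0.69, "b_s": 1.11, "a_fs": 0.31, "b_fs": 2.58}


class NumericRangeError(FloatingPointError):
    """Raised when an exponential term of the strain energy overflows.

    Carries ``term``, one of ``"isotropic"``, ``"fibre"``, ``"sheet"``,
    ``"shear"``, identifying the offending contribution.
    """

    def __init__(self, term: str, exponent: float):
        self.term = term
        self.exponent = float(exponent)
        super().__init__(
            f"exponent {exponent:.3g} in the {term} term exceeds the "
            f"numeric-range guard ({_EXP_GUARD:g})"
        )


class UniaxialSolveError(RuntimeError):
    """Lateral-stretch root find for the uni-axial protocol failed."""

    def __init__(self, message: str, residual: np.ndarray | None = None):
        self.residual = residual
        super().__init__(message)


@dataclass(frozen=True)
class MaterialParameters:
    """The eight Holzapfel-Ogden material constants.

    a, a_f, a_s, a_fs are stiffness-like (kPa); b, b_f, b_s, b_fs are
    dimensionless exponents.  a/b set the isotropic matrix response, a_f/b_f
    the extra stiffness along myofibres, a_s/b_s along the sheet direction,
    and a_fs/b_fs the fibre-sheet shear coupling.
    """

    a: float
    b: float
    a_f: float
    b_f: float
    a_s: float = field(default=_REDUCED_FIXED["a_s"])
    b_s: float = field(default=_REDUCED_FIXED["b_s"])
    a_fs: float = field(default=_REDUCED_FIXED["a_fs"])
    b_fs: float = field(default=_REDUCED_FIXED["b_fs"])

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0.0:
                raise ValueError(f"material constant {f.name}={v!r} must be "
                                 "strictly positive and finite")

    @classmethod
    def reduced(cls, a: float, b: float, a_f: float, b_f: float) -> "MaterialParameters":
        """Reduced four-parameter form: sheet/shear constants held at the
        literature values (a_s=0.69 kPa, b_s=1.11, a_fs=0.31 kPa, b_fs=2.58)."""
        return cls(a=a, b=b, a_f=a_f, b_f=b_f, **_REDUCED_FIXED)

    @classmethod
    def names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.names()], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "MaterialParameters":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (8,):
            raise ValueError("expected 8 material constants")
        return cls(**dict(zip(cls.names(), arr)))

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in self.names()}

    def with_(self, **kw) -> "MaterialParameters":
        return replace(self, **kw)


def _check_unit(v: np.ndarray, name: str, tol: float = 1e-8) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector")
    if abs(np.linalg.norm(v) - 1.0) > tol:
        raise ValueError(f"{name} must be a unit vector (|{name}|="
                         f"{np.linalg.norm(v):.6g})")
    return v


@dataclass(frozen=True)
class DeformationState:
    """A deformation gradient with reference fibre/sheet directions.

    F must be (approximately) isochoric, det F = 1; m0 and s0 must be unit
    and mutually orthogonal.
    """

    F: np.ndarray
    m0: np.ndarray
    s0: np.ndarray

    def __post_init__(self):
        F = np.asarray(self.F, dtype=float)
        if F.shape != (3, 3):
            raise ValueError("F must be a 3x3 matrix")
        object.__setattr__(self, "F", F)
        m0 = _check_unit(self.m0, "m0")
        s0 = _check_unit(self.s0, "s0")
        if abs(float(m0 @ s0)) > 1e-8:
            raise ValueError("m0 and s0 must be orthogonal")
        object.__setattr__(self, "m0", m0)
        object.__setattr__(self, "s0", s0)
        J = float(np.linalg.det(F))
        if abs(J - 1.0) > 1e-6:
            raise ValueError(f"det F = {J:.8g}; deformation must be isochoric")


@dataclass(frozen=True)
class InvariantSet:
    """Strain invariants I1, I4f, I4s, I8fs of C = F^T F."""

    I1: float
    I4f: float
    I4s: float
    I8fs: float

    def __post_init__(self):
        if self.I4f <= 0 or self.I4s <= 0:
            raise ValueError("I4f and I4s must be positive")


@dataclass(frozen=True)
class StressTensor:
    """Cauchy stress tau (kPa, symmetric) and Lagrange multiplier p (kPa)."""

    tau: np.ndarray
    p: float

    def __post_init__(self):
        tau = np.asarray(self.tau, dtype=float)
        if tau.shape != (3, 3):
            raise ValueError("tau must be 3x3")
        if not np.allclose(tau, tau.T, atol=1e-8 * max(1.0, np.abs(tau).max())):
            raise ValueError("tau must be symmetric")
        object.__setattr__(self, "tau", 0.5 * (tau + tau.T))


def compute_invariants(state: DeformationState) -> InvariantSet:
    """Invariants I1 = tr C, I4f = m0.(C m0), I4s = s0.(C s0), I8fs = m0.(C s0)."""
    C = state.F.T @ state.F
    return InvariantSet(
        I1=float(np.trace(C)),
        I4f=float(state.m0 @ C @ state.m0),
        I4s=float(state.s0 @ C @ state.s0),
        I8fs=float(state.m0 @ C @ state.s0),
    )


def _guarded_exp(x: float, term: str) -> float:
    if x > _EXP_GUARD:
        raise NumericRangeError(term, x)
    return float(np.exp(x))


def strain_energy(params: MaterialParameters, inv: InvariantSet) -> float:
    """Strain-energy density Psi in kPa.

    Anisotropic I4 terms use max(I4, 1): fibres/sheets support extension only.
    Psi = 0 at the reference configuration (I1=3, I4f=I4s=1, I8fs=0).
    """
    p = params
    e1 = _guarded_exp(p.b * (inv.I1 - 3.0), "isotropic")
    psi = p.a / (2.0 * p.b) * (e1 - 1.0)
    for a_i, b_i, I4, term in (
        (p.a_f, p.b_f, inv.I4f, "fibre"),
        (p.a_s, p.b_s, inv.I4s, "sheet"),
    ):
        stretch = max(I4, 1.0) - 1.0
        e4 = _guarded_exp(b_i * stretch * stretch, term)
        psi += a_i / (2.0 * b_i) * (e4 - 1.0)
    e8 = _guarded_exp(p.b_fs * inv.I8fs ** 2, "shear")
    psi += p.a_fs / (2.0 * p.b_fs) * (e8 - 1.0)
    return float(psi)


def _dpsi(params: MaterialParameters, inv: InvariantSet) -> tuple[float, float, float, float]:
    """Partial derivatives (dPsi/dI1, dPsi/dI4f, dPsi/dI4s, dPsi/dI8fs).

    At I4 exactly 1 the derivative is defined on the compression branch (0).
    """
    p = params
    d1 = 0.5 * p.a * _guarded_exp(p.b * (inv.I1 - 3.0), "isotropic")
    d4 = []
    for a_i, b_i, I4, term in (
        (p.a_f, p.b_f, inv.I4f, "fibre"),
        (p.a_s, p.b_s, inv.I4s, "sheet"),
    ):
        if I4 > 1.0:
            d4.append(a_i * (I4 - 1.0) * _guarded_exp(b_i * (I4 - 1.0) ** 2, term))
        else:
            d4.append(0.0)
    d8 = p.a_fs * inv.I8fs * _guarded_exp(p.b_fs * inv.I8fs ** 2, "shear")
    return d1, d4[0], d4[1], d8


def cauchy_stress(params: MaterialParameters, state: DeformationState, p: float = 0.0) -> StressTensor:
    """Cauchy stress tau = F dPsi/dF (push-forward) - p I, in kPa.

    tau_bar = 2 psi1 B + 2 psi4f m(x)m + 2 psi4s s(x)s + psi8 (m(x)s + s(x)m)
    with B = F F^T, m = F m0, s = F s0 and psi_i = dPsi/dI_i.
    """
    inv = compute_invariants(state)
    d1, d4f, d4s, d8 = _dpsi(params, inv)
    F = state.F
    B = F @ F.T
    m = F @ state.m0
    s = F @ state.s0
    tau = 2.0 * d1 * B
    tau += 2.0 * d4f * np.outer(m, m)
    tau += 2.0 * d4s * np.outer(s, s)
    tau += d8 * (np.outer(m, s) + np.outer(s, m))
    # Incompressibility gauge: the energy is defined only on det F = 1, so
    # the spherical part of the push-forward is indeterminate and absorbed
    # into the Lagrange multiplier.  Report the deviatoric part minus p I;
    # stress differences (the observable part) are unaffected.
    tau -= (np.trace(tau) / 3.0) * np.eye(3)
    tau -= p * np.eye(3)
    return StressTensor(tau=tau, p=float(p))


# -- homogeneous uni-axial stretch protocol ---------------------------------

_DIRECTION_AXIS = {"fibre": 0, "sheet": 1}


def _uniaxial_tau_bar(params: MaterialParameters, lams: np.ndarray) -> np.ndarray:
    """Deviatoric Cauchy stress for a diagonal stretch state, material frame
    m0 = e1, s0 = e2.  Bypasses the isochoric check so the root finder can
    iterate through non-isochoric trial states."""
    l1, l2, l3 = lams
    inv = InvariantSet(I1=float(l1 * l1 + l2 * l2 + l3 * l3),
                       I4f=float(l1 * l1), I4s=float(l2 * l2), I8fs=0.0)
    d1, d4f, d4s, _ = _dpsi(params, inv)
    tau = 2.0 * d1 * np.array([l1 * l1, l2 * l2, l3 * l3])
    tau[0] += 2.0 * d4f * l1 * l1
    tau[1] += 2.0 * d4s * l2 * l2
    return np.diag(tau)


def uniaxial_stress(params: MaterialParameters, stretch: float,
                    direction: str = "fibre") -> float:
    """Axial Cauchy stress (kPa) of a homogeneous uni-axial stretch test.

    A myocardial strip is stretched to lambda = l/L along the myocyte
    (``"fibre"``) or sheet (``"sheet"``) direction.  The two lateral
    stretches are found by root-finding such that the material is isochoric
    (lam1 lam2 lam3 = 1) and both lateral Cauchy stresses vanish; the
    equal-lateral isotropic solution lambda^(-1/2) seeds the solver.
    Orthotropy makes the two lateral directions inequivalent, hence the full
    two-variable solve.
    """
    if direction not in _DIRECTION_AXIS:
        raise ValueError("direction must be 'fibre' or 'sheet'")
    lam = float(stretch)
    if lam <= 0:
        raise ValueError("stretch must be positive")
    axis = _DIRECTION_AXIS[direction]
    lateral = [i for i in range(3) if i != axis]

    if abs(lam - 1.0) < 1e-14:
        return 0.0

    def tau_bar(lat: np.ndarray) -> np.ndarray:
        lams = np.empty(3)
        lams[axis] = lam
        lams[lateral[0]], lams[lateral[1]] = lat
        return _uniaxial_tau_bar(params, lams)

    def residual(lat: np.ndarray) -> np.ndarray:
        # p eliminated with the third lateral condition: p = tau_bar[l1];
        # remaining equations: tau[l0] - tau[l1] = 0 and incompressibility.
        tb = tau_bar(lat)
        return np.array([
            tb[lateral[0], lateral[0]] - tb[lateral[1], lateral[1]],
            lam * lat[0] * lat[1] - 1.0,
        ])

    x0 = np.array([lam ** -0.5, lam ** -0.5])
    sol = optimize.root(residual, x0, method="hybr", tol=1e-12)
    res = residual(sol.x)
    if not sol.success or np.abs(res).max() > 1e-8 or np.any(sol.x <= 0):
        raise UniaxialSolveError(
            f"lateral-stretch solve failed at stretch={lam:.4g} "
            f"({direction}): residual {res}", residual=res)
    tb = tau_bar(sol.x)
    p = tb[lateral[1], lateral[1]]
    return float(tb[axis, axis] - p)
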