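"""Input-parameter space, priors and quasi-random experimental designs.

The eleven forward-model inputs are the eight Holzapfel-Ogden material
constants, the end-diastolic pressure (EDP, mmHg) and the two rule-based
fibre helix angles (degrees).  Bounds follow the personalised-LV modelling
literature: material constants on [0.1, 10] (kPa or dimensionless), EDP on
[4, 30] mmHg, alpha_endo on [0, 90] deg, alpha_epi on [-90, 0] deg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc


def _sobol_points(d: int, n: int, seed) -> np.ndarray:
    # truncated (non power-of-two) draws are fine for our designs; silence
    # the balance-properties advisory
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*balance properties.*")
        return qmc.Sobol(d=d, scramble=True, seed=seed).random(n)

__all__ = [
    "MATERIAL_NAMES",
    "REDUCED_NAMES",
    "INPUT_NAMES",
    "DESIGN_BOUNDS",
    "PriorSpec",
    "sobol_design",
    "two_block_design",
]

MATERIAL_NAMES: tuple[str, ...] = (
    "a", "b", "a_f", "b_f", "a_s", "b_s", "a_fs", "b_fs")
#: Parameters kept free in the reduced parameterization.
REDUCED_NAMES: tuple[str, ...] = ("a", "b", "a_f", "b_f")
INPUT_NAMES: tuple[str, ...] = MATERIAL_NAMES + ("EDP", "alpha_endo", "alpha_epi")

DESIGN_BOUNDS: dict[str, tuple[float, float]] = {
    **{name: (0.1, 10.0) for name in MATERIAL_NAMES},
    "EDP": (4.0, 30.0),
    "alpha_endo": (0.0, 90.0),
    "alpha_epi": (-90.0, 0.0),
}


def _as_bounds_array(bounds) -> np.ndarray:
    if isinstance(bounds, dict):
        bounds = list(bounds.values())
    arr = np.asarray(bounds, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or np.any(arr[:, 0] >= arr[:, 1]):
        raise ValueError("bounds must be a (d, 2) array of (lower < upper)")
    return arr


def _map_unit(u: np.ndarray, bounds: np.ndarray, space) -> np.ndarray:
    """Map unit-cube samples to bounds, per-dimension linear or log."""
    d = bounds.shape[0]
    if isinstance(space, str):
        space = [space] * d
    if len(space) != d:
        raise ValueError("one space label per dimension required")
    out = np.empty_like(u)
    for k, sp in enumerate(space):
        lo, hi = bounds[k]
        if sp == "linear":
            out[:, k] = lo + (hi - lo) * u[:, k]
        elif sp == "log":
            if lo <= 0:
                raise ValueError(
                    f"log-space dimension {k} requires positive bounds, got {lo}")
            out[:, k] = np.exp(np.log(lo) + (np.log(hi) - np.log(lo)) * u[:, k])
        else:
            raise ValueError(f"unknown space {sp!r} (use 'linear' or 'log')")
    return out


def sobol_design(n: int, bounds, space="linear", seed: int | None = None) -> np.ndarray:
    """Scrambled Sobol low-discrepancy design mapped to ``bounds``.

    ``space`` is ``'linear'`` or ``'log'`` (scalar or per-dimension);
    log dimensions are uniform in log between their bounds.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    b = _as_bounds_array(bounds)
    u = _sobol_points(b.shape[0], n, seed)
    return _map_unit(u, b, space)


def two_block_design(n: int, bounds=None, log_names=MATERIAL_NAMES,
                     seed: int | None = None) -> np.ndarray:
    """Two-block training design over the eleven inputs.

    The first half samples the material constants uniformly in linear space,
    the second half uniformly in log space (favouring soft configurations);
    EDP and fibre angles are linear throughout.  Returns an (n, 11) array in
    ``INPUT_NAMES`` column order.
    """
    if bounds is None:
        bounds = DESIGN_BOUNDS
    b = _as_bounds_array(bounds)
    names = list(bounds.keys()) if isinstance(bounds, dict) else list(INPUT_NAMES)
    u = _sobol_points(b.shape[0], n, seed)
    n_lin = n // 2
    linear = ["linear"] * b.shape[0]
    logsp = ["log" if nm in log_names else "linear" for nm in names]
    top = _map_unit(u[:n_lin], b, linear)
    bot = _map_unit(u[n_lin:], b, logsp)
    return np.vstack([top, bot])


@dataclass(frozen=True)
class PriorSpec:
    """Independent per-input prior: uniform / log-uniform / fixed.

    ``entries`` maps input name -> ("uniform", lo, hi), ("loguniform", lo, hi)
    or ("fixed", value).  Only non-fixed inputs count as random dimensions.
    """

    entries: dict

    def __post_init__(self):
        for name, spec in self.entries.items():
            kind = spec[0]
            if kind in ("uniform", "loguniform"):
                _, lo, hi = spec
                if lo >= hi:
                    raise ValueError(f"{name}: lower bound must be < upper")
                if kind == "loguniform" and lo <= 0:
                    raise ValueError(f"{name}: log-uniform needs positive bounds")
            elif kind == "fixed":
                if len(spec) != 2:
                    raise ValueError(f"{name}: fixed entry must be ('fixed', value)")
            else:
                raise ValueError(f"{name}: unknown prior kind {kind!r}")

    @property
    def names(self) -> list[str]:
        return list(self.entries.keys())

    @property
    def varying(self) -> list[str]:
        return [n for n, s in self.entries.items() if s[0] != "fixed"]

    @property
    def n_varying(self) -> int:
        return len(self.varying)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Map unit-cube samples over the varying dimensions to full input
        rows (fixed entries filled in), columns in ``self.names`` order."""
        u = np.atleast_2d(np.asarray(u, dtype=float))
        if u.shape[1] != self.n_varying:
            raise ValueError(f"expected {self.n_varying} varying columns")
        out = np.empty((u.shape[0], len(self.entries)))
        j = 0
        for k, (name, spec) in enumerate(self.entries.items()):
            if spec[0] == "fixed":
                out[:, k] = spec[1]
            else:
                lo, hi = spec[1], spec[2]
                if spec[0] == "uniform":
                    out[:, k] = lo + (hi - lo) * u[:, j]
                else:
                    out[:, k] = np.exp(np.log(lo)
                                       + (np.log(hi) - np.log(lo)) * u[:, j])
                j += 1
        return out

    @classmethod
    def sa1(cls, material_space: str = "uniform") -> "PriorSpec":
        """All eleven inputs random: material constants uniform or
        log-uniform, EDP and fibre angles uniform."""
        kind = {"uniform": "uniform", "loguniform": "loguniform"}[material_space]
        entries = {}
        for name in INPUT_NAMES:
            lo, hi = DESIGN_BOUNDS[name]
            entries[name] = ((kind, lo, hi) if name in MATERIAL_NAMES
                             else ("uniform", lo, hi))
        return cls(entries)

    @classmethod
    def reduced(cls, edp: float, material_space: str = "uniform") -> "PriorSpec":
        """Reduced parameterization at fixed EDP: a, b, a_f, b_f random,
        sheet/shear constants fixed to the literature values, fibre angles
        fixed to 60 / -90 degrees."""
        from .constitutive import MaterialParameters

        kind = {"uniform": "uniform", "loguniform": "loguniform"}[material_space]
        fixed = MaterialParameters.reduced(1, 1, 1, 1).to_dict()
        entries = {}
        for name in INPUT_NAMES:
            if name in REDUCED_NAMES:
                lo, hi = DESIGN_BOUNDS[name]
                entries[name] = (kind, lo, hi)
            elif name in MATERIAL_NAMES:
                entries[name] = ("fixed", fixed[name])
            elif name == "EDP":
                entries[name] = ("fixed", float(edp))
            elif name == "alpha_endo":
                entries[name] = ("fixed", 60.0)
            else:
                entries[name] = ("fixed", -90.0)
        return cls(entries)
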