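"""Domain types for two-state chemical-exchange saturation-transfer analysis.

The central object is :class:`ExchangeModel`, the parameter set of a single
residue undergoing two-state exchange A (ground, visible) <-> B (excited,
invisible).  Kinetics are parameterized by the total exchange rate
``k_ex = k_AB + k_BA`` and the minor-state population ``p_B``; the
microscopic rates follow from detailed balance::

    k_AB = p_B * k_ex        (forward, A -> B)
    k_BA = (1 - p_B) * k_ex  (reverse, B -> A)

Chemical shifts are in ppm with the signed convention
``delta_delta = delta_B - delta_A``, so a residue at 118.0 ppm with
``delta_delta = -5.0`` shows its minor-state dip at 113.0 ppm.

:class:`Acquisition` carries the experiment constants (static-field Larmor
frequency of the observed nucleus, saturation time, nominal B1 list and the
fractional width of the Gaussian B1-inhomogeneity distribution), and
:class:`CestProfile` one measured Z-spectrum (one residue at one B1 field).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .exceptions import ValidationError

TWO_PI = 2.0 * math.pi

__all__ = [
    "ExchangeModel",
    "Acquisition",
    "CestProfile",
    "FitResult",
    "make_model",
    "model_from_rates",
    "angular_frequencies",
]


def _require(cond: bool, name: str, message: str) -> None:
    if not cond:
        raise ValidationError(f"parameter '{name}': {message}")


@dataclass(frozen=True)
class ExchangeModel:
    """Spin-system and kinetic parameters of one residue.

    Use :func:`make_model` / :func:`model_from_rates` rather than the raw
    constructor; they validate bounds and fill the derived rates.
    """

    delta_A: float        # ground-state shift, ppm
    delta_delta: float    # delta_B - delta_A, ppm (signed)
    k_ex: float           # k_AB + k_BA, 1/s
    p_B: float            # minor-state population, in (0, 1)
    R1_A: float           # 1/s
    R1_B: float           # 1/s
    R2_A: float           # 1/s
    R2_B: float           # 1/s

    @property
    def p_A(self) -> float:
        return 1.0 - self.p_B

    @property
    def k_AB(self) -> float:
        return self.p_B * self.k_ex

    @property
    def k_BA(self) -> float:
        return (1.0 - self.p_B) * self.k_ex

    @property
    def delta_B(self) -> float:
        return self.delta_A + self.delta_delta

    def __post_init__(self) -> None:
        _require(np.isfinite(self.delta_A), "delta_A", "must be finite")
        _require(np.isfinite(self.delta_delta), "delta_delta", "must be finite")
        _require(self.k_ex >= 0.0 and np.isfinite(self.k_ex), "k_ex", "must be >= 0 and finite")
        _require(0.0 < self.p_B < 1.0, "p_B", "must lie strictly in (0, 1)")
        for name in ("R1_A", "R1_B", "R2_A", "R2_B"):
            val = getattr(self, name)
            _require(val >= 0.0 and np.isfinite(val), name, "must be >= 0 and finite")


def make_model(
    k_ex: float,
    p_B: float,
    delta_A: float,
    delta_delta: float,
    R1_A: float = 1.5,
    R2_A: float = 10.0,
    R2_B: float = 10.0,
    R1_B: Optional[float] = None,
) -> ExchangeModel:
    """Build a validated :class:`ExchangeModel` from (k_ex, p_B).

    ``R1_B`` defaults to ``R1_A`` (tied): the minor-state longitudinal rate
    is essentially unconstrained by CEST data at typical conditions.
    """
    if R1_B is None:
        R1_B = R1_A
    return ExchangeModel(
        delta_A=delta_A, delta_delta=delta_delta, k_ex=k_ex, p_B=p_B,
        R1_A=R1_A, R1_B=R1_B, R2_A=R2_A, R2_B=R2_B,
    )


def model_from_rates(
    k_AB: float,
    k_BA: float,
    delta_A: float,
    delta_delta: float,
    **relaxation,
) -> ExchangeModel:
    """Inverse parameterization: build the model from (k_AB, k_BA)."""
    _require(k_AB >= 0.0, "k_AB", "must be >= 0")
    _require(k_BA >= 0.0, "k_BA", "must be >= 0")
    k_ex = k_AB + k_BA
    _require(k_ex > 0.0, "k_AB+k_BA", "must be > 0 to define p_B")
    p_B = k_AB / k_ex
    return make_model(k_ex=k_ex, p_B=p_B, delta_A=delta_A,
                      delta_delta=delta_delta, **relaxation)


@dataclass(frozen=True)
class Acquisition:
    """Experiment constants shared by all profiles of a project."""

    larmor_MHz: float                 # observed-nucleus Larmor frequency, MHz
    T_sat: float                      # saturation pulse duration, s
    b1_fields: Tuple[float, ...]      # nominal RF field strengths nu1, Hz
    b1_frac_sigma: float = 0.0        # fractional sigma of Gaussian B1 spread
    b1_grid_points: int = 11          # quadrature points for B1 averaging

    def __post_init__(self) -> None:
        object.__setattr__(self, "b1_fields", tuple(float(b) for b in self.b1_fields))
        _require(self.larmor_MHz > 0.0, "larmor_MHz", "must be > 0")
        _require(self.T_sat >= 0.0, "T_sat", "must be >= 0")
        _require(len(self.b1_fields) >= 1, "b1_fields", "must contain at least one field")
        for nu1 in self.b1_fields:
            _require(nu1 > 0.0, "b1_fields", f"every nu1 must be > 0, got {nu1}")
        _require(self.b1_frac_sigma >= 0.0, "b1_frac_sigma", "must be >= 0")
        _require(
            self.b1_grid_points >= 1 and self.b1_grid_points % 2 == 1,
            "b1_grid_points", "must be an odd integer >= 1",
        )


@dataclass
class CestProfile:
    """One Z-spectrum: a residue at one nominal B1 field.

    ``sigmas`` may be a scalar (broadcast), an array, or None (unknown; the
    fitting layer will estimate a noise level from the baseline).
    Offsets are sorted ascending on construction and must be distinct.
    """

    residue_id: str
    b1_Hz: float
    offsets_ppm: np.ndarray
    intensities: np.ndarray
    sigmas: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        off = np.asarray(self.offsets_ppm, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        _require(off.ndim == 1 and inten.ndim == 1, "offsets_ppm", "must be 1-D arrays")
        _require(off.size == inten.size, "intensities", "length must match offsets_ppm")
        _require(off.size >= 3, "offsets_ppm", "need at least 3 points")
        _require(bool(np.all(np.isfinite(off))), "offsets_ppm", "must be finite")
        _require(bool(np.all(np.isfinite(inten))), "intensities", "must be finite")
        _require(self.b1_Hz > 0.0, "b1_Hz", "must be > 0")
        sig = self.sigmas
        if sig is not None:
            sig = np.broadcast_to(np.asarray(sig, dtype=float), off.shape).copy()
            _require(bool(np.all(sig > 0.0)), "sigmas", "must be > 0")
        order = np.argsort(off, kind="stable")
        off = off[order]
        _require(bool(np.all(np.diff(off) > 0.0)), "offsets_ppm",
                 "must be distinct (duplicate offsets should be averaged on load)")
        self.offsets_ppm = off
        self.intensities = inten[order]
        self.sigmas = None if sig is None else sig[order]

    def __len__(self) -> int:
        return int(self.offsets_ppm.size)


@dataclass
class FitResult:
    """Outcome of a (joint) fit.

    ``global_params`` maps parameter name -> (value, stderr); for shared
    kinetics it holds k_ex, p_B and the derived k_AB, k_BA.  ``per_residue``
    maps residue_id -> {param -> (value, stderr)}.  ``curves`` maps
    (residue_id, b1_Hz) -> fitted intensity array aligned with the input
    profile of that key.
    """

    method: str
    global_params: Dict[str, Tuple[float, float]]
    per_residue: Dict[str, Dict[str, Tuple[float, float]]]
    red_chisq: float
    n_data: int
    n_params: int
    curves: Dict[Tuple[str, float], np.ndarray]
    success: bool = True
    message: str = ""
    flags: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _require(self.n_data > self.n_params, "n_data",
                 "must exceed n_params for a defined reduced chi-square")
        _require(self.red_chisq >= 0.0, "red_chisq", "must be >= 0")


def angular_frequencies(
    model: ExchangeModel,
    acq: Acquisition,
    delta_sat_ppm,
    nu1_Hz: float,
):
    """Angular frequencies (rad/s) seen from the saturation carrier.

    Returns ``(Omega_A, Omega_B, omega1)`` with
    ``Omega_S = 2*pi*(delta_S - delta_sat)*larmor_MHz`` (ppm * MHz = Hz) and
    ``omega1 = 2*pi*nu1``.  ``delta_sat_ppm`` may be scalar or array.
    """
    delta_sat = np.asarray(delta_sat_ppm, dtype=float)
    if not np.all(np.isfinite(delta_sat)):
        raise ValidationError("parameter 'delta_sat_ppm': must be finite")
    omega_A = TWO_PI * (model.delta_A - delta_sat) * acq.larmor_MHz
    omega_B = TWO_PI * (model.delta_B - delta_sat) * acq.larmor_MHz
    omega1 = TWO_PI * float(nu1_Hz)
    return omega_A, omega_B, omega1
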