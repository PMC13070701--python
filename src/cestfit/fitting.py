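"""Residue screening, initialization, joint multi-field fitting, and errors.

The central entry point is :func:`joint_fit`: a simultaneous weighted
nonlinear least-squares fit of all CEST profiles of one or more residues
acquired at two or more RF field strengths.  By default the kinetics
(k_ex, p_B) are shared across residues while chemical shifts and
relaxation rates are per residue; fitting at a single field raises
:class:`~cestfit.exceptions.DegeneracyError` because (k_ex, p_B, R2_B)
cannot be separated from one field alone.

The optimization is two-stage: automatic initial estimates (dip detection
for shifts, a coarse grid search with the analytical kernel for kinetics)
followed by bound-constrained refinement with SciPy's Trust-Region
Reflective least squares.  Uncertainties come from the linearized
covariance and, optionally, parametric Monte-Carlo resampling
(:func:`monte_carlo_errors`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.optimize
import scipy.signal

from .exceptions import DegeneracyError, ValidationError
from .model import Acquisition, CestProfile, ExchangeModel, FitResult, make_model
from . import kernels

__all__ = [
    "FitSpec",
    "MonteCarloResult",
    "detect_dips",
    "estimate_noise",
    "initial_estimates",
    "joint_fit",
    "reduced_chisq",
    "monte_carlo_errors",
]

DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "k_ex": (1.0, 1e5),          # 1/s
    "p_B": (1e-4, 0.5),
    "delta_delta": (-30.0, 30.0),  # ppm
    "R1": (0.05, 10.0),          # 1/s
    "R2": (0.5, 200.0),          # 1/s
}

# coarse initialization grid for the kinetic parameters
KEX_GRID = (50.0, 100.0, 200.0, 400.0, 800.0, 1600.0)
PB_GRID = (0.005, 0.01, 0.02, 0.05, 0.1)

# defaults used during initialization and as fallback starting values
INIT_R1, INIT_R2 = 1.5, 10.0
FALLBACK_DELTA_DELTA = 2.0
FALLBACK_KEX, FALLBACK_PB = 200.0, 0.02


@dataclass(frozen=True)
class FitSpec:
    """Options controlling a joint fit."""

    method: str = "baldwin"            # baldwin | matrix | noex
    share_kinetics: bool = True
    bounds: Optional[Dict[str, Tuple[float, float]]] = None
    mc_iterations: int = 0
    seed: Optional[int] = None
    snr_threshold: float = 3.0         # dip depth threshold, multiples of sigma
    max_nfev: Optional[int] = None

    def __post_init__(self) -> None:
        if self.method not in ("baldwin", "matrix", "noex"):
            raise ValidationError(
                f"parameter 'method': unknown method {self.method!r}")
        if self.mc_iterations < 0:
            raise ValidationError("parameter 'mc_iterations': must be >= 0")
        merged = dict(DEFAULT_BOUNDS)
        if self.bounds:
            unknown = set(self.bounds) - set(DEFAULT_BOUNDS) - {"delta_A"}
            if unknown:
                raise ValidationError(
                    f"parameter 'bounds': unknown parameter(s) {sorted(unknown)}")
            merged.update(self.bounds)
        for name, (lo, hi) in merged.items():
            if not lo < hi:
                raise ValidationError(
                    f"parameter 'bounds[{name}]': low must be < high")
        object.__setattr__(self, "_merged_bounds", merged)

    @property
    def merged_bounds(self) -> Dict[str, Tuple[float, float]]:
        return dict(self._merged_bounds)


# ---------------------------------------------------------------------------
# screening and noise estimation
# ---------------------------------------------------------------------------

def _robust_baseline(intensities: np.ndarray) -> float:
    """Median of the upper intensity quartile (exchange dips excluded)."""
    q75 = np.quantile(intensities, 0.75)
    return float(np.median(intensities[intensities >= q75]))


def detect_dips(profile: CestProfile, snr_threshold: float = 3.0
                ) -> List[Tuple[float, float]]:
    """Exchange-induced dips of one Z-spectrum, deepest first.

    A dip is a local intensity minimum whose depth below the robust
    baseline (median of the upper intensity quartile) exceeds
    ``snr_threshold`` times the median point uncertainty.  Returns
    ``(position_ppm, depth)`` pairs sorted by depth descending, so the
    first entry is the ground-state candidate and the second, when
    present, the minor-state candidate.
    """
    if len(profile) < 3:
        raise ValidationError("parameter 'profile': need at least 3 points")
    inten = profile.intensities
    if profile.sigmas is not None:
        sigma = float(np.median(profile.sigmas))
    else:
        sigma = estimate_noise(profile)
    baseline = _robust_baseline(inten)
    # a nominal sigma larger than the profile's dynamic range (e.g. unit
    # sigmas on noiseless data) would veto every dip; fall back to the
    # baseline-scatter estimate
    if snr_threshold * sigma >= baseline - float(np.min(inten)):
        sigma = estimate_noise(profile)
    threshold = snr_threshold * sigma
    # prominence suppresses noise-split twin minima inside one dip
    step = float(np.median(np.diff(profile.offsets_ppm)))
    distance = max(1, int(round(0.4 / step))) if step > 0 else 1
    idx, _ = scipy.signal.find_peaks(
        -inten, prominence=max(threshold, 1e-9), distance=distance)
    dips = [(float(profile.offsets_ppm[i]), float(baseline - inten[i]))
            for i in idx if baseline - inten[i] > threshold]
    dips.sort(key=lambda d: -d[1])
    return dips


def estimate_noise(profile: CestProfile) -> float:
    """Intensity noise estimated from the flat baseline of the profile.

    Standard deviation of the intensities at the 20% of offsets farthest
    from any detected dip (coarse sigma-free dip detection); used when the
    input has no uncertainty column.
    """
    off, inten = profile.offsets_ppm, profile.intensities
    idx, _ = scipy.signal.find_peaks(-inten, prominence=0.1)
    if idx.size:
        dist = np.min(np.abs(off[:, None] - off[idx][None, :]), axis=1)
    else:
        dist = np.abs(off - off[np.argmin(inten)])
    n_keep = max(4, int(np.ceil(0.2 * off.size)))
    sel = np.argsort(dist)[-n_keep:]
    return float(max(np.std(inten[sel], ddof=1), 1e-6))


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

MAX_INIT_DELTA_DELTA = 12.0  # ppm; plausible window for the minor dip


def _dip_based_shifts(profiles: Sequence[CestProfile],
                      snr_threshold: float) -> Tuple[float, float, List[str]]:
    """(delta_A, delta_delta, flags) from the lowest-B1 profile's dips.

    The minor-state candidate is the deepest secondary dip within a
    plausible shift window of the ground-state dip; noise blips far from
    any resonance are ignored.
    """
    low = min(profiles, key=lambda p: p.b1_Hz)
    flags: List[str] = []
    dips = detect_dips(low, snr_threshold)
    if not dips:
        delta_a = float(low.offsets_ppm[np.argmin(low.intensities)])
        flags.append(f"{low.residue_id}: no dips above threshold; "
                     "using global minimum as delta_A")
    else:
        delta_a = dips[0][0]
    secondary = [pos for pos, _ in dips[1:]
                 if abs(pos - delta_a) <= MAX_INIT_DELTA_DELTA]
    if secondary:
        delta_delta = secondary[0] - delta_a
    else:
        delta_delta = FALLBACK_DELTA_DELTA
        flags.append(f"{low.residue_id}: no secondary dip; "
                     f"delta_delta start set to +{FALLBACK_DELTA_DELTA} ppm")
    return delta_a, delta_delta, flags


def _grid_chisq(shifts: Dict[str, Tuple[float, float]],
                grouped: Dict[str, List[CestProfile]],
                acq: Acquisition, k_ex: float, p_B: float) -> float:
    total = 0.0
    for rid, profs in grouped.items():
        da, dd = shifts[rid]
        model = make_model(k_ex=k_ex, p_B=p_B, delta_A=da, delta_delta=dd,
                           R1_A=INIT_R1, R2_A=INIT_R2, R2_B=INIT_R2)
        for prof in profs:
            calc = kernels.predict_profile(model, acq, prof.b1_Hz,
                                           prof.offsets_ppm, "baldwin")
            sig = prof.sigmas if prof.sigmas is not None else 1.0
            total += float(np.sum(((prof.intensities - calc) / sig) ** 2))
    return total


def _kinetic_grid_search(shifts, grouped, acq) -> Tuple[float, float]:
    best = (np.inf, FALLBACK_KEX, FALLBACK_PB)
    for kex in KEX_GRID:
        for pb in PB_GRID:
            chi = _grid_chisq(shifts, grouped, acq, kex, pb)
            if chi < best[0]:
                best = (chi, kex, pb)
    return best[1], best[2]


#: reduced kinetic nodes for the per-residue (k_ex, p_B, delta_delta) scan
_COARSE_KINETICS = ((50.0, 0.01), (50.0, 0.05), (200.0, 0.01),
                    (200.0, 0.05), (800.0, 0.01), (800.0, 0.05))


def _coarse_shift_scan(profs: Sequence[CestProfile], acq: Acquisition,
                       delta_a: float, dd0: float) -> float:
    """Joint coarse scan of (k_ex, p_B, delta_delta) for one residue.

    Dip detection can miss a shoulder dip or pick a noise blip, and a bad
    delta_delta start drags the kinetic grid into a compensating corner.
    Scanning shift and kinetics jointly (Baldwin kernel, relaxation at
    defaults) locates the right basin; only delta_delta is harvested —
    kinetics are refined globally afterwards.
    """
    rid = profs[0].residue_id
    grouped = {rid: list(profs)}
    cands = {round(dd, 3) for dd in
             (dd0, -dd0, -7.0, -5.0, -3.0, -2.0, -1.0, -0.5,
              0.5, 1.0, 2.0, 3.0, 5.0, 7.0)}
    best = (np.inf, dd0)
    for dd in sorted(cands):
        for kex, pb in _COARSE_KINETICS:
            chi = _grid_chisq({rid: (delta_a, dd)}, grouped, acq, kex, pb)
            if chi < best[0]:
                best = (chi, dd)
    return best[1]


def _scan_delta_delta(profs: Sequence[CestProfile], acq: Acquisition,
                      delta_a: float, dd0: float, k_ex: float,
                      p_B: float) -> float:
    """Fine 1-D delta_delta scan at fixed kinetics (0.5 ppm steps)."""
    cands = np.concatenate([np.arange(-8.0, -0.24, 0.5),
                            np.arange(0.26, 8.01, 0.5), [dd0, -dd0]])
    rid = profs[0].residue_id
    best = (np.inf, dd0)
    for dd in cands:
        chi = _grid_chisq({rid: (delta_a, float(dd))}, {rid: list(profs)},
                          acq, k_ex, p_B)
        if chi < best[0]:
            best = (chi, float(dd))
    return best[1]


def initial_estimates(profiles: Sequence[CestProfile], acq: Acquisition,
                      snr_threshold: float = 3.0
                      ) -> Tuple[ExchangeModel, List[str]]:
    """Automatic starting parameters for one residue.

    delta_A and delta_delta come from dip detection on the lowest-B1
    profile; (k_ex, p_B) from a coarse grid search minimizing the
    analytical-kernel chi-square with relaxation at defaults; delta_delta
    is then refined by a 1-D kernel scan and the kinetic grid re-run.
    Always returns a usable model; fallbacks are reported in the flags.
    """
    if not profiles:
        raise ValidationError("parameter 'profiles': need at least one profile")
    rid = profiles[0].residue_id
    delta_a, delta_delta, flags = _dip_based_shifts(profiles, snr_threshold)
    grouped = {rid: list(profiles)}
    delta_delta = _coarse_shift_scan(profiles, acq, delta_a, delta_delta)
    kex, pb = _kinetic_grid_search({rid: (delta_a, delta_delta)},
                                   grouped, acq)
    delta_delta = _scan_delta_delta(profiles, acq, delta_a, delta_delta,
                                    kex, pb)
    kex, pb = _kinetic_grid_search({rid: (delta_a, delta_delta)},
                                   grouped, acq)
    model = make_model(k_ex=kex, p_B=pb, delta_A=delta_a,
                       delta_delta=delta_delta, R1_A=INIT_R1,
                       R2_A=INIT_R2, R2_B=INIT_R2)
    return model, flags


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

PER_RESIDUE_EXCHANGE = ("delta_A", "delta_delta", "R1_A", "R2_A", "R2_B")
PER_RESIDUE_NOEX = ("delta_A", "R1_A", "R2_A")

_X_SCALE = {"k_ex": 100.0, "p_B": 0.01, "delta_A": 0.1, "delta_delta": 0.1,
            "R1_A": 0.5, "R2_A": 5.0, "R2_B": 5.0}


@dataclass
class _Layout:
    """Maps the flat optimizer vector to named, per-residue parameters."""

    method: str
    share_kinetics: bool
    residues: List[str]
    names: List[str] = field(default_factory=list)
    lower: np.ndarray = None
    upper: np.ndarray = None
    x_scale: np.ndarray = None

    @classmethod
    def build(cls, method: str, share_kinetics: bool, residues: List[str],
              windows: Dict[str, Tuple[float, float]],
              bounds: Dict[str, Tuple[float, float]]) -> "_Layout":
        lay = cls(method=method, share_kinetics=share_kinetics,
                  residues=list(residues))
        names, lo, hi, xs = [], [], [], []

        def add(name, b, scale):
            names.append(name)
            lo.append(b[0])
            hi.append(b[1])
            xs.append(scale)

        kinetic = method != "noex"
        if kinetic and share_kinetics:
            add("k_ex", bounds["k_ex"], _X_SCALE["k_ex"])
            add("p_B", bounds["p_B"], _X_SCALE["p_B"])
        per = PER_RESIDUE_NOEX if method == "noex" else PER_RESIDUE_EXCHANGE
        for rid in residues:
            if kinetic and not share_kinetics:
                add(f"{rid}:k_ex", bounds["k_ex"], _X_SCALE["k_ex"])
                add(f"{rid}:p_B", bounds["p_B"], _X_SCALE["p_B"])
            for pname in per:
                if pname == "delta_A":
                    b = windows[rid]
                elif pname == "delta_delta":
                    b = bounds["delta_delta"]
                elif pname == "R1_A":
                    b = bounds["R1"]
                else:
                    b = bounds["R2"]
                add(f"{rid}:{pname}", b, _X_SCALE[pname])
        lay.names = names
        lay.lower = np.array(lo)
        lay.upper = np.array(hi)
        lay.x_scale = np.array(xs)
        return lay

    def index(self, name: str) -> int:
        return self.names.index(name)

    def models(self, x: np.ndarray) -> Dict[str, ExchangeModel]:
        """Per-residue ExchangeModel at parameter vector x."""
        out = {}
        get = lambda n: float(x[self.index(n)])
        for rid in self.residues:
            if self.method == "noex":
                out[rid] = make_model(
                    k_ex=0.0, p_B=1e-6, delta_A=get(f"{rid}:delta_A"),
                    delta_delta=0.0, R1_A=get(f"{rid}:R1_A"),
                    R2_A=get(f"{rid}:R2_A"), R2_B=get(f"{rid}:R2_A"))
                continue
            if self.share_kinetics:
                kex, pb = get("k_ex"), get("p_B")
            else:
                kex, pb = get(f"{rid}:k_ex"), get(f"{rid}:p_B")
            out[rid] = make_model(
                k_ex=kex, p_B=pb, delta_A=get(f"{rid}:delta_A"),
                delta_delta=get(f"{rid}:delta_delta"),
                R1_A=get(f"{rid}:R1_A"), R2_A=get(f"{rid}:R2_A"),
                R2_B=get(f"{rid}:R2_B"))
        return out


# ---------------------------------------------------------------------------
# joint fit
# ---------------------------------------------------------------------------

def _group_profiles(profiles: Sequence[CestProfile]
                    ) -> Dict[str, List[CestProfile]]:
    grouped: Dict[str, List[CestProfile]] = {}
    for prof in profiles:
        grouped.setdefault(prof.residue_id, []).append(prof)
    return grouped


def _fill_sigmas(profiles: Sequence[CestProfile]) -> List[CestProfile]:
    out = []
    for prof in profiles:
        if prof.sigmas is None:
            sig = estimate_noise(prof)
            prof = CestProfile(prof.residue_id, prof.b1_Hz,
                               prof.offsets_ppm, prof.intensities,
                               np.full(len(prof), sig))
        out.append(prof)
    return out


def _initial_vector(layout: _Layout, grouped, acq, spec) -> Tuple[np.ndarray, List[str]]:
    flags: List[str] = []
    shifts: Dict[str, Tuple[float, float]] = {}
    for rid, profs in grouped.items():
        da, dd, fl = _dip_based_shifts(profs, spec.snr_threshold)
        shifts[rid] = (da, dd)
        flags.extend(fl)
    x0 = np.empty(len(layout.names))
    if layout.method != "noex":
        if layout.share_kinetics:
            for rid, profs in grouped.items():
                da, dd = shifts[rid]
                shifts[rid] = (da, _coarse_shift_scan(profs, acq, da, dd))
            kex, pb = _kinetic_grid_search(shifts, grouped, acq)
            for rid, profs in grouped.items():
                da, dd = shifts[rid]
                shifts[rid] = (da, _scan_delta_delta(profs, acq, da, dd,
                                                     kex, pb))
            kex, pb = _kinetic_grid_search(shifts, grouped, acq)
            x0[layout.index("k_ex")] = kex
            x0[layout.index("p_B")] = pb
        else:
            for rid, profs in grouped.items():
                model, fl = initial_estimates(profs, acq, spec.snr_threshold)
                flags.extend(fl)
                shifts[rid] = (model.delta_A, model.delta_delta)
                x0[layout.index(f"{rid}:k_ex")] = model.k_ex
                x0[layout.index(f"{rid}:p_B")] = model.p_B
    for rid in layout.residues:
        da, dd = shifts[rid]
        x0[layout.index(f"{rid}:delta_A")] = da
        if layout.method != "noex":
            x0[layout.index(f"{rid}:delta_delta")] = dd
            x0[layout.index(f"{rid}:R2_B")] = INIT_R2
        x0[layout.index(f"{rid}:R1_A")] = INIT_R1
        x0[layout.index(f"{rid}:R2_A")] = INIT_R2
    # strictly interior start for the reflective trust region
    span = layout.upper - layout.lower
    return np.clip(x0, layout.lower + 1e-9 * span,
                   layout.upper - 1e-9 * span), flags


def _residuals(x, layout, grouped, acq, spec):
    models = layout.models(x)
    parts = []
    for rid in layout.residues:
        for prof in grouped[rid]:
            calc = kernels.predict_profile(models[rid], acq, prof.b1_Hz,
                                           prof.offsets_ppm, spec.method)
            parts.append((prof.intensities - calc) / prof.sigmas)
    return np.concatenate(parts)


def joint_fit(profiles: Sequence[CestProfile], acq: Acquisition,
              spec: FitSpec = FitSpec()) -> FitResult:
    """Simultaneous weighted least-squares fit of all profiles.

    Minimizes ``sum(((I_obs - I_calc)/sigma)**2)`` over shared kinetics
    (k_ex, p_B) plus per-residue (delta_A, delta_delta, R1_A, R2_A, R2_B)
    within bounds, with the kernel selected by ``spec.method`` (B1
    inhomogeneity averaging applies when configured on ``acq``).  R1_B is
    tied to R1_A.  Requires profiles at >= 2 distinct B1 fields.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("parameter 'profiles': empty")
    fields = {prof.b1_Hz for prof in profiles}
    if len(fields) < 2:
        raise DegeneracyError(
            "fitting requires profiles at two or more distinct RF field "
            f"strengths to resolve the (k_ex, p_B, R2_B) degeneracy; got "
            f"only {sorted(fields)} Hz")
    profiles = _fill_sigmas(profiles)
    grouped = _group_profiles(profiles)
    residues = list(grouped)
    windows = {
        rid: (min(p.offsets_ppm[0] for p in profs),
              max(p.offsets_ppm[-1] for p in profs))
        for rid, profs in grouped.items()
    }
    layout = _Layout.build(spec.method, spec.share_kinetics, residues,
                           windows, spec.merged_bounds)
    x0, flags = _initial_vector(layout, grouped, acq, spec)
    result = scipy.optimize.least_squares(
        _residuals, x0, bounds=(layout.lower, layout.upper), method="trf",
        x_scale=layout.x_scale, max_nfev=spec.max_nfev,
        args=(layout, grouped, acq, spec),
    )
    success = result.status > 0
    if not success:
        flags.append("optimizer did not converge within the evaluation "
                     "budget; best point reported")
    return _package_result(result, layout, grouped, acq, spec,
                           success, flags)


def _package_result(result, layout, grouped, acq, spec, success,
                    flags) -> FitResult:
    x = result.x
    n_data = result.fun.size
    n_params = x.size
    dof = n_data - n_params
    if dof <= 0:
        raise ValidationError(
            f"underdetermined fit: {n_data} points for {n_params} parameters")
    red = float(2.0 * result.cost / dof)
    # linearized covariance, scaled by the reduced chi-square
    jac = result.jac
    try:
        cov = np.linalg.pinv(jac.T @ jac) * red
        stderr = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        cov = None
        stderr = np.full(n_params, np.nan)

    def entry(name):
        i = layout.index(name)
        return float(x[i]), float(stderr[i])

    global_params: Dict[str, Tuple[float, float]] = {}
    if layout.method != "noex" and layout.share_kinetics:
        global_params["k_ex"] = entry("k_ex")
        global_params["p_B"] = entry("p_B")
        kex, pb = global_params["k_ex"][0], global_params["p_B"][0]
        ik, ip = layout.index("k_ex"), layout.index("p_B")
        if cov is not None:
            var_kab = (pb ** 2 * cov[ik, ik] + kex ** 2 * cov[ip, ip]
                       + 2 * pb * kex * cov[ik, ip])
            var_kba = ((1 - pb) ** 2 * cov[ik, ik] + kex ** 2 * cov[ip, ip]
                       - 2 * (1 - pb) * kex * cov[ik, ip])
            err_kab = float(np.sqrt(max(var_kab, 0.0)))
            err_kba = float(np.sqrt(max(var_kba, 0.0)))
        else:
            err_kab = err_kba = float("nan")
        global_params["k_AB"] = (pb * kex, err_kab)
        global_params["k_BA"] = ((1 - pb) * kex, err_kba)

    per_names = (PER_RESIDUE_NOEX if layout.method == "noex"
                 else PER_RESIDUE_EXCHANGE)
    per_residue: Dict[str, Dict[str, Tuple[float, float]]] = {}
    for rid in layout.residues:
        entries = {p: entry(f"{rid}:{p}") for p in per_names}
        if layout.method != "noex" and not layout.share_kinetics:
            entries["k_ex"] = entry(f"{rid}:k_ex")
            entries["p_B"] = entry(f"{rid}:p_B")
        per_residue[rid] = entries

    models = layout.models(x)
    curves = {}
    for rid in layout.residues:
        for prof in grouped[rid]:
            curves[(rid, prof.b1_Hz)] = kernels.predict_profile(
                models[rid], acq, prof.b1_Hz, prof.offsets_ppm, spec.method)
    return FitResult(
        method=spec.method, global_params=global_params,
        per_residue=per_residue, red_chisq=red, n_data=n_data,
        n_params=n_params, curves=curves, success=success,
        message=str(getattr(result, "message", "")), flags=flags,
    )


def reduced_chisq(observed, calculated, sigmas, n_params: int) -> float:
    """``sum(((obs - calc)/sigma)**2) / (n_data - n_params)``."""
    obs = np.asarray(observed, dtype=float)
    calc = np.asarray(calculated, dtype=float)
    sig = np.broadcast_to(np.asarray(sigmas, dtype=float), obs.shape)
    if obs.shape != calc.shape:
        raise ValidationError("parameter 'calculated': shape mismatch")
    if obs.size <= n_params:
        raise ValidationError(
            f"n_data ({obs.size}) must exceed n_params ({n_params})")
    return float(np.sum(((obs - calc) / sig) ** 2) / (obs.size - n_params))


# ---------------------------------------------------------------------------
# Monte-Carlo uncertainty estimation
# ---------------------------------------------------------------------------

@dataclass
class MonteCarloResult:
    """Parametric-bootstrap parameter spreads."""

    stds: Dict[str, float]
    samples: Dict[str, np.ndarray]
    n_iterations: int
    n_bound_saturated: int
    flags: List[str] = field(default_factory=list)


def monte_carlo_errors(best: FitResult, profiles: Sequence[CestProfile],
                       acq: Acquisition, spec: FitSpec) -> MonteCarloResult:
    """Parametric Monte-Carlo parameter uncertainties.

    Each iteration synthesizes a dataset as best-fit curves plus Gaussian
    noise of the per-point sigma, refits it starting from the best-fit
    parameters, and records the fitted parameters; the reported
    uncertainty is the standard deviation over iterations.  Deterministic
    given ``spec.seed``.
    """
    if spec.mc_iterations < 2:
        raise ValidationError("parameter 'mc_iterations': need >= 2")
    rng = np.random.default_rng(spec.seed)
    profiles = _fill_sigmas(list(profiles))
    refit_spec = replace(spec, mc_iterations=0,
                         max_nfev=spec.max_nfev or 60)
    collected: Dict[str, List[float]] = {}
    n_saturated = 0
    for _ in range(spec.mc_iterations):
        synth = []
        for prof in profiles:
            curve = best.curves[(prof.residue_id, prof.b1_Hz)]
            noisy = curve + rng.normal(0.0, 1.0, curve.size) * prof.sigmas
            synth.append(CestProfile(prof.residue_id, prof.b1_Hz,
                                     prof.offsets_ppm, noisy, prof.sigmas))
        fit = _warm_joint_fit(synth, acq, refit_spec, best)
        hit_bound = False
        for name, (value, _) in fit.global_params.items():
            collected.setdefault(name, []).append(value)
            if name in ("k_ex", "p_B"):
                hit_bound |= _at_bound(name, value, refit_spec)
        for rid, entries in fit.per_residue.items():
            for pname, (value, _) in entries.items():
                collected.setdefault(f"{rid}:{pname}", []).append(value)
        n_saturated += bool(hit_bound)
    samples = {k: np.asarray(v) for k, v in collected.items()}
    stds = {k: float(np.std(v, ddof=1)) for k, v in samples.items()}
    flags = []
    if n_saturated > spec.mc_iterations / 2:
        flags.append("more than half of the Monte-Carlo refits saturated a "
                     "kinetic parameter bound; spreads are unreliable")
    return MonteCarloResult(stds=stds, samples=samples,
                            n_iterations=spec.mc_iterations,
                            n_bound_saturated=n_saturated, flags=flags)


def _at_bound(name: str, value: float, spec: FitSpec,
              rel: float = 1e-6) -> bool:
    lo, hi = spec.merged_bounds[name]
    span = hi - lo
    return value - lo < rel * span or hi - value < rel * span


def _warm_joint_fit(profiles, acq, spec, best: FitResult) -> FitResult:
    """Joint fit started from a previous result's parameters."""
    grouped = _group_profiles(list(profiles))
    residues = list(grouped)
    windows = {
        rid: (min(p.offsets_ppm[0] for p in profs),
              max(p.offsets_ppm[-1] for p in profs))
        for rid, profs in grouped.items()
    }
    layout = _Layout.build(spec.method, spec.share_kinetics, residues,
                           windows, spec.merged_bounds)
    x0 = np.empty(len(layout.names))
    for i, name in enumerate(layout.names):
        if ":" in name:
            rid, pname = name.split(":", 1)
            x0[i] = best.per_residue[rid][pname][0]
        else:
            x0[i] = best.global_params[name][0]
    span = layout.upper - layout.lower
    x0 = np.clip(x0, layout.lower + 1e-9 * span, layout.upper - 1e-9 * span)
    result = scipy.optimize.least_squares(
        _residuals, x0, bounds=(layout.lower, layout.upper), method="trf",
        x_scale=layout.x_scale, max_nfev=spec.max_nfev,
        args=(layout, grouped, acq, spec),
    )
    return _package_result(result, layout, grouped, acq, spec,
                           result.status > 0, [])
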