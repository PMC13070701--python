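"""Scikit-learn estimator interface to the joint CEST fit.

:class:`CestRegressor` presents the multi-profile nonlinear regression as
a standard estimator: ``X`` holds one row per measured point with columns
``(residue_id, b1_Hz, offset_ppm)`` (pandas DataFrame, or a plain numeric
array — see :meth:`CestRegressor.fit`), ``y`` the normalized intensities.
It composes with sklearn tooling (``get_params``/``set_params``,
``clone``, pipelines, scoring); the underlying engine is
:func:`cestfit.fitting.joint_fit`.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import ValidationError
from .model import Acquisition, CestProfile
from .fitting import FitSpec, joint_fit, monte_carlo_errors
from . import kernels

__all__ = ["CestRegressor"]


def _as_columns(X):
    """(residue_ids, b1_values, offsets) from a DataFrame or array."""
    if hasattr(X, "columns"):
        required = {"residue_id", "b1_Hz", "offset_ppm"}
        missing = required - set(X.columns)
        if missing:
            raise ValidationError(
                f"parameter 'X': missing column(s) {sorted(missing)}")
        return (np.asarray(X["residue_id"]).astype(str),
                np.asarray(X["b1_Hz"], dtype=float),
                np.asarray(X["offset_ppm"], dtype=float))
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] not in (2, 3):
        raise ValidationError(
            "parameter 'X': need a DataFrame with columns (residue_id, "
            "b1_Hz, offset_ppm), an (n, 3) array (residue index, b1_Hz, "
            "offset_ppm), or an (n, 2) array (b1_Hz, offset_ppm) for a "
            "single residue")
    if arr.shape[1] == 2:
        rids = np.full(arr.shape[0], "r0")
        return rids, arr[:, 0], arr[:, 1]
    return (np.char.add("r", arr[:, 0].astype(int).astype(str)),
            arr[:, 1], arr[:, 2])


class CestRegressor(RegressorMixin, BaseEstimator):
    """Joint dual-B1-field CEST Z-spectrum regressor.

    Fits two-state exchange parameters — shared kinetics (k_ex, p_B) plus
    per-residue shifts and relaxation rates — to normalized intensities by
    bound-constrained trust-region least squares.

    Parameters
    ----------
    method : {"baldwin", "matrix", "noex"}
        Forward kernel: analytical R1rho model, full 7x7 Bloch-McConnell
        propagation, or the exchange-free baseline.
    larmor_MHz, T_sat : float
        Static-field Larmor frequency of the observed nucleus (MHz) and
        saturation pulse duration (s).
    share_kinetics : bool
        One (k_ex, p_B) pair for all residues (default) or per residue.
    b1_frac_sigma, b1_grid_points
        Gaussian B1-inhomogeneity fractional width and quadrature size.
    bounds : dict, optional
        Overrides for the default parameter bounds.
    mc_iterations, seed
        Monte-Carlo error iterations run after the fit (0 disables).

    Attributes
    ----------
    k_ex_, p_B_, k_AB_, k_BA_ : float
        Shared kinetic parameters (when ``share_kinetics``).
    per_residue_ : dict
        Per-residue fitted parameters with 1-sigma uncertainties.
    red_chisq_ : float
        Reduced chi-square of the joint fit.
    result_ : FitResult
        Full fit result (curves, flags, covering both layouts).
    mc_errors_ : MonteCarloResult or None
        Monte-Carlo spreads when ``mc_iterations > 0``.
    """

    def __init__(self, method: str = "baldwin", larmor_MHz: float = 80.12,
                 T_sat: float = 0.4, share_kinetics: bool = True,
                 b1_frac_sigma: float = 0.0, b1_grid_points: int = 11,
                 bounds: Optional[Dict[str, Tuple[float, float]]] = None,
                 mc_iterations: int = 0, seed: Optional[int] = None,
                 snr_threshold: float = 3.0,
                 max_nfev: Optional[int] = None):
        self.method = method
        self.larmor_MHz = larmor_MHz
        self.T_sat = T_sat
        self.share_kinetics = share_kinetics
        self.b1_frac_sigma = b1_frac_sigma
        self.b1_grid_points = b1_grid_points
        self.bounds = bounds
        self.mc_iterations = mc_iterations
        self.seed = seed
        self.snr_threshold = snr_threshold
        self.max_nfev = max_nfev

    # ------------------------------------------------------------------
    def _profiles_from_xy(self, X, y, sample_weight):
        rids, b1s, offsets = _as_columns(X)
        y = np.asarray(y, dtype=float)
        if y.shape != offsets.shape:
            raise ValidationError("parameter 'y': length must match X")
        if sample_weight is not None:
            sw = np.asarray(sample_weight, dtype=float)
            if sw.shape != y.shape or np.any(sw <= 0):
                raise ValidationError(
                    "parameter 'sample_weight': must be positive, one per row")
            sigmas = 1.0 / np.sqrt(sw)
        else:
            sigmas = None
        profiles = []
        for rid in dict.fromkeys(rids):          # preserve order
            for b1 in dict.fromkeys(b1s[rids == rid]):
                sel = (rids == rid) & (b1s == b1)
                profiles.append(CestProfile(
                    residue_id=str(rid), b1_Hz=float(b1),
                    offsets_ppm=offsets[sel], intensities=y[sel],
                    sigmas=None if sigmas is None else sigmas[sel]))
        return profiles

    def _acquisition(self, b1_fields) -> Acquisition:
        return Acquisition(
            larmor_MHz=self.larmor_MHz, T_sat=self.T_sat,
            b1_fields=tuple(sorted(set(float(b) for b in b1_fields))),
            b1_frac_sigma=self.b1_frac_sigma,
            b1_grid_points=self.b1_grid_points)

    def _fit_spec(self) -> FitSpec:
        return FitSpec(method=self.method,
                       share_kinetics=self.share_kinetics,
                       bounds=self.bounds,
                       mc_iterations=self.mc_iterations,
                       seed=self.seed,
                       snr_threshold=self.snr_threshold,
                       max_nfev=self.max_nfev)

    # ------------------------------------------------------------------
    def fit(self, X, y, sample_weight=None):
        """Fit exchange parameters to intensities.

        ``sample_weight`` maps to per-point variances (w = 1/sigma^2);
        when omitted, per-profile noise is estimated from the baseline.
        """
        profiles = self._profiles_from_xy(X, y, sample_weight)
        acq = self._acquisition([p.b1_Hz for p in profiles])
        spec = self._fit_spec()
        result = joint_fit(profiles, acq, spec)
        self.result_ = result
        self.per_residue_ = result.per_residue
        self.red_chisq_ = result.red_chisq
        self.n_features_in_ = 3
        self._acq_ = acq
        self._spec_ = spec
        if result.global_params:
            self.k_ex_ = result.global_params["k_ex"][0]
            self.p_B_ = result.global_params["p_B"][0]
            self.k_AB_ = result.global_params["k_AB"][0]
            self.k_BA_ = result.global_params["k_BA"][0]
        if self.mc_iterations > 0:
            self.mc_errors_ = monte_carlo_errors(result, profiles, acq, spec)
        else:
            self.mc_errors_ = None
        return self

    def _model_for(self, rid: str):
        from .model import make_model
        entries = self.per_residue_.get(rid)
        if entries is None:
            raise ValidationError(
                f"parameter 'X': residue {rid!r} was not seen during fit")
        if self.method == "noex":
            return make_model(k_ex=0.0, p_B=1e-6,
                              delta_A=entries["delta_A"][0], delta_delta=0.0,
                              R1_A=entries["R1_A"][0],
                              R2_A=entries["R2_A"][0],
                              R2_B=entries["R2_A"][0])
        if self.share_kinetics:
            kex, pb = self.k_ex_, self.p_B_
        else:
            kex, pb = entries["k_ex"][0], entries["p_B"][0]
        return make_model(k_ex=kex, p_B=pb, delta_A=entries["delta_A"][0],
                          delta_delta=entries["delta_delta"][0],
                          R1_A=entries["R1_A"][0], R2_A=entries["R2_A"][0],
                          R2_B=entries["R2_B"][0])

    def predict(self, X):
        """Predicted normalized intensities at the given rows."""
        check_is_fitted(self, "result_")
        rids, b1s, offsets = _as_columns(X)
        out = np.empty(offsets.shape)
        for rid in dict.fromkeys(rids):
            model = self._model_for(str(rid))
            for b1 in dict.fromkeys(b1s[rids == rid]):
                sel = (rids == rid) & (b1s == b1)
                out[sel] = kernels.predict_profile(
                    model, self._acq_, float(b1), offsets[sel], self.method)
        return out
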