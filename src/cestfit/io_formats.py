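"""Plain-text profile and configuration I/O.

Profile files are two- or three-column plain text (offset_ppm, intensity
[, sigma]), whitespace- or comma-delimited, with ``#`` comment lines —
the column convention of relaxation-dispersion tools.  One file holds one
residue at one B1 field; a YAML project configuration binds files to their
metadata and carries the acquisition constants.

Example configuration::

    version: 1
    acquisition:
      larmor_MHz: 80.12
      T_sat: 0.4
      b1_fields: [10.0, 100.0]
      b1_frac_sigma: 0.0
      b1_grid_points: 11
    fit:
      method: baldwin
      share_kinetics: true
      mc_iterations: 0
      seed: 1
    data:
      - {path: A1_10Hz.txt, residue: A1, b1_Hz: 10.0}
      - {path: A1_100Hz.txt, residue: A1, b1_Hz: 100.0}
    output_dir: results

Writers are deterministic: the same inputs produce byte-identical files.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .exceptions import ParseError, ValidationError
from .model import Acquisition, CestProfile, FitResult
from .fitting import FitSpec

logger = logging.getLogger(__name__)

__all__ = [
    "ProjectConfig",
    "ManifestEntry",
    "read_profile",
    "read_config",
    "save_config",
    "config_hash",
    "write_report",
    "write_curves",
]

FORMAT_VERSION = 1
_FLOAT_RE = re.compile(r"[-+]?(\d+\.?\d*|\.\d+)([eE][-+]?\d+)?$")


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def read_profile(path, residue_id: str, b1_Hz: float,
                 offsets_relative_hz: bool = False,
                 carrier_ppm: Optional[float] = None,
                 larmor_MHz: Optional[float] = None) -> CestProfile:
    """Parse one plain-text Z-spectrum file.

    Two columns give (offset_ppm, intensity); a third, the per-point
    uncertainty.  Lines starting with ``#`` are comments; fields may be
    separated by whitespace and/or commas.  Rows are sorted by offset and
    duplicate offsets averaged (logged).  With ``offsets_relative_hz`` the
    first column is a frequency offset in Hz relative to ``carrier_ppm``
    and is converted to absolute ppm via ``larmor_MHz``.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError("profile file not found", path=path)
    rows: List[Tuple[float, ...]] = []
    ncols = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = [f for f in re.split(r"[,\s]+", line) if f]
        # 4-column files are fitted-curve outputs; the first three columns
        # are (offset, I_obs, sigma)
        if len(fields) not in (2, 3, 4):
            raise ParseError(
                f"expected 2-4 columns, got {len(fields)}",
                path=path, line=lineno)
        if ncols is None:
            ncols = len(fields)
        elif len(fields) != ncols:
            raise ParseError(
                f"inconsistent column count ({len(fields)} vs {ncols})",
                path=path, line=lineno)
        vals = []
        for f in fields[:3]:
            if not _FLOAT_RE.match(f):
                raise ParseError(f"non-numeric field {f!r}",
                                 path=path, line=lineno)
            vals.append(float(f))
        if not abs(vals[1]) <= 1.5:
            raise ParseError(
                f"normalized intensity {vals[1]} outside [-1.5, 1.5]",
                path=path, line=lineno)
        rows.append(tuple(vals))
    if len(rows) < 3:
        raise ParseError(f"need at least 3 data rows, got {len(rows)}",
                         path=path)
    arr = np.asarray(rows, dtype=float)
    if offsets_relative_hz:
        if carrier_ppm is None or larmor_MHz is None:
            raise ValidationError(
                "parameter 'offsets_relative_hz': requires carrier_ppm "
                "and larmor_MHz")
        arr[:, 0] = carrier_ppm + arr[:, 0] / larmor_MHz
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    uniq, inverse, counts = np.unique(arr[:, 0], return_inverse=True,
                                      return_counts=True)
    if np.any(counts > 1):
        logger.warning("%s: %d duplicate offsets averaged",
                       path, int(np.sum(counts > 1)))
        merged = np.zeros((uniq.size, arr.shape[1]))
        merged[:, 0] = uniq
        for c in range(1, arr.shape[1]):
            merged[:, c] = np.bincount(inverse, weights=arr[:, c]) / counts
        arr = merged
    return CestProfile(
        residue_id=residue_id, b1_Hz=float(b1_Hz),
        offsets_ppm=arr[:, 0], intensities=arr[:, 1],
        sigmas=arr[:, 2] if arr.shape[1] == 3 else None)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestEntry:
    path: str
    residue: str
    b1_Hz: float


@dataclass(frozen=True)
class ProjectConfig:
    """Archivable description of one analysis project."""

    acquisition: Acquisition
    fit: FitSpec
    manifest: Tuple[ManifestEntry, ...]
    output_dir: str = "results"
    version: int = FORMAT_VERSION
    offsets_relative_hz: bool = False
    carrier_ppm: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "manifest", tuple(self.manifest))
        fields = set(self.acquisition.b1_fields)
        for entry in self.manifest:
            if entry.b1_Hz not in fields:
                raise ValidationError(
                    f"parameter 'manifest': file {entry.path!r} declares "
                    f"B1 = {entry.b1_Hz} Hz, not one of the acquisition "
                    f"fields {sorted(fields)}")

    def load_profiles(self, base_dir=None) -> List[CestProfile]:
        base = Path(base_dir) if base_dir is not None else Path(".")
        return [
            read_profile(base / e.path, e.residue, e.b1_Hz,
                         offsets_relative_hz=self.offsets_relative_hz,
                         carrier_ppm=self.carrier_ppm,
                         larmor_MHz=self.acquisition.larmor_MHz)
            for e in self.manifest
        ]


_ACQ_KEYS = {"larmor_MHz", "T_sat", "b1_fields", "b1_frac_sigma",
             "b1_grid_points", "carrier_ppm", "offsets_relative_hz"}
_FIT_KEYS = {"method", "share_kinetics", "bounds", "mc_iterations", "seed",
             "snr_threshold", "max_nfev"}
_TOP_KEYS = {"version", "acquisition", "fit", "data", "output_dir"}
_ENTRY_KEYS = {"path", "residue", "b1_Hz"}


def _reject_unknown(given, allowed, context: str) -> None:
    unknown = set(given) - allowed
    if not unknown:
        return
    parts = []
    for key in sorted(unknown):
        hint = difflib.get_close_matches(key, allowed, n=1)
        parts.append(f"{key!r}" + (f" (did you mean {hint[0]!r}?)" if hint else ""))
    raise ParseError(f"unknown {context} key(s): {', '.join(parts)}")


def read_config(path) -> ProjectConfig:
    """Load and validate a YAML project configuration."""
    path = Path(path)
    if not path.exists():
        raise ParseError("configuration file not found", path=path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"invalid YAML: {exc}", path=path) from exc
    if not isinstance(doc, dict):
        raise ParseError("configuration must be a mapping", path=path)
    _reject_unknown(doc, _TOP_KEYS, "configuration")
    missing = []
    acq_doc = doc.get("acquisition") or {}
    for key in ("larmor_MHz", "T_sat", "b1_fields"):
        if key not in acq_doc:
            missing.append(f"acquisition.{key}")
    if not doc.get("data"):
        missing.append("data (file manifest)")
    if missing:
        raise ParseError("missing required configuration key(s): "
                         + ", ".join(missing), path=path)
    _reject_unknown(acq_doc, _ACQ_KEYS, "acquisition")
    fit_doc = doc.get("fit") or {}
    _reject_unknown(fit_doc, _FIT_KEYS, "fit")
    offsets_relative_hz = bool(acq_doc.pop("offsets_relative_hz", False))
    carrier_ppm = acq_doc.pop("carrier_ppm", None)
    try:
        acq = Acquisition(**acq_doc)
        if "bounds" in fit_doc and fit_doc["bounds"] is not None:
            fit_doc["bounds"] = {k: tuple(v)
                                 for k, v in fit_doc["bounds"].items()}
        fit = FitSpec(**fit_doc)
    except (TypeError, ValidationError) as exc:
        raise ParseError(f"invalid configuration: {exc}", path=path) from exc
    entries = []
    for i, entry in enumerate(doc["data"]):
        if not isinstance(entry, dict):
            raise ParseError(f"data entry {i} must be a mapping", path=path)
        _reject_unknown(entry, _ENTRY_KEYS, f"data entry {i}")
        try:
            entries.append(ManifestEntry(path=str(entry["path"]),
                                         residue=str(entry["residue"]),
                                         b1_Hz=float(entry["b1_Hz"])))
        except KeyError as exc:
            raise ParseError(f"data entry {i} missing key {exc}", path=path)
    return ProjectConfig(
        acquisition=acq, fit=fit, manifest=tuple(entries),
        output_dir=str(doc.get("output_dir", "results")),
        version=int(doc.get("version", FORMAT_VERSION)),
        offsets_relative_hz=offsets_relative_hz,
        carrier_ppm=carrier_ppm)


def _config_doc(config: ProjectConfig) -> dict:
    acq = config.acquisition
    fit = config.fit
    doc = {
        "version": config.version,
        "acquisition": {
            "larmor_MHz": acq.larmor_MHz,
            "T_sat": acq.T_sat,
            "b1_fields": list(acq.b1_fields),
            "b1_frac_sigma": acq.b1_frac_sigma,
            "b1_grid_points": acq.b1_grid_points,
        },
        "fit": {
            "method": fit.method,
            "share_kinetics": fit.share_kinetics,
            "mc_iterations": fit.mc_iterations,
            "seed": fit.seed,
            "snr_threshold": fit.snr_threshold,
            "max_nfev": fit.max_nfev,
        },
        "data": [{"path": e.path, "residue": e.residue, "b1_Hz": e.b1_Hz}
                 for e in config.manifest],
        "output_dir": config.output_dir,
    }
    if fit.bounds:
        doc["fit"]["bounds"] = {k: list(v) for k, v in fit.bounds.items()}
    if config.offsets_relative_hz:
        doc["acquisition"]["offsets_relative_hz"] = True
        doc["acquisition"]["carrier_ppm"] = config.carrier_ppm
    return doc


def save_config(config: ProjectConfig, path) -> None:
    """Write the configuration as YAML (round-trips through read_config)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(_config_doc(config), sort_keys=True,
                                   default_flow_style=False))


def config_hash(config: ProjectConfig) -> str:
    """Short digest over all semantic fields (excludes output_dir)."""
    doc = _config_doc(config)
    doc.pop("output_dir", None)
    blob = json.dumps(doc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_report(result: FitResult, path, config_digest: str = "") -> None:
    """Tab-separated parameter report (global + per-residue, with errors)."""
    lines = [
        f"# method\t{result.method}",
        f"# config_hash\t{config_digest}",
        f"# n_data\t{result.n_data}",
        f"# n_params\t{result.n_params}",
        f"# reduced_chisq\t{_fmt(result.red_chisq)}",
        f"# converged\t{result.success}",
    ]
    for flag in result.flags:
        lines.append(f"# flag\t{flag}")
    summary = [result.method]
    for key in ("k_AB", "k_BA"):
        if key in result.global_params:
            value, err = result.global_params[key]
            summary.append(f"{key}={_fmt(value)}+/-{_fmt(err)}")
        else:
            summary.append(f"{key}=-")
    summary.append(f"red_chisq={_fmt(result.red_chisq)}")
    lines.append("# summary\t" + "\t".join(summary))
    lines.append("scope\tparameter\tvalue\tstderr")
    for name in sorted(result.global_params):
        value, err = result.global_params[name]
        lines.append(f"global\t{name}\t{_fmt(value)}\t{_fmt(err)}")
    for rid in sorted(result.per_residue):
        for pname in sorted(result.per_residue[rid]):
            value, err = result.per_residue[rid][pname]
            lines.append(f"{rid}\t{pname}\t{_fmt(value)}\t{_fmt(err)}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n")


def curve_filename(residue_id: str, b1_Hz: float) -> str:
    return f"{residue_id}_{b1_Hz:g}Hz.txt"


def write_curves(result: FitResult, profiles: Sequence[CestProfile],
                 out_dir) -> List[Path]:
    """Per-profile files with observed and fitted intensities.

    Columns: offset_ppm, I_obs, [sigma,] I_fit — readable back by
    :func:`read_profile` (which takes the first two/three columns).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for prof in profiles:
        key = (prof.residue_id, prof.b1_Hz)
        if key not in result.curves:
            raise ValidationError(
                f"parameter 'profiles': no fitted curve for {key}")
        fit = result.curves[key]
        lines = [f"# residue\t{prof.residue_id}",
                 f"# b1_Hz\t{_fmt(prof.b1_Hz)}"]
        if prof.sigmas is not None:
            lines.append("# columns\toffset_ppm I_obs sigma I_fit")
            for o, i, s, f in zip(prof.offsets_ppm, prof.intensities,
                                  prof.sigmas, fit):
                lines.append(f"{_fmt(o)}\t{_fmt(i)}\t{_fmt(s)}\t{_fmt(f)}")
        else:
            lines.append("# columns\toffset_ppm I_obs I_fit")
            for o, i, f in zip(prof.offsets_ppm, prof.intensities, fit):
                lines.append(f"{_fmt(o)}\t{_fmt(i)}\t{_fmt(f)}")
        target = out_dir / curve_filename(prof.residue_id, prof.b1_Hz)
        target.write_text("\n".join(lines) + "\n")
        written.append(target)
    return written
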