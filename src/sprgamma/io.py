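"""File formats, run configuration, and the end-to-end pipeline.

Angle scans travel as two-column delimited text (``angle_deg,
reflectivity``) with '#' comment lines; layer stacks and run
configurations as JSON or YAML documents; reports as JSON with full
provenance (config hash, seeds, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, FormatError
from .features import (
    DEFAULT_SPR_WINDOW,
    DEFAULT_TIR_WINDOW,
    calibrate_prism,
    extract_features,
)
from .inversion import fit_bulk_eps, fit_interfacial_eps
from .optics import AngleScan, LayerStack, OpticalLayer
from .thermo import default_calibration, gamma_excess

__all__ = [
    "read_angle_scan",
    "write_angle_scan",
    "read_stack_config",
    "write_stack_config",
    "stack_from_config",
    "stack_to_config",
    "RunConfig",
    "run_pipeline",
]


# --- angle scans --------------------------------------------------------


def read_angle_scan(path) -> AngleScan:
    """Read and validate a two-column angle scan.

    Accepts comma-, tab- or whitespace-delimited text with an optional
    ``angle_deg, reflectivity`` header and '#' comments.  Non-monotone
    angles or reflectivities outside [-0.05, 1.05] raise
    :class:`FormatError` naming the offending line; values are then
    clipped into [0, 1].
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, comment="#", sep=None, engine="python", header=None,
            skip_blank_lines=True,
        )
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse ({exc})") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need two columns (angle, reflectivity)")
    first = df.iloc[0]
    header_offset = 1
    try:
        float(first.iloc[0])
        header_offset = 0
    except (TypeError, ValueError):
        df = df.iloc[1:]
    try:
        angles = df.iloc[:, 0].astype(float).to_numpy()
        refl = df.iloc[:, 1].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric data ({exc})") from exc
    if np.isnan(angles).any() or np.isnan(refl).any():
        raise FormatError(f"{path}: missing or unparseable values")
    bad = np.nonzero(np.diff(angles) <= 0)[0]
    if bad.size:
        # +2: 1-based line numbering plus the offending *second* row
        line = int(bad[0]) + 2 + header_offset
        raise FormatError(
            f"{path}: angles not strictly increasing at data line {line}"
        )
    out = np.nonzero((refl < -0.05) | (refl > 1.05))[0]
    if out.size:
        line = int(out[0]) + 1 + header_offset
        raise FormatError(
            f"{path}: reflectivity outside [-0.05, 1.05] at data line {line}"
        )
    meta = _read_hash_metadata(path)
    meta.setdefault("source", "measured")
    meta["path"] = str(path)
    return AngleScan(angles, np.clip(refl, 0.0, 1.0), meta)


def _read_hash_metadata(path: Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, val = body.split(":", 1)
                try:
                    meta[key.strip()] = json.loads(val.strip())
                except json.JSONDecodeError:
                    meta[key.strip()] = val.strip()
    return meta


def write_angle_scan(scan: AngleScan, path) -> None:
    """Write a scan with its metadata embedded as '#' header lines."""
    with open(path, "w") as fh:
        for key, val in scan.metadata.items():
            fh.write(f"# {key}: {json.dumps(val)}\n")
        fh.write("angle_deg,reflectivity\n")
        for a, r in zip(scan.angles_deg, scan.reflectivity):
            fh.write(f"{a:.9g},{r:.9g}\n")


# --- stack configs ------------------------------------------------------


def stack_to_config(stack: LayerStack) -> dict:
    return {
        "wavelength_nm": stack.wavelength_nm,
        "layers": [
            {
                "label": l.label,
                "eps_real": complex(l.eps).real,
                "eps_imag": complex(l.eps).imag,
                **(
                    {"thickness_nm": l.thickness_nm}
                    if l.thickness_nm is not None
                    else {}
                ),
                **({"interfacial": True} if l.interfacial else {}),
            }
            for l in stack.layers
        ],
    }


def stack_from_config(doc: dict) -> LayerStack:
    try:
        layers = tuple(
            OpticalLayer(
                label=entry["label"],
                eps=complex(
                    float(entry.get("eps_real", 1.0)),
                    float(entry.get("eps_imag", 0.0)),
                ),
                thickness_nm=entry.get("thickness_nm"),
                interfacial=bool(entry.get("interfacial", False)),
            )
            for entry in doc["layers"]
        )
        return LayerStack(layers, float(doc.get("wavelength_nm", 632.8)))
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"invalid stack config: {exc}") from exc


def read_stack_config(path) -> LayerStack:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: expected a mapping document")
    return stack_from_config(doc)


def write_stack_config(stack: LayerStack, path) -> None:
    path = Path(path)
    doc = stack_to_config(stack)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


# --- pipeline -----------------------------------------------------------


@dataclass
class RunConfig:
    """Everything one index-matched measurement pair needs.

    ``partner_scan`` is the index-matched reference (e.g. ethanol); when
    present, the bulk permittivity is taken from *its* TIR edge and the
    prism is calibrated against ``reference_eps_bulk`` (literature value
    of the reference liquid).  Without a partner the sample scan's own
    edge is used and the report flags the fallback.
    """

    stack_config: str
    sample_scan: str
    partner_scan: str | None = None
    reference_eps_bulk: float | None = None
    t_nm: float = 1.0
    tir_window: tuple[float, float] = DEFAULT_TIR_WINDOW
    spr_window: tuple[float, float] = DEFAULT_SPR_WINDOW
    fit_mode: str = "curve"
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.t_nm <= 0:
            raise ConfigurationError("assumed thickness must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tir_window"] = list(d["tir_window"])
        d["spr_window"] = list(d["spr_window"])
        return d

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        for key in ("tir_window", "spr_window"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Calibrate, extract features, invert, and compute Gamma.

    Deterministic for fixed inputs; the report carries full provenance.
    """
    stack = read_stack_config(config.stack_config)
    stack = stack.without_interfacial_layer()
    sample = read_angle_scan(config.sample_scan)
    partner = (
        read_angle_scan(config.partner_scan) if config.partner_scan else None
    )

    if partner is not None and config.reference_eps_bulk is not None:
        eps_prism = calibrate_prism(
            partner, config.reference_eps_bulk, config.tir_window
        )
        calibration = "partner scan + reference_eps_bulk"
    else:
        eps_prism = complex(stack.prism.eps).real
        calibration = "stack config prism value"

    bulk_source_scan = partner if partner is not None else sample
    eps_bulk = fit_bulk_eps(bulk_source_scan, eps_prism, config.tir_window)

    feats = extract_features(sample, config.tir_window, config.spr_window)
    fit = fit_interfacial_eps(
        sample,
        stack,
        eps_bulk,
        t_nm=config.t_nm,
        mode=config.fit_mode,
        window=config.spr_window,
    )
    excess = gamma_excess(
        fit.eps_interf, eps_bulk, config.t_nm, default_calibration()
    )
    report = {
        "theta_tir_deg": feats.theta_tir,
        "theta_spr_deg": feats.theta_spr,
        "eps_prism": eps_prism,
        "eps_bulk": eps_bulk,
        "eps_interf": fit.eps_interf,
        "assumed_thickness_nm": config.t_nm,
        "fit_residual": fit.residual,
        "fit_converged": fit.converged,
        "x_interf": excess.x_interf,
        "x_bulk": excess.x_bulk,
        "gamma_ng_cm2": excess.gamma_ng_cm2,
        "gamma_ng_nm2": excess.gamma_ng_nm2,
        "excess_molecules_per_nm3": excess.excess_molecules_per_nm3,
        "provenance": {
            "package_version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "prism_calibration": calibration,
            "bulk_from_partner": partner is not None,
            "seed": config.seed,
        },
    }
    if partner is None:
        report["provenance"]["fallback"] = (
            "no index-matched partner: bulk permittivity taken from the "
            "sample scan's own TIR edge"
        )
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2) + "\n"
        )
    return report
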