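"""File formats: TIFF image pairs, CSV bundles, YAML configuration.

A complex image travels as a pair of 32-bit float TIFFs,
``<prefix>_amp.tiff`` (transmissivity in [0, 1]) and
``<prefix>_phase.tiff`` (radians, wrapped).  Beat acquisitions travel as
a CSV metadata table plus a CSV sample matrix, coefficients as a
(n, u, v, re, im) CSV.  All formats are plain text or uncompressed TIFF
for interoperability with generic viewers.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import fields as dataclass_fields
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .coefficients import CoefficientSet
from .exceptions import InvalidArgumentError
from .forward import AcquisitionConfig, BeatRecord
from .geometry import SystemConfig
from .hadamard import HadamardPlan, basis_pattern
from .image import ComplexImage, wrap_phase

__all__ = [
    "write_complex_image",
    "read_complex_image",
    "save_beat_records",
    "load_beat_records",
    "write_coefficients_csv",
    "read_coefficients_csv",
    "write_path_csv",
    "export_patterns",
    "load_config",
]

logger = logging.getLogger("spholo")

_AMP_TOL = 1e-6  # float32 round-off allowance on the [0, 1] amplitude range


def write_complex_image(image: ComplexImage, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>_amp.tiff`` and ``<prefix>_phase.tiff`` (float32)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    amp_path = prefix.with_name(prefix.name + "_amp.tiff")
    phase_path = prefix.with_name(prefix.name + "_phase.tiff")
    tifffile.imwrite(amp_path, image.amplitude.astype(np.float32))
    tifffile.imwrite(phase_path, image.phase.astype(np.float32))
    return amp_path, phase_path


def read_complex_image(prefix: str | Path, strict: bool = True) -> ComplexImage:
    """Read an amplitude/phase TIFF pair written by :func:`write_complex_image`.

    With ``strict=True`` (objects) amplitudes outside [0, 1] are rejected;
    reconstructions may be read back with ``strict=False``.  Out-of-range
    phase values are wrapped with a logged warning.
    """
    prefix = Path(prefix)
    amp_path = prefix.with_name(prefix.name + "_amp.tiff")
    phase_path = prefix.with_name(prefix.name + "_phase.tiff")
    for p, part in ((amp_path, "amplitude"), (phase_path, "phase")):
        if not p.exists():
            raise InvalidArgumentError(f"missing {part} file: {p}")
    amp = np.asarray(tifffile.imread(amp_path), dtype=np.float64)
    phase = np.asarray(tifffile.imread(phase_path), dtype=np.float64)
    if amp.shape != phase.shape:
        raise InvalidArgumentError(
            f"amplitude {amp.shape} and phase {phase.shape} shapes differ"
        )
    if strict and (amp.min() < -_AMP_TOL or amp.max() > 1.0 + _AMP_TOL):
        raise InvalidArgumentError(
            f"amplitude outside [0, 1] (range {amp.min():.4g}..{amp.max():.4g})"
        )
    amp = np.clip(amp, 0.0, None)
    if phase.size and (phase.min() <= -np.pi - 1e-6 or phase.max() > np.pi + 1e-6):
        logger.warning("phase values outside (-pi, pi]; wrapping on read")
        phase = np.asarray(wrap_phase(phase))
    return ComplexImage(amplitude=amp, phase=phase)


def save_beat_records(records: list[BeatRecord], prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>_meta.csv`` (order, t_start) and ``<prefix>_samples.csv``."""
    if not records:
        raise InvalidArgumentError("no records to save")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    meta_path = prefix.with_name(prefix.name + "_meta.csv")
    samples_path = prefix.with_name(prefix.name + "_samples.csv")
    with open(meta_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["order", "t_start"])
        for r in records:
            writer.writerow([r.order, repr(float(r.t_start))])
    np.savetxt(samples_path, np.stack([r.samples for r in records]), delimiter=",")
    return meta_path, samples_path


def load_beat_records(prefix: str | Path) -> list[BeatRecord]:
    prefix = Path(prefix)
    meta_path = prefix.with_name(prefix.name + "_meta.csv")
    samples_path = prefix.with_name(prefix.name + "_samples.csv")
    for p in (meta_path, samples_path):
        if not p.exists():
            raise InvalidArgumentError(f"missing beat bundle file: {p}")
    with open(meta_path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    samples = np.atleast_2d(np.loadtxt(samples_path, delimiter=","))
    if len(rows) != samples.shape[0]:
        raise InvalidArgumentError("metadata and sample matrix row counts differ")
    return [
        BeatRecord(order=int(row["order"]), t_start=float(row["t_start"]), samples=s)
        for row, s in zip(rows, samples)
    ]


def write_coefficients_csv(
    coeffs: CoefficientSet, plan: HadamardPlan, path: str | Path
) -> Path:
    """Write coefficients as (n, u, v, re, im) rows."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    u, v = plan.index_map(coeffs.orders)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["n", "u", "v", "re", "im"])
        for n, uu, vv, c in zip(coeffs.orders, u, v, coeffs.values):
            writer.writerow([int(n), int(uu), int(vv), repr(float(c.real)), repr(float(c.imag))])
    return path


def read_coefficients_csv(path: str | Path, kind: str = "binary") -> CoefficientSet:
    path = Path(path)
    if not path.exists():
        raise InvalidArgumentError(f"missing coefficient file: {path}")
    orders, values = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            orders.append(int(row["n"]))
            values.append(float(row["re"]) + 1j * float(row["im"]))
    return CoefficientSet(orders=np.array(orders), values=np.array(values), kind=kind)


def write_path_csv(plan: HadamardPlan, path: str | Path) -> Path:
    """Export the square sampling path as (n, u, v) rows."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["n", "u", "v"])
        for n, (u, v) in zip(plan.path, plan.pairs):
            writer.writerow([int(n), int(u), int(v)])
    return path


def export_patterns(plan: HadamardPlan, orders, path: str | Path) -> Path:
    """Export binary patterns as an 8-bit TIFF stack (0/255) for inspection."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stack = np.stack(
        [basis_pattern(plan, int(n), "binary").values * np.uint8(255) for n in orders]
    ).astype(np.uint8)
    tifffile.imwrite(path, stack, photometric="minisblack")
    return path


def _build_from_mapping(cls, mapping: dict, section: str):
    allowed = {f.name for f in dataclass_fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise InvalidArgumentError(
            f"unknown key(s) in '{section}' section: {', '.join(sorted(unknown))}; "
            f"allowed: {', '.join(sorted(allowed))}"
        )
    try:
        return cls(**mapping)
    except TypeError as e:
        raise InvalidArgumentError(f"invalid '{section}' configuration: {e}") from None


def load_config(path: str | Path | None = None) -> tuple[AcquisitionConfig, SystemConfig]:
    """Load acquisition and system configuration from a YAML file.

    The file holds optional ``acquisition`` and ``system`` mappings; an
    empty (or absent) file yields the full default configuration.
    Unknown keys are rejected with a field-level message; physical
    validation (Nyquist, positive lengths) happens in the dataclasses.
    """
    data: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise InvalidArgumentError(f"missing configuration file: {path}")
        loaded = yaml.safe_load(path.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise InvalidArgumentError("configuration root must be a mapping")
        data = loaded
    unknown = set(data) - {"acquisition", "system"}
    if unknown:
        raise InvalidArgumentError(
            f"unknown top-level section(s): {', '.join(sorted(unknown))}"
        )
    acq = _build_from_mapping(AcquisitionConfig, data.get("acquisition") or {}, "acquisition")
    sys_ = _build_from_mapping(SystemConfig, data.get("system") or {}, "system")
    logger.info("effective acquisition config: %s", acq)
    logger.info("effective system config: %s", sys_)
    return acq, sys_
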