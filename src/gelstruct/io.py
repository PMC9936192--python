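"""File formats, configuration, and reproducibility plumbing.

Images travel as single- or multi-page TIFF with a JSON sidecar holding the
physical calibration and provenance (package version, seed, config hash).
Curves and histograms are CSV with a JSON metadata sidecar.  Lengths are
always µm in configs and outputs; pixels exist only internally.  All writes
are atomic (temp file + rename).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .params import CorrelationCurve, IntensityHistogram, InvalidParameterError

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "write_curve_csv",
    "read_curve_csv",
    "write_histogram_csv",
    "read_histogram_csv",
    "load_config",
    "config_from_dict",
    "provenance",
    "atomic_write_json",
]


class ConfigError(ValueError):
    """Raised on unknown or missing configuration keys."""


def _atomic_bytes(path: Path, data: bytes) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_json(path, obj) -> None:
    _atomic_bytes(Path(path), json.dumps(obj, indent=2, sort_keys=True).encode())


def provenance(config: dict | None = None, seed: int | None = None) -> dict:
    """Provenance record attached to every artifact."""
    from . import __version__

    rec: dict[str, Any] = {"package": "gelstruct", "version": __version__}
    if seed is not None:
        rec["seed"] = int(seed)
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        rec["config_sha256"] = hashlib.sha256(blob).hexdigest()
    return rec


# ---------------------------------------------------------------------------
# images


def read_image_stack(
    path,
    expected_bits: int = 8,
    pixel_size: float | None = None,
    rescale_policy: str | None = None,
) -> tuple[list[np.ndarray], dict]:
    """Read a single- or multi-page TIFF as a list of 2D 8-bit arrays.

    The physical calibration comes from, in order: the ``pixel_size``
    argument, a JSON sidecar (``<path>.json`` with key ``pixel_size_um``),
    or TIFF resolution tags.  16-bit input is refused unless
    ``rescale_policy="divide256"`` is configured.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.series[0].asarray()
        tags = tf.pages[0].tags
        res = tags.get("XResolution")
        unit = tags.get("ResolutionUnit")
    if data.ndim == 2:
        pages = [data]
    elif data.ndim == 3:
        pages = list(data)
    else:
        raise InvalidParameterError(f"expected a 2-D image or a stack, got shape {data.shape}")
    meta: dict[str, Any] = {"path": str(path), "n_pages": len(pages)}

    sidecar = path.with_name(path.name + ".json")
    if pixel_size is None and sidecar.exists():
        pixel_size = json.loads(sidecar.read_text()).get("pixel_size_um")
        meta["pixel_size_source"] = "sidecar"
    if pixel_size is None and res is not None and unit is not None:
        num, den = res.value
        if num > 0 and unit.value == 3:  # pixels per centimetre
            pixel_size = 1e4 * den / num
            meta["pixel_size_source"] = "tiff_tags"
    if pixel_size is None:
        raise ConfigError(
            "missing physical calibration: set config key 'pixel_size_um' "
            "(or provide a sidecar/TIFF resolution tag)"
        )
    meta["pixel_size_um"] = float(pixel_size)

    out = []
    for arr in pages:
        if arr.dtype == np.uint8:
            out.append(arr)
        elif arr.dtype == np.uint16:
            if rescale_policy == "divide256":
                out.append((arr // 256).astype(np.uint8))
            else:
                raise ConfigError(
                    "16-bit input requires config key 'rescale_policy: divide256' "
                    f"(expected {expected_bits}-bit data)"
                )
        else:
            raise InvalidParameterError(f"unsupported image dtype {arr.dtype}")
    return out, meta


def write_image_stack(path, images: list[np.ndarray], pixel_size: float, extra: dict | None = None) -> None:
    """Write a multi-page TIFF plus a JSON sidecar with calibration/provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stack = np.stack([np.asarray(im) for im in images])
    tifffile.imwrite(path, stack)
    side = {"pixel_size_um": float(pixel_size), **provenance(), **(extra or {})}
    atomic_write_json(path.with_name(path.name + ".json"), side)


# ---------------------------------------------------------------------------
# curves and histograms


def write_curve_csv(path, curve: CorrelationCurve, meta: dict | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame({"r_um": curve.r, "C": curve.C})
    if curve.sem is not None:
        df["sem"] = curve.sem
    _atomic_bytes(path, df.to_csv(index=False).encode())
    atomic_write_json(
        path.with_name(path.name + ".json"),
        {"n_replicates": curve.n_replicates, **provenance(), **(meta or {})},
    )


def read_curve_csv(path) -> CorrelationCurve:
    df = pd.read_csv(path)
    sem = df["sem"].to_numpy() if "sem" in df else None
    n_rep = 1
    sidecar = Path(path).with_name(Path(path).name + ".json")
    if sidecar.exists():
        n_rep = int(json.loads(sidecar.read_text()).get("n_replicates", 1))
    return CorrelationCurve(r=df["r_um"].to_numpy(), C=df["C"].to_numpy(), sem=sem, n_replicates=n_rep)


def write_histogram_csv(path, hist: IntensityHistogram, meta: dict | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame({"level": hist.levels, "count": hist.counts})
    _atomic_bytes(path, df.to_csv(index=False).encode())
    atomic_write_json(
        path.with_name(path.name + ".json"),
        {"n_pixels": hist.n_pixels, **provenance(), **(meta or {})},
    )


def read_histogram_csv(path) -> IntensityHistogram:
    df = pd.read_csv(path)
    return IntensityHistogram(counts=df["count"].to_numpy(), levels=df["level"].to_numpy())


# ---------------------------------------------------------------------------
# configuration


def config_from_dict(cls, data: dict):
    """Build a dataclass from a nested dict with strict key validation."""
    if not dataclasses.is_dataclass(cls):
        raise TypeError(f"{cls} is not a dataclass")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        target = ftype if dataclasses.is_dataclass(ftype) else None
        if target is None and isinstance(ftype, str):
            # resolve string annotations against the package namespace
            import gelstruct

            target = getattr(gelstruct, ftype, None)
            if not dataclasses.is_dataclass(target):
                target = None
        if target is not None and isinstance(value, dict):
            kwargs[name] = config_from_dict(target, value)
        elif isinstance(value, list):
            kwargs[name] = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path) -> dict:
    """Load a YAML config file as a plain dict."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping")
    return data
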