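"""File formats, run configuration, and provenance.

Images travel as multi-page TIFF (16-bit for acquisition-like stacks,
32-bit float for wavefronts and ratio maps, voxel size in the resolution
tags), tables as CSV, configuration as YAML (JSON is valid YAML and is
accepted).  A run is reproducible from its config + seed alone; the
provenance manifest records input hashes, the seed, and the package
version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import ImageStack, ImagingConfig
from .psf import OpticalConfig, PSF
from .zernike import PupilGrid, Wavefront, ZernikeCoeffs

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "save_provenance",
    "write_stack",
    "read_stack",
    "write_wavefront",
    "read_wavefront",
    "write_coeffs",
    "read_coeffs",
]


class ConfigError(ValueError):
    """Malformed run configuration."""


@dataclass(frozen=True)
class EyeConfigBlock:
    seed: int = 0
    rms_min_um: float = 0.45
    rms_max_um: float = 0.75
    field_amp_rel: float = 1.2
    field_corr_um: float = 200.0
    fov_um: float = 580.0


@dataclass(frozen=True)
class SensingConfigBlock:
    area_side_um: float = 19.0
    n_across: int = 16
    photons: float = 0.0


@dataclass(frozen=True)
class SweepConfigBlock:
    amp_min_um: float = -0.1
    amp_max_um: float = 0.1
    amp_step_um: float = 0.02


@dataclass(frozen=True)
class MetricsConfigBlock:
    smoothing_sigma_px: float = 1.0
    radial_bin_um: float = 5.0
    dff_percentile: float = 10.0


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of a simulated experiment."""

    seed: int = 0
    out_dir: str = "retao_out"
    optical: OpticalConfig = field(default_factory=OpticalConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    eye: EyeConfigBlock = field(default_factory=EyeConfigBlock)
    sensing: SensingConfigBlock = field(default_factory=SensingConfigBlock)
    sweep: SweepConfigBlock = field(default_factory=SweepConfigBlock)
    metrics: MetricsConfigBlock = field(default_factory=MetricsConfigBlock)

    def to_dict(self) -> dict:
        return asdict(self)


_BLOCK_TYPES = {
    "optical": OpticalConfig,
    "imaging": ImagingConfig,
    "eye": EyeConfigBlock,
    "sensing": SensingConfigBlock,
    "sweep": SweepConfigBlock,
    "metrics": MetricsConfigBlock,
}


def _build_block(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in '{where}': {sorted(unknown)}")
    # YAML lists for tuple-typed fields
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**coerced)


def load_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Load a RunConfig from YAML/JSON, filling defaults, rejecting unknown keys."""
    if data is None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    top_known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for key, val in data.items():
        if key in _BLOCK_TYPES:
            if not isinstance(val, dict):
                raise ConfigError(f"'{key}' must be a mapping")
            kwargs[key] = _build_block(_BLOCK_TYPES[key], val, key)
        else:
            kwargs[key] = val
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_jsonable(cfg.to_dict()), sort_keys=False))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def save_provenance(out_dir: str | Path, cfg: RunConfig | None = None, extra: dict | None = None) -> dict:
    """Write a manifest of every file in out_dir with hashes, seed, version."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": cfg.seed if cfg is not None else None,
        "config": _jsonable(cfg.to_dict()) if cfg is not None else None,
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    if extra:
        manifest.update(_jsonable(extra))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ------------------------------------------------------------------- images


def write_stack(stack: ImageStack, path: str | Path, dtype=np.uint16) -> None:
    """Write an image stack as multi-page TIFF with µm resolution tags."""
    data = stack.data
    if np.issubdtype(dtype, np.integer):
        peak = data.max()
        scale = (np.iinfo(dtype).max / peak) if peak > 0 else 1.0
        data = (data * scale).astype(dtype)
    else:
        data = data.astype(dtype)
    tifffile.imwrite(
        str(path),
        data,
        resolution=(1.0 / stack.px_um, 1.0 / stack.px_um),
        metadata={"spacing": stack.dz_um, "unit": "um", "provenance": _jsonable(stack.provenance)},
    )


def read_stack(path: str | Path) -> ImageStack:
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray().astype(float)
        px_um, dz_um = 1.0, 1.0
        page = tf.pages[0]
        res = page.tags.get("XResolution")
        if res is not None:
            num, den = res.value
            if num:
                px_um = den / num
        meta = tf.imagej_metadata or tf.shaped_metadata
        if isinstance(meta, (list, tuple)) and meta:
            meta = meta[0]
        if isinstance(meta, dict) and "spacing" in meta:
            dz_um = float(meta["spacing"])
    if data.ndim == 2:
        data = data[None]
    return ImageStack(data, px_um, dz_um, {"source": str(path)})


def write_wavefront(w: Wavefront, path: str | Path) -> None:
    """Single-plane 32-bit float TIFF in µm units (NaN outside the pupil)."""
    out = np.where(w.grid.mask, w.phase, np.nan).astype(np.float32)
    tifffile.imwrite(str(path), out)


def read_wavefront(path: str | Path) -> Wavefront:
    data = tifffile.imread(str(path)).astype(float)
    grid = PupilGrid(data.shape[0])
    return Wavefront(grid, np.nan_to_num(data))


def write_psf(p: PSF, path: str | Path) -> None:
    tifffile.imwrite(
        str(path),
        p.intensity.astype(np.float32),
        resolution=(1.0 / p.voxel_um[0], 1.0 / p.voxel_um[1]),
        metadata={"spacing": p.voxel_um[2], "unit": "um"},
    )


# ------------------------------------------------------------------- tables


def write_coeffs(c: ZernikeCoeffs, path: str | Path) -> None:
    pd.DataFrame(
        {"noll_index": np.arange(1, c.n_modes + 1), "amp_um_rms": c.coeffs}
    ).to_csv(path, index=False)


def read_coeffs(path: str | Path) -> ZernikeCoeffs:
    df = pd.read_csv(path)
    n = int(df["noll_index"].max())
    coeffs = np.zeros(n)
    coeffs[df["noll_index"].to_numpy() - 1] = df["amp_um_rms"].to_numpy()
    return ZernikeCoeffs(coeffs)
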