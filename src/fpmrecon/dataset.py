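"""Dataset containers on disk.

A dataset is one directory holding:

* ``stack.tif``       — the LR intensity stack as multi-page float TIFF;
* ``wavevectors.tsv`` — per-capture (fx, fy) in cycles/um, full precision;
* ``metadata.yaml``   — optics, LED geometry, pupil radius, capture ordering,
  degradation provenance and RNG seed, with explicit units;
* optionally ``truth_amplitude.tif`` / ``truth_phase.tif`` — the HR ground
  truth as float TIFFs.

Reconstruction results are written the same way (amplitude/phase/spectrum
TIFFs plus a per-iteration ``history.csv``).
"""

from __future__ import annotations

import dataclasses
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .degrade import DegradationSpec
from .fixtures import FixtureSet
from .optics import CaptureStack, LEDGeometry, OpticalConfig, pupil_mask
from .recon import ReconResult

try:
    _VERSION = version("fpmrecon")
except PackageNotFoundError:  # pragma: no cover - running from a source tree
    _VERSION = "unknown"


def _optics_meta(optics: OpticalConfig) -> dict:
    return {
        "na_objective": optics.na_objective,
        "wavelength_um": optics.wavelength_um,
        "pixel_size_lr_um": optics.pixel_size_lr_um,
        "n_hr": optics.n_hr,
        "n_lr": optics.n_lr,
    }


def _geometry_meta(geometry: LEDGeometry) -> dict:
    return {
        "rows": geometry.rows,
        "cols": geometry.cols,
        "pitch_mm": geometry.pitch_mm,
        "height_mm": geometry.height_mm,
        "center_offset_mm": list(geometry.center_offset_mm),
    }


def save_dataset(
    out_dir: str | Path,
    stack: CaptureStack,
    optics: OpticalConfig,
    geometry: LEDGeometry | None = None,
    truth_field: np.ndarray | None = None,
    degradation: DegradationSpec | None = None,
    seed: int | None = None,
    dtype: str = "float32",
) -> Path:
    """Write a capture stack (and optional truth) as a dataset directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "stack.tif", stack.images.astype(dtype))
    np.savetxt(
        out / "wavevectors.tsv",
        stack.wavevectors,
        fmt="%.17g",
        delimiter="\t",
        header="fx_cyc_per_um\tfy_cyc_per_um",
    )
    meta: dict = {
        "format": "fpmrecon-dataset-v1",
        "software_version": _VERSION,
        "optics": _optics_meta(optics),
        "pupil_radius_px": float(pupil_mask(optics).radius_px),
        "stack_dtype": dtype,
        "units": {"lengths": "um (optics) / mm (geometry)", "frequency": "cycles/um"},
    }
    if geometry is not None:
        meta["led_geometry"] = _geometry_meta(geometry)
    if stack.ordering is not None:
        meta["ordering_led_row_col"] = np.asarray(stack.ordering).tolist()
    if degradation is not None:
        meta["degradation"] = dataclasses.asdict(degradation)
    if seed is not None:
        meta["seed"] = int(seed)
    if truth_field is not None:
        tifffile.imwrite(out / "truth_amplitude.tif", np.abs(truth_field).astype("float64"))
        tifffile.imwrite(out / "truth_phase.tif", np.angle(truth_field).astype("float64"))
        meta["has_truth"] = True
    with open(out / "metadata.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return out


@dataclasses.dataclass
class Dataset:
    """In-memory view of a dataset directory."""

    stack: CaptureStack
    optics: OpticalConfig
    geometry: LEDGeometry | None
    truth_field: np.ndarray | None
    meta: dict


def load_dataset(path: str | Path) -> Dataset:
    """Load a dataset directory written by :func:`save_dataset`."""
    path = Path(path)
    with open(path / "metadata.yaml") as fh:
        meta = yaml.safe_load(fh)
    o = meta["optics"]
    optics = OpticalConfig(
        na_objective=o["na_objective"],
        wavelength_um=o["wavelength_um"],
        pixel_size_lr_um=o["pixel_size_lr_um"],
        n_hr=int(o["n_hr"]),
        n_lr=int(o["n_lr"]),
    )
    images = np.asarray(tifffile.imread(path / "stack.tif"))
    if images.ndim == 2:
        images = images[None]
    wv = np.loadtxt(path / "wavevectors.tsv", delimiter="\t", ndmin=2)
    ordering = meta.get("ordering_led_row_col")
    stack = CaptureStack(
        images=images.astype(float),
        wavevectors=wv,
        pupil=pupil_mask(optics),
        ordering=None if ordering is None else np.asarray(ordering),
    )
    geometry = None
    if "led_geometry" in meta:
        g = meta["led_geometry"]
        geometry = LEDGeometry(
            rows=int(g["rows"]),
            cols=int(g["cols"]),
            pitch_mm=g["pitch_mm"],
            height_mm=g["height_mm"],
            center_offset_mm=tuple(g.get("center_offset_mm", (0.0, 0.0))),
        )
    truth = None
    if (path / "truth_amplitude.tif").exists():
        amp = np.asarray(tifffile.imread(path / "truth_amplitude.tif"), dtype=float)
        pha = np.asarray(tifffile.imread(path / "truth_phase.tif"), dtype=float)
        truth = amp * np.exp(1j * pha)
    return Dataset(stack=stack, optics=optics, geometry=geometry, truth_field=truth, meta=meta)


def save_fixture(out_dir: str | Path, fixture: FixtureSet, with_truth: bool = True) -> Path:
    """Persist a :class:`FixtureSet` as a dataset directory."""
    return save_dataset(
        out_dir,
        fixture.stack,
        fixture.optics,
        geometry=fixture.geometry,
        truth_field=fixture.truth_field if with_truth else None,
        degradation=fixture.degradation,
        seed=fixture.seed,
    )


def save_recon(out_dir: str | Path, result: ReconResult) -> Path:
    """Write a reconstruction: amplitude/phase TIFFs, the complex spectrum
    (real and imaginary float TIFFs) and the per-iteration history CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "amplitude.tif", result.amplitude.astype("float64"))
    tifffile.imwrite(out / "phase.tif", result.phase.astype("float64"))
    tifffile.imwrite(out / "spectrum_real.tif", result.spectrum.real.astype("float64"))
    tifffile.imwrite(out / "spectrum_imag.tif", result.spectrum.imag.astype("float64"))
    result.history.to_csv(out / "history.csv", index=False)
    with open(out / "recon.yaml", "w") as fh:
        yaml.safe_dump(
            {"algorithm": result.algorithm, "params": result.params, "software_version": _VERSION},
            fh,
            sort_keys=False,
        )
    return out


def load_recon_spectrum(path: str | Path) -> np.ndarray:
    path = Path(path)
    re = np.asarray(tifffile.imread(path / "spectrum_real.tif"), dtype=float)
    im = np.asarray(tifffile.imread(path / "spectrum_imag.tif"), dtype=float)
    return re + 1j * im
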