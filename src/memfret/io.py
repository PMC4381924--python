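"""File formats: TIFF image sets with JSON sidecars, CSV tables, JSON results.

Images travel as plain multi-page TIFF (one page per channel or wavelength
plane) with a JSON sidecar carrying the optics parameters and, for
synthetic data, the ground truth. Tables are CSV with documented headers;
results are JSON. Schema violations raise ``SchemaError`` naming the
offending columns.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from .dimer import BinnedFretPoint, DimerFitResult
from .photophysics import FluorophorePair
from .spectral import HistogramFit
from .synthetic import (KineticsDataset, OpticsParams, SceneParams,
                        SpectralImage, VesicleGroundTruth, VesicleImageSet)


class SchemaError(ValueError):
    """A table does not match its declared schema."""


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def read_table(path: str | Path, required_columns: list[str],
               numeric_columns: list[str] | None = None) -> pd.DataFrame:
    """CSV reader with schema validation.

    Raises :class:`SchemaError` naming missing columns and non-numeric
    cells (with their line numbers).
    """
    frame = pd.read_csv(path)
    missing = [c for c in required_columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col in numeric_columns or []:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]  # 1-based + header
            raise SchemaError(
                f"{path}: non-numeric values in column '{col}' at lines "
                f"{lines}")
        frame[col] = coerced
    return frame


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Image sets
# ---------------------------------------------------------------------------


def _optics_to_dict(optics: OpticsParams) -> dict:
    return dataclasses.asdict(optics)


def _scene_params_to_dict(params: SceneParams) -> dict:
    return dataclasses.asdict(params)


def write_vesicle_images(images: VesicleImageSet, tiff_path: str | Path
                         ) -> None:
    """3-page TIFF (donor, acceptor, FRET) + JSON sidecar (.json)."""
    tiff_path = Path(tiff_path)
    tiff_path.parent.mkdir(parents=True, exist_ok=True)
    stack = np.stack([images.donor_scan, images.acceptor_scan,
                      images.fret_scan]).astype(np.float32)
    tifffile.imwrite(tiff_path, stack, photometric='minisblack')
    sidecar: dict[str, Any] = {
        "channels": ["donor", "acceptor", "fret"],
        "optics": _optics_to_dict(images.optics),
    }
    if images.ground_truth is not None:
        gt = images.ground_truth
        sidecar["ground_truth"] = {
            "mean_Eapp": gt.mean_Eapp, "sigma_D": gt.sigma_D,
            "sigma_A": gt.sigma_A, "dimer_fraction": gt.dimer_fraction,
            "scene_params": _scene_params_to_dict(gt.scene_params),
        }
    tiff_path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_vesicle_images(tiff_path: str | Path, pair: FluorophorePair
                        ) -> VesicleImageSet:
    tiff_path = Path(tiff_path)
    stack = tifffile.imread(tiff_path).astype(float)
    sidecar = json.loads(tiff_path.with_suffix(".json").read_text())
    od = sidecar["optics"]
    od["image_shape"] = tuple(od["image_shape"])
    if od.get("vesicle_center") is not None:
        od["vesicle_center"] = tuple(od["vesicle_center"])
    optics = OpticsParams(**od)
    gt = None
    if "ground_truth" in sidecar:
        g = sidecar["ground_truth"]
        gt = VesicleGroundTruth(
            mean_Eapp=g["mean_Eapp"], sigma_D=g["sigma_D"],
            sigma_A=g["sigma_A"], dimer_fraction=g["dimer_fraction"],
            scene_params=SceneParams(**g["scene_params"]))
    return VesicleImageSet(donor_scan=stack[0], acceptor_scan=stack[1],
                           fret_scan=stack[2], optics=optics, pair=pair,
                           ground_truth=gt)


def write_spectral_image(image: SpectralImage, tiff_path: str | Path) -> None:
    """Multi-page TIFF (one page per wavelength) + JSON sidecar."""
    tiff_path = Path(tiff_path)
    tiff_path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(tiff_path, image.stack.astype(np.float32),
                     photometric='minisblack')
    sidecar: dict[str, Any] = {
        "wavelengths_nm": image.wavelengths.tolist(),
        "excitation": image.excitation,
    }
    tiff_path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_spectral_image(tiff_path: str | Path) -> SpectralImage:
    tiff_path = Path(tiff_path)
    stack = tifffile.imread(tiff_path).astype(float)
    sidecar = json.loads(tiff_path.with_suffix(".json").read_text())
    return SpectralImage(stack=stack,
                         wavelengths=np.asarray(sidecar["wavelengths_nm"]),
                         excitation=sidecar["excitation"])


# ---------------------------------------------------------------------------
# Results JSON
# ---------------------------------------------------------------------------


def binned_points_to_frame(points: list[BinnedFretPoint]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(p) for p in points])


def dimer_fit_to_dict(fit: DimerFitResult) -> dict:
    d = dataclasses.asdict(fit)
    d["flags"] = list(fit.flags)
    return d


def histogram_fit_to_dict(fit: HistogramFit) -> dict:
    d = dataclasses.asdict(fit)
    d["peaks"] = list(fit.peaks)
    d["widths"] = list(fit.widths)
    d["weights"] = list(fit.weights)
    d["bounds"] = list(fit.bounds)
    d["flags"] = list(fit.flags)
    return d


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default))


def _json_default(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"not JSON serializable: {type(value)}")


def read_kinetics_csv(path: str | Path, enzyme_nM: float,
                      cosubstrate_uM: float | None = None) -> KineticsDataset:
    frame = read_table(path, ["substrate_uM", "replicate",
                              "velocity_nM_per_min"],
                       ["substrate_uM", "velocity_nM_per_min"])
    return KineticsDataset.from_frame(frame, enzyme_conc=enzyme_nM,
                                      cosubstrate=cosubstrate_uM)
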