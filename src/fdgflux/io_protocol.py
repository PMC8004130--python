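"""External artifacts: dynamic PET volumes, ROI label maps, serum tables,
acquisition-protocol configs and result exports.

All images travel as NIfTI-1; frame timing lives in a separate two-column
CSV because the NIfTI header has no reliable per-frame timing slot.  The
internal unit system is fixed: activity concentrations in kBq/mL, times in
minutes, glucose in mg/dL at the boundary (converted downstream).  Images
are assumed decay-corrected to scan start by the reconstruction; the
pipeline applies no further decay handling and records that assumption in
every run manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FdgFluxError",
    "ValidationError",
    "FormatError",
    "ConsistencyError",
    "FitError",
    "ROI_LABELS",
    "FrameTiming",
    "DynamicImage",
    "RoiMask",
    "SerumSeries",
    "AcquisitionProtocol",
    "read_dynamic_pet",
    "write_dynamic_pet",
    "read_masks",
    "write_masks",
    "read_serum",
    "write_serum",
    "read_timing",
    "write_timing",
    "read_tacs",
    "write_tacs",
    "read_protocol",
    "write_protocol",
    "write_results",
    "read_results_json",
    "write_manifest",
]


class FdgFluxError(Exception):
    """Base class for pipeline errors."""


class ValidationError(FdgFluxError, ValueError):
    """A domain-type invariant is violated."""


class FormatError(FdgFluxError):
    """A file is not in the expected format."""


class ConsistencyError(FdgFluxError):
    """Two artifacts that must agree do not."""


class FitError(FdgFluxError):
    """Model fitting failed or was refused."""


ROI_LABELS = ("myocardium", "blood_pool", "skeletal_muscle")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameTiming:
    """Per-frame start times and durations, minutes since infusion start."""

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        if start.ndim != 1 or start.shape != dur.shape:
            raise ValidationError("frame_start and frame_duration must be equal-length 1-D arrays")
        if start.size == 0:
            raise ValidationError("timing must contain at least one frame")
        if np.any(dur <= 0):
            raise ValidationError("all frame durations must be > 0")
        if np.any(np.diff(start) <= 0):
            raise ValidationError("frame starts must be strictly increasing")
        if np.any(start[1:] < start[:-1] + dur[:-1] - 1e-9):
            raise ValidationError("frames must not overlap")

    def __len__(self) -> int:
        return int(self.frame_start.size)

    @property
    def frame_mid(self) -> np.ndarray:
        return self.frame_start + self.frame_duration / 2.0

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @classmethod
    def uniform(cls, n_frames: int = 60, duration: float = 1.0) -> "FrameTiming":
        """n equal frames of ``duration`` minutes starting at 0."""
        starts = np.arange(n_frames) * duration
        return cls(starts, np.full(n_frames, float(duration)))


@dataclass(frozen=True)
class DynamicImage:
    """4-D dynamic PET volume (x, y, z, frame), activity in kBq/mL."""

    data: np.ndarray
    voxel_size: tuple
    timing: FrameTiming

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        if data.ndim != 4:
            raise ValidationError(f"dynamic image must be 4-D, got {data.ndim}-D")
        if data.shape[3] != len(self.timing):
            raise ConsistencyError(
                f"image has {data.shape[3]} frames but timing lists {len(self.timing)}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValidationError(f"voxel sizes must be 3 positive values, got {self.voxel_size}")
        if not np.all(np.isfinite(data)):
            raise ValidationError("image contains non-finite voxel values")

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]


@dataclass(frozen=True)
class RoiMask:
    """Boolean ROI mask aligned to a DynamicImage's spatial grid."""

    label: str
    voxels: np.ndarray

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=bool)
        object.__setattr__(self, "voxels", vox)
        if self.label not in ROI_LABELS:
            raise ValidationError(f"unknown ROI label {self.label!r}; expected one of {ROI_LABELS}")
        if vox.ndim != 3:
            raise ValidationError(f"mask must be 3-D, got {vox.ndim}-D")
        if not vox.any():
            raise ValidationError(f"mask for {self.label!r} contains no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass(frozen=True)
class SerumSeries:
    """Serum samples over the scan: time (min), glucose (mg/dL), lactate (mmol/L)."""

    sample_time: np.ndarray
    glucose: np.ndarray
    lactate: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_time, dtype=float)
        g = np.asarray(self.glucose, dtype=float)
        order = np.argsort(t, kind="stable")
        t, g = t[order], g[order]
        lac = self.lactate
        if lac is not None:
            lac = np.asarray(lac, dtype=float)[order]
        object.__setattr__(self, "sample_time", t)
        object.__setattr__(self, "glucose", g)
        object.__setattr__(self, "lactate", lac)
        if t.ndim != 1 or t.shape != g.shape:
            raise ValidationError("sample_time and glucose must be equal-length 1-D arrays")
        if t.size and t[0] < 0:
            raise ValidationError("sample times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("sample times must be distinct")
        ok = np.isfinite(g)
        if np.any(g[ok] <= 0):
            raise ValidationError("glucose values must be > 0")


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Constant-infusion FDG protocol with a mid-scan gas switch.

    Defaults follow the clinical protocol the pipeline targets: 10 mCi FDG
    infused at 0.01 mL/s for 60 min after an 8 mL line-priming bolus; room
    air (21% O2) for the first 15 min, then 12% O2 for the remainder.  The
    normoxia fit window covers the pre-switch phase; the hypoxia window
    starts after a wash-in period once arterial saturation has fallen.
    """

    infusion_rate: float = 0.01          # mL/s
    total_activity: float = 10.0         # mCi
    bolus_volume: float = 8.0            # mL
    gas_switch_time: float = 15.0        # min
    scan_duration: float = 60.0          # min
    normoxia_fit_window: tuple = (0.0, 15.0)
    hypoxia_fit_window: tuple = (25.0, 60.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "normoxia_fit_window", tuple(map(float, self.normoxia_fit_window)))
        object.__setattr__(self, "hypoxia_fit_window", tuple(map(float, self.hypoxia_fit_window)))
        for name in ("infusion_rate", "total_activity", "bolus_volume",
                     "gas_switch_time", "scan_duration"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("normoxia_fit_window", "hypoxia_fit_window"):
            t0, t1 = getattr(self, name)
            if not (0 <= t0 < t1 <= self.scan_duration + 1e-9):
                raise ValidationError(
                    f"{name} must satisfy 0 <= t0 < t1 <= scan_duration, got {(t0, t1)}")
        if self.normoxia_fit_window[1] > self.gas_switch_time + 1e-9:
            raise ValidationError("normoxia window must end at or before the gas switch")
        if self.hypoxia_fit_window[0] < self.gas_switch_time - 1e-9:
            raise ValidationError("hypoxia window must start at or after the gas switch")

    def window(self, condition: str) -> tuple:
        if condition == "normoxia":
            return self.normoxia_fit_window
        if condition == "hypoxia":
            return self.hypoxia_fit_window
        raise ValidationError(f"unknown condition {condition!r}")


# ---------------------------------------------------------------------------
# Timing and image I/O
# ---------------------------------------------------------------------------

def read_timing(path) -> FrameTiming:
    """Read a 2-column frame-timing CSV (start_min, duration_min)."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    start_col = cols.get("frame_start_min") or cols.get("start") or df.columns[0]
    dur_col = cols.get("frame_duration_min") or cols.get("duration") or df.columns[1]
    return FrameTiming(df[start_col].to_numpy(float), df[dur_col].to_numpy(float))


def write_timing(timing: FrameTiming, path) -> None:
    pd.DataFrame({
        "frame_start_min": timing.frame_start,
        "frame_duration_min": timing.frame_duration,
    }).to_csv(path, index=False)


def read_dynamic_pet(image_path, timing_path) -> DynamicImage:
    """Load a 4-D NIfTI dynamic PET volume plus its frame-timing table.

    Voxel values are taken as kBq/mL as stored (after the container's scale
    slope, which nibabel applies); frames are never reordered.
    """
    img = nib.load(str(image_path))
    if img.ndim != 4:
        raise FormatError(f"{image_path}: expected a 4-D dynamic volume, got {img.ndim}-D")
    timing = read_timing(timing_path)
    if img.shape[3] != len(timing):
        raise ConsistencyError(
            f"{image_path} has {img.shape[3]} frames but {timing_path} lists {len(timing)}")
    data = np.asarray(img.get_fdata(dtype=np.float64))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DynamicImage(data, voxel_size, timing)


def write_dynamic_pet(image: DynamicImage, image_path, timing_path=None) -> None:
    affine = np.diag(list(image.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(image.data.astype(np.float32), affine), str(image_path))
    if timing_path is not None:
        write_timing(image.timing, timing_path)


def read_masks(path, labelmap: Dict[str, int],
               reference: Optional[DynamicImage] = None) -> List[RoiMask]:
    """Read an integer label volume and split it into boolean ROI masks.

    ``labelmap`` maps ROI names (myocardium, blood_pool, skeletal_muscle) to
    the integer values used in the volume.
    """
    img = nib.load(str(path))
    if img.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D label volume, got {img.ndim}-D")
    vol = np.asarray(img.get_fdata()).round().astype(int)
    if reference is not None and vol.shape != reference.spatial_shape:
        raise ConsistencyError(
            f"label volume shape {vol.shape} does not match image grid {reference.spatial_shape}")
    masks = []
    for name, value in labelmap.items():
        sel = vol == int(value)
        if not sel.any():
            raise ValidationError(f"label {value} ({name}) is absent from {path}")
        masks.append(RoiMask(name, sel))
    return masks


def write_masks(masks: Sequence[RoiMask], labelmap: Dict[str, int], path,
                voxel_size=(1.0, 1.0, 1.0)) -> None:
    shape = masks[0].voxels.shape
    vol = np.zeros(shape, dtype=np.int16)
    for m in masks:
        vol[m.voxels] = labelmap[m.label]
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(vol, affine), str(path))


# ---------------------------------------------------------------------------
# Serum and TAC tables
# ---------------------------------------------------------------------------

def read_serum(path) -> SerumSeries:
    """Read a serum CSV with columns time_min, glucose_mg_dl[, lactate_mmol_l]."""
    df = pd.read_csv(path)
    for col in ("time_min", "glucose_mg_dl"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    lactate = df["lactate_mmol_l"].to_numpy(float) if "lactate_mmol_l" in df.columns else None
    return SerumSeries(df["time_min"].to_numpy(float),
                       df["glucose_mg_dl"].to_numpy(float), lactate)


def write_serum(serum: SerumSeries, path) -> None:
    cols = {"time_min": serum.sample_time, "glucose_mg_dl": serum.glucose}
    if serum.lactate is not None:
        cols["lactate_mmol_l"] = serum.lactate
    pd.DataFrame(cols).to_csv(path, index=False)


def write_tacs(tacs, path) -> None:
    """Write TACs in the pipeline dialect: roi, frame_start_min,
    frame_duration_min, activity_kbq_ml (one row per ROI per frame)."""
    rows = []
    for tac in tacs:
        start = tac.frame_mid - tac.frame_duration / 2.0
        for s, d, a in zip(start, tac.frame_duration, tac.activity):
            rows.append({"roi": tac.roi_label, "frame_start_min": s,
                         "frame_duration_min": d, "activity_kbq_ml": a})
    pd.DataFrame(rows, columns=["roi", "frame_start_min", "frame_duration_min",
                                "activity_kbq_ml"]).to_csv(path, index=False)


def read_tacs(path) -> dict:
    """Read the TAC CSV dialect back into {roi: TimeActivityCurve}."""
    from .tac_extraction import TimeActivityCurve

    df = pd.read_csv(path)
    needed = {"roi", "frame_start_min", "frame_duration_min", "activity_kbq_ml"}
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing TAC columns {sorted(missing)}")
    out = {}
    for roi, grp in df.groupby("roi", sort=False):
        grp = grp.sort_values("frame_start_min")
        start = grp["frame_start_min"].to_numpy(float)
        dur = grp["frame_duration_min"].to_numpy(float)
        out[str(roi)] = TimeActivityCurve(
            roi_label=str(roi), frame_mid=start + dur / 2.0, frame_duration=dur,
            activity=grp["activity_kbq_ml"].to_numpy(float),
            n_voxels=int(grp["n_voxels"].iloc[0]) if "n_voxels" in grp else 1)
    return out


# ---------------------------------------------------------------------------
# Protocol config
# ---------------------------------------------------------------------------

_PROTOCOL_FIELDS = ("infusion_rate", "total_activity", "bolus_volume",
                    "gas_switch_time", "scan_duration",
                    "normoxia_fit_window", "hypoxia_fit_window")


def read_protocol(path) -> AcquisitionProtocol:
    """Read a flat key-value YAML protocol config; missing keys keep defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: protocol config must be a key-value mapping")
    kwargs = {k: raw[k] for k in _PROTOCOL_FIELDS if k in raw}
    return AcquisitionProtocol(**kwargs)


def write_protocol(protocol: AcquisitionProtocol, path) -> None:
    data = {k: getattr(protocol, k) for k in _PROTOCOL_FIELDS}
    data["normoxia_fit_window"] = list(protocol.normoxia_fit_window)
    data["hypoxia_fit_window"] = list(protocol.hypoxia_fit_window)
    data["units"] = {"activity": "kBq/mL", "time": "min"}
    data["decay_correction"] = "assumed decay-corrected to scan start by reconstruction"
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Results export
# ---------------------------------------------------------------------------

def _result_row(res, subject_id="", group="") -> dict:
    return {
        "subject": subject_id,
        "group": group,
        "tissue": res.tissue,
        "condition": res.condition,
        "Ki": res.ki,
        "rate": res.rate,
        "LC": res.lc.value,
        "SSE": res.fit.sse,
        "converged": res.fit.converged,
    }


def write_results(results, path, subject_id: str = "", group: str = "") -> None:
    """Write metabolic-rate results as a long-format CSV plus a JSON sidecar.

    The CSV (one row per tissue x condition) is the interface to external
    statistics tools; the sidecar holds full fit detail — parameters,
    bounds, seeds and residuals — for exact reconstruction.
    """
    path = Path(path)
    rows = [_result_row(r, subject_id, group) for r in results]
    df = pd.DataFrame(rows, columns=["subject", "group", "tissue", "condition",
                                     "Ki", "rate", "LC", "SSE", "converged"])
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    payload = {
        "subject": subject_id,
        "group": group,
        "results": [r.to_dict() for r in results],
    }
    with open(sidecar, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_results_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_manifest(path, **entries) -> None:
    """Record run parameters (seed, config, assumptions) as a JSON manifest."""
    payload = {
        "units": {"activity": "kBq/mL", "time": "min", "glucose": "mg/dL"},
        "decay_correction": "images assumed decay-corrected to scan start by reconstruction",
    }
    payload.update(entries)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
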