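"""Volume and table I/O.

Canonical on-disk formats are NIfTI-1 (``.nii``/``.nii.gz``) for SUV
volumes and binary tumor masks, and CSV for per-patient feature tables.
All downstream modules consume only the containers defined here.

Image orientation is deliberately ignored: every feature computed
downstream is orientation-averaged, so volumes are handled in scanner
voxel space with the header voxel sizes (mm) attached.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    EmptyRegionError,
    FormatError,
    SchemaError,
    TableParseError,
)

#: Reserved CSV column names; everything else is a feature column.
ID_COLUMN = "patient_id"
RESPONSE_COLUMN = "response"
TIME_COLUMN = "time_months"
EVENT_COLUMN = "event"
RESERVED_COLUMNS = (ID_COLUMN, RESPONSE_COLUMN, TIME_COLUMN, EVENT_COLUMN)


@dataclass(frozen=True)
class SUVolume:
    """A 3D PET volume in SUV units with per-axis voxel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3 or values.size == 0:
            raise FormatError("SUV volume must be a non-empty 3D grid")
        if np.any(values < 0):
            raise FormatError("SUV values must be non-negative")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError("voxel spacing must be three positive lengths (mm)")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class BinaryMask:
    """A binary tumor mask on the same grid as its paired :class:`SUVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3 or values.size == 0:
            raise FormatError("mask must be a non-empty 3D grid")
        if values.dtype != bool:
            unique = np.unique(values)
            if not np.all(np.isin(unique, (0, 1))):
                raise FormatError(
                    "mask must be strictly binary; fractional masks are rejected"
                )
            values = values > 0.5
        if not values.any():
            raise EmptyRegionError("mask selects no voxels")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError("voxel spacing must be three positive lengths (mm)")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class FeatureTable:
    """Patients x features matrix plus optional outcome columns.

    ``response`` is a binary treatment-response label (1 = complete
    response), ``time``/``event`` carry right-censored survival in months.
    Categorical clinical covariates must be numerically encoded upstream.
    """

    patient_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    response: np.ndarray | None = None
    time: np.ndarray | None = None
    event: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SchemaError("feature matrix must be 2D (patients x features)")
        n, p = self.values.shape
        if len(self.patient_ids) != n:
            raise SchemaError("patient_ids length must match matrix rows")
        if len(self.feature_names) != p:
            raise SchemaError("feature_names length must match matrix columns")
        if len(set(self.feature_names)) != p:
            raise SchemaError("duplicated feature names")
        if (self.time is None) != (self.event is None):
            raise SchemaError("time and event must be present together")
        for name in ("response", "time", "event"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (n,):
                    raise SchemaError(f"{name} must have one value per patient")
                setattr(self, name, arr)
        if self.time is not None and np.any(self.time < 0):
            raise SchemaError("survival times must be non-negative")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise SchemaError(f"unknown feature {name!r}") from None
        return self.values[:, j]

    def subset(self, names: list[str]) -> "FeatureTable":
        """Restrict to the named feature columns (outcomes preserved)."""
        unknown = [n for n in names if n not in self.feature_names]
        if unknown:
            raise SchemaError(f"unknown feature(s): {', '.join(unknown)}")
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(
            patient_ids=list(self.patient_ids),
            feature_names=list(names),
            values=self.values[:, idx].copy(),
            response=None if self.response is None else self.response.copy(),
            time=None if self.time is None else self.time.copy(),
            event=None if self.event is None else self.event.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, ID_COLUMN, self.patient_ids)
        if self.response is not None:
            df[RESPONSE_COLUMN] = self.response
        if self.time is not None:
            df[TIME_COLUMN] = self.time
            df[EVENT_COLUMN] = self.event
        return df


def _load_3d(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D image, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def read_volume_pair(
    volume_path: str | Path, mask_path: str | Path
) -> tuple[SUVolume, BinaryMask]:
    """Read an SUV volume and its tumor mask; shapes/spacings must match.

    No resampling is attempted: a mismatch is an :class:`AlignmentError`.
    """
    vol_data, vol_spacing = _load_3d(volume_path)
    mask_data, mask_spacing = _load_3d(mask_path)
    if vol_data.shape != mask_data.shape:
        raise AlignmentError(
            f"volume shape {vol_data.shape} != mask shape {mask_data.shape}"
        )
    if not np.allclose(vol_spacing, mask_spacing, rtol=1e-4):
        raise AlignmentError(
            f"volume spacing {vol_spacing} != mask spacing {mask_spacing}"
        )
    return SUVolume(vol_data, vol_spacing), BinaryMask(mask_data, vol_spacing)


def write_volume_pair(
    volume: SUVolume,
    mask: BinaryMask,
    volume_path: str | Path,
    mask_path: str | Path,
) -> None:
    """Write a volume/mask pair as NIfTI-1 with spacing in the header."""
    for arr, spacing, path in (
        (volume.values, volume.spacing, volume_path),
        (mask.values.astype(np.uint8), mask.spacing, mask_path),
    ):
        affine = np.diag(list(spacing) + [1.0])
        img = nib.Nifti1Image(np.asarray(arr), affine)
        img.header.set_zooms(spacing)
        nib.save(img, str(path))


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a CSV feature table (UTF-8, '.' decimal, header row).

    Columns named in :data:`RESERVED_COLUMNS` are mapped onto the
    corresponding ``FeatureTable`` fields; all other columns are numeric
    features. Missing outcome columns yield absent optional fields.
    """
    import csv

    with open(path, newline="", encoding="utf-8") as fh:
        cols = next(csv.reader(fh))
    if len(set(cols)) != len(cols):
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        raise SchemaError(f"repeated column name(s) in header: {dupes}")
    # round_trip parsing: written values must come back bit-identical
    df = pd.read_csv(path, dtype={ID_COLUMN: str}, float_precision="round_trip")
    if ID_COLUMN not in df.columns:
        raise SchemaError(f"missing required column {ID_COLUMN!r}")
    feature_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    values = np.empty((len(df), len(feature_cols)), dtype=float)
    for j, col in enumerate(feature_cols):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableParseError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, row {row}"
            )
        values[:, j] = converted.to_numpy(dtype=float)
    return FeatureTable(
        patient_ids=df[ID_COLUMN].astype(str).tolist(),
        feature_names=feature_cols,
        values=values,
        response=(
            df[RESPONSE_COLUMN].to_numpy(float) if RESPONSE_COLUMN in df else None
        ),
        time=df[TIME_COLUMN].to_numpy(float) if TIME_COLUMN in df else None,
        event=df[EVENT_COLUMN].to_numpy(float) if EVENT_COLUMN in df else None,
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV, preserving values to full precision."""
    table.to_frame().to_csv(path, index=False, float_format="%.17g")
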