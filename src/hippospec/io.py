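"""Data model and readers/writers for hyperspectral maps, masks, logs, manifests.

The canonical on-disk container for a hyperspectral map is HDF5 with three
members: ``absorbance`` (rows x cols x channels, float), ``wavenumbers``
(channels, cm^-1, strictly increasing) and scalar attributes (``animal_id``,
``group``, ``pixel_size_um``).  Layer masks are integer label images (plain
text grid, PNG or TIFF) with a JSON sidecar legend mapping label -> layer
name.  Seizure logs are tidy CSV, one row per animal-day.  A study manifest
is a CSV listing one map/mask/log triple per animal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

#: Canonical cellular-layer names of the hippocampal formation plus background.
LAYERS = ("GR", "PY", "MU", "MO")
BACKGROUND = "background"

LOG_COLUMNS = (
    "animal_id",
    "day",
    "clonic_intensity",
    "clonic_duration_s",
    "tonic_intensity",
    "tonic_duration_s",
)


class FormatError(ValueError):
    """A file does not conform to its documented schema."""


class ValidationError(ValueError):
    """An in-memory object violates an invariant."""


@dataclass
class SpectralMap:
    """Hyperspectral absorbance cube with a calibrated wavenumber axis.

    Parameters
    ----------
    absorbance
        Array of shape (rows, cols, channels), absorbance in AU.
    wavenumbers
        Strictly increasing axis in cm^-1, length = channels.
    animal_id, group
        Sample provenance; ``group`` is ``"K"`` (stimulated) or ``"N"``
        (control) in the two-group design.
    pixel_size_um
        Edge length of one pixel in micrometres (instrument spatial
        resolution; ~25 um for the mapping system emulated here).
    """

    absorbance: np.ndarray
    wavenumbers: np.ndarray
    animal_id: str = ""
    group: str = ""
    pixel_size_um: float = 25.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.absorbance.ndim != 3:
            raise ValidationError("absorbance cube must have 3 axes (row, col, channel)")
        if self.wavenumbers.ndim != 1:
            raise ValidationError("wavenumber axis must be 1-D")
        if self.absorbance.shape[2] != self.wavenumbers.size:
            raise ValidationError(
                f"channel mismatch: cube has {self.absorbance.shape[2]} channels, "
                f"axis has {self.wavenumbers.size}"
            )
        if self.wavenumbers.size >= 2:
            d = np.diff(self.wavenumbers)
            if np.any(d < 0):
                # accept a descending axis by re-sorting; flag in metadata
                if np.all(d < 0):
                    order = np.argsort(self.wavenumbers)
                    self.wavenumbers = self.wavenumbers[order]
                    self.absorbance = self.absorbance[:, :, order]
                    self.metadata["resorted_axis"] = True
                else:
                    raise FormatError("wavenumber axis is not monotonic")
            if np.any(np.diff(self.wavenumbers) == 0):
                raise FormatError("wavenumber axis contains duplicate values")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValidationError("absorbance cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.absorbance.shape[:2]


@dataclass
class LayerMask:
    """Integer label image assigning each pixel to a layer or background."""

    labels: np.ndarray
    legend: Mapping[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("mask must be a 2-D label image")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("mask labels must be integers")
        self.legend = {int(k): str(v) for k, v in dict(self.legend).items()}
        present = set(np.unique(self.labels).tolist())
        known = set(self.legend)
        orphans = sorted(present - known)
        if orphans:
            raise FormatError(f"mask labels missing from legend: {orphans}")

    def layer_label(self, layer: str) -> int:
        for k, v in self.legend.items():
            if v == layer:
                return k
        raise KeyError(f"layer {layer!r} absent from mask legend")

    def layer_pixels(self, layer: str) -> np.ndarray:
        """Boolean image of pixels carrying the given layer name."""
        return self.labels == self.layer_label(layer)


@dataclass
class SeizureLog:
    """Daily clonic/tonic seizure record for one animal.

    ``records`` is a DataFrame with columns day, clonic_intensity,
    clonic_duration_s, tonic_intensity, tonic_duration_s; one row per
    stimulation day (1..n_days).
    """

    animal_id: str
    records: pd.DataFrame
    n_days: int = 21

    def __post_init__(self) -> None:
        need = set(LOG_COLUMNS) - {"animal_id"}
        missing = need - set(self.records.columns)
        if missing:
            raise FormatError(f"seizure log missing columns: {sorted(missing)}")
        if len(self.records) != self.n_days:
            raise ValidationError(
                f"animal {self.animal_id}: log has {len(self.records)} days, "
                f"expected {self.n_days}"
            )
        r = self.records
        if (r["tonic_intensity"] < 0).any() or (r["tonic_intensity"] > 3).any():
            raise ValidationError(f"animal {self.animal_id}: tonic intensity outside 0..3")
        if (r[["clonic_duration_s", "tonic_duration_s"]] < 0).any().any():
            raise ValidationError(f"animal {self.animal_id}: negative seizure duration")
        if (r["clonic_intensity"] < 0).any():
            raise ValidationError(f"animal {self.animal_id}: negative clonic intensity")


@dataclass
class StudyManifest:
    """One row per animal: id, group and paths to its map/mask/log files."""

    entries: pd.DataFrame  # columns: animal_id, group, map, mask, log

    def __post_init__(self) -> None:
        need = {"animal_id", "group", "map", "mask", "log"}
        missing = need - set(self.entries.columns)
        if missing:
            raise FormatError(f"manifest missing columns: {sorted(missing)}")
        ids = self.entries["animal_id"]
        if ids.duplicated().any():
            dup = sorted(ids[ids.duplicated()].unique().tolist())
            raise ValidationError(f"duplicate animal ids in manifest: {dup}")

    @property
    def group_counts(self) -> dict[str, int]:
        return self.entries["group"].value_counts().to_dict()

    @property
    def n_samples(self) -> int:
        return len(self.entries)

    def animals(self, group: str | None = None) -> list[str]:
        df = self.entries
        if group is not None:
            df = df[df["group"] == group]
        return df["animal_id"].tolist()


# ---------------------------------------------------------------------------
# hyperspectral container


def write_map(smap: SpectralMap, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("absorbance", data=smap.absorbance)
        f.create_dataset("wavenumbers", data=smap.wavenumbers)
        f.attrs["animal_id"] = smap.animal_id
        f.attrs["group"] = smap.group
        f.attrs["pixel_size_um"] = smap.pixel_size_um


def read_map(path: str | Path) -> SpectralMap:
    with h5py.File(path, "r") as f:
        for name in ("absorbance", "wavenumbers"):
            if name not in f:
                raise FormatError(f"{path}: missing dataset {name!r}")
        cube = f["absorbance"][()]
        wn = f["wavenumbers"][()]
        attrs = dict(f.attrs)
    return SpectralMap(
        cube,
        wn,
        animal_id=str(attrs.get("animal_id", "")),
        group=str(attrs.get("group", "")),
        pixel_size_um=float(attrs.get("pixel_size_um", 25.0)),
    )


# ---------------------------------------------------------------------------
# masks


def write_mask(mask: LayerMask, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in {".txt", ".tsv"}:
        np.savetxt(path, mask.labels, fmt="%d")
    else:
        import imageio.v3 as iio

        iio.imwrite(path, mask.labels.astype(np.uint8))
    legend_path = path.with_suffix(path.suffix + ".legend.json")
    legend_path.write_text(json.dumps({str(k): v for k, v in mask.legend.items()}))


def read_mask(path: str | Path) -> LayerMask:
    path = Path(path)
    legend_path = path.with_suffix(path.suffix + ".legend.json")
    if not legend_path.exists():
        raise FormatError(f"mask legend sidecar not found: {legend_path}")
    legend = {int(k): v for k, v in json.loads(legend_path.read_text()).items()}
    if path.suffix in {".txt", ".tsv"}:
        labels = np.loadtxt(path, dtype=int, ndmin=2)
    else:
        import imageio.v3 as iio

        labels = np.asarray(iio.imread(path)).astype(int)
    return LayerMask(labels, legend)


# ---------------------------------------------------------------------------
# seizure logs


def write_logs(logs: Sequence[SeizureLog], path: str | Path) -> None:
    frames = []
    for log in logs:
        df = log.records.copy()
        df.insert(0, "animal_id", log.animal_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True)[list(LOG_COLUMNS)].to_csv(path, index=False)


def read_logs(path: str | Path, n_days: int = 21) -> list[SeizureLog]:
    df = pd.read_csv(path)
    missing = set(LOG_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: log table missing columns {sorted(missing)}")
    if df.empty:
        raise ValidationError(f"{path}: empty seizure log table")
    logs = []
    for animal_id, sub in df.groupby("animal_id", sort=False):
        sub = sub.sort_values("day").reset_index(drop=True)
        logs.append(SeizureLog(str(animal_id), sub.drop(columns="animal_id"), n_days=n_days))
    return logs


# ---------------------------------------------------------------------------
# manifest


def write_manifest(manifest: StudyManifest, path: str | Path) -> None:
    manifest.entries.to_csv(path, index=False)


def read_manifest(path: str | Path, check_files: bool = True) -> StudyManifest:
    df = pd.read_csv(path)
    manifest = StudyManifest(df)
    if check_files:
        root = Path(path).parent
        for _, row in df.iterrows():
            for col in ("map", "mask", "log"):
                p = Path(row[col])
                if not p.is_absolute():
                    p = root / p
                if not p.exists():
                    raise FormatError(
                        f"manifest entry {row['animal_id']}: missing {col} file {p}"
                    )
    return manifest


def resolve_path(manifest_path: str | Path, p: str | Path) -> Path:
    """Resolve a manifest-relative path against the manifest's directory."""
    p = Path(p)
    return p if p.is_absolute() else Path(manifest_path).parent / p
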