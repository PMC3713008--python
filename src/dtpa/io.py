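"""Reading and writing of DSCE-MRI series, tissue-of-interest definitions and reports.

A dynamic susceptibility contrast enhanced (DSCE) examination is a 4D raster:
repeated echo-planar volumes acquired while a gadolinium bolus passes the
brain.  Internally every series uses the axis order ``(time, slice, row, col)``
regardless of the on-disk layout; all loaders normalize to it.

Tissue-of-interest (TOI) definitions come either as an integer label raster
(NIfTI plus a JSON sidecar mapping label values to tissue classes) or as named
closed 2D polygons in voxel coordinates.  Polygons are rasterized with the
even-odd rule evaluated at voxel centers; a voxel center lying exactly on the
polygon boundary counts as inside.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUE_CLASSES = ("EL", "NEL", "NAWM", "OTHER")

#: interval in which the contour of each tissue class is conventionally drawn
DEFINITION_INTERVALS = {"NEL": "BLP", "EL": "RPP", "NAWM": "IFP"}


@dataclass
class DSCESeries:
    """A 4D DSCE-MRI signal time series with acquisition metadata.

    ``signal`` is indexed ``(time, slice, row, col)`` in arbitrary scanner
    units; ``te_ms``/``tr_ms`` are the echo and repetition times in
    milliseconds (the repetition time doubles as the time resolution).
    """

    signal: np.ndarray
    te_ms: float
    tr_ms: float
    voxel_size_mm: tuple[float, float, float] = (1.8, 1.8, 5.0)
    field_strength_T: float = 1.5
    provenance: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (time, slice, row, col)")
        if self.n_time < 4:
            raise ValueError("need at least 4 time points (one per interval)")
        if self.te_ms <= 0 or self.tr_ms <= 0:
            raise ValueError("te_ms and tr_ms must be positive")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")

    @property
    def n_time(self) -> int:
        return self.signal.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[1:]


@dataclass
class TOI:
    """A tissue of interest: a labelled boolean mask on the series grid."""

    label: str
    tissue_class: str
    mask: np.ndarray
    slice_index: int | None = None
    definition_interval: str | None = None

    def __post_init__(self) -> None:
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(f"unknown tissue class {self.tissue_class!r}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim not in (2, 3):
            raise ValueError("mask must be 2D or 3D")
        if not self.mask.any():
            raise ValueError(f"TOI {self.label!r} has an empty mask")
        if self.definition_interval is None:
            self.definition_interval = DEFINITION_INTERVALS.get(self.tissue_class)

    def mask3d(self, spatial_shape: tuple[int, int, int]) -> np.ndarray:
        """Expand to a 3D mask aligned with ``spatial_shape`` (slice, row, col)."""
        if self.mask.ndim == 3:
            if self.mask.shape != spatial_shape:
                raise ValueError("TOI mask shape does not match series grid")
            return self.mask
        if self.mask.shape != spatial_shape[1:]:
            raise ValueError("TOI mask shape does not match series slice grid")
        out = np.zeros(spatial_shape, dtype=bool)
        sl = 0 if self.slice_index is None else self.slice_index
        out[sl] = self.mask
        return out


@dataclass
class StatReport:
    """Bundle of the per-TOI statistic records and the group test results."""

    records: pd.DataFrame
    test_results: pd.DataFrame | None = None
    delta_markers: pd.DataFrame | None = None
    header: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# series I/O

def _sidecar_path(path: Path) -> Path:
    suffixes = "".join(path.suffixes)
    stem = path.name[: -len(suffixes)] if suffixes else path.name
    return path.with_name(stem + ".json")


def load_dsce_series(
    path: str | Path,
    format: str = "nifti4d",
    te_ms: float | None = None,
    tr_ms: float | None = None,
) -> DSCESeries:
    """Load a DSCE series from a 4D NIfTI file or a DICOM directory.

    NIfTI stores the time axis last; it is transposed to time-first.  TE/TR
    are read from a BIDS-style JSON sidecar (``EchoTime``/``RepetitionTime``
    in seconds) or taken from the explicit overrides; missing values are a
    hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "nifti4d":
        return _load_nifti4d(path, te_ms, tr_ms)
    if format == "dicom_dir":
        return _load_dicom_dir(path, te_ms, tr_ms)
    raise ValueError(f"unknown format {format!r}")


def _load_nifti4d(path: Path, te_ms: float | None, tr_ms: float | None) -> DSCESeries:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D NIfTI, got {data.ndim}D")
    # NIfTI axis order (col, row, slice, time) -> (time, slice, row, col)
    signal = np.transpose(data, (3, 2, 1, 0))

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if te_ms is None:
        if "EchoTime" in meta:
            te_ms = float(meta["EchoTime"]) * 1000.0
        else:
            raise ValueError("echo time required: no sidecar EchoTime and no override")
    if tr_ms is None:
        if "RepetitionTime" in meta:
            tr_ms = float(meta["RepetitionTime"]) * 1000.0
        else:
            raise ValueError(
                "repetition time required: no sidecar RepetitionTime and no override"
            )
    zooms = img.header.get_zooms()[:3]
    voxel = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return DSCESeries(
        signal=signal,
        te_ms=te_ms,
        tr_ms=tr_ms,
        voxel_size_mm=voxel,
        field_strength_T=float(meta.get("MagneticFieldStrength", 1.5)),
        provenance=str(path),
    )


def write_dsce_series(series: DSCESeries, path: str | Path) -> None:
    """Write a series as 4D NIfTI plus a JSON sidecar carrying TE/TR."""
    import nibabel as nib

    path = Path(path)
    data = np.transpose(series.signal, (3, 2, 1, 0))
    affine = np.diag(list(series.voxel_size_mm[::-1]) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(series.voxel_size_mm[::-1]) + (series.tr_ms / 1000.0,))
    nib.save(img, str(path))
    sidecar = {
        "EchoTime": series.te_ms / 1000.0,
        "RepetitionTime": series.tr_ms / 1000.0,
        "MagneticFieldStrength": series.field_strength_T,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def _load_dicom_dir(path: Path, te_ms: float | None, tr_ms: float | None) -> DSCESeries:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not files:
        files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = [pydicom.dcmread(str(f)) for f in files]
    if not datasets:
        raise ValueError(f"no DICOM files found in {path}")

    def sort_key(ds):
        t = getattr(ds, "AcquisitionTime", None)
        n = int(getattr(ds, "InstanceNumber", 0))
        if t is None:
            return (0.0, n)
        return (float(t), n)

    if any(getattr(ds, "AcquisitionTime", None) is None for ds in datasets):
        logger.warning("AcquisitionTime missing on some slices; sorting by InstanceNumber")
    datasets.sort(key=sort_key)

    times = []
    for ds in datasets:
        t = getattr(ds, "AcquisitionTime", None)
        times.append(float(t) if t is not None else None)
    if all(t is not None for t in times):
        unique_times = sorted(set(times))
        n_time = len(unique_times)
    else:
        n_time = len({int(getattr(ds, "AcquisitionNumber", i)) for i, ds in enumerate(datasets)})
        unique_times = None
    if n_time < 2 or len(datasets) % n_time != 0:
        raise ValueError("non-uniform slice count across time points")
    n_slices = len(datasets) // n_time

    rows, cols = datasets[0].Rows, datasets[0].Columns
    signal = np.empty((n_time, n_slices, rows, cols), dtype=float)
    if unique_times is not None:
        by_time: dict[float, list] = {t: [] for t in unique_times}
        for ds, t in zip(datasets, times):
            by_time[t].append(ds)
        for k, t in enumerate(unique_times):
            group = by_time[t]
            if len(group) != n_slices:
                raise ValueError("non-uniform slice count across time points")
            group.sort(key=lambda d: float(getattr(d, "SliceLocation", getattr(d, "InstanceNumber", 0))))
            for s, ds in enumerate(group):
                signal[k, s] = ds.pixel_array.astype(float)
    else:
        for i, ds in enumerate(datasets):
            signal[i // n_slices, i % n_slices] = ds.pixel_array.astype(float)

    ds0 = datasets[0]
    if te_ms is None:
        te = getattr(ds0, "EchoTime", None)
        if te is None:
            raise ValueError("echo time required: no EchoTime tag and no override")
        te_ms = float(te)
    if tr_ms is None:
        tr = getattr(ds0, "RepetitionTime", None)
        if tr is None:
            raise ValueError("repetition time required: no RepetitionTime tag and no override")
        tr_ms = float(tr)
    pix = getattr(ds0, "PixelSpacing", [1.8, 1.8])
    thick = float(getattr(ds0, "SliceThickness", 5.0))
    return DSCESeries(
        signal=signal,
        te_ms=te_ms,
        tr_ms=tr_ms,
        voxel_size_mm=(float(pix[0]), float(pix[1]), thick),
        field_strength_T=float(getattr(ds0, "MagneticFieldStrength", 1.5)),
        provenance=str(path),
    )


# ---------------------------------------------------------------------------
# TOI I/O

def point_in_polygon(point: Sequence[float], vertices: np.ndarray) -> bool:
    """Even-odd rule point-in-polygon test with inclusive boundary.

    ``vertices`` is an (n, 2) array of (row, col) voxel coordinates describing
    a closed polygon (last vertex implicitly joined to the first).
    """
    y, x = float(point[0]), float(point[1])
    v = np.asarray(vertices, dtype=float)
    n = len(v)
    inside = False
    for i in range(n):
        y1, x1 = v[i]
        y2, x2 = v[(i + 1) % n]
        # boundary: point on the closed segment counts as inside
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12:
            if min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 and \
               min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12:
                return True
        if (y1 > y) != (y2 > y):
            x_int = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < x_int:
                inside = not inside
    return inside


def rasterize_polygon(vertices: Sequence[Sequence[float]], shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed polygon onto a (rows, cols) grid of voxel centers."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
        raise ValueError("polygon needs at least 3 (row, col) vertices")
    mask = np.zeros(shape, dtype=bool)
    rmin = max(int(np.floor(v[:, 0].min())), 0)
    rmax = min(int(np.ceil(v[:, 0].max())), shape[0] - 1)
    cmin = max(int(np.floor(v[:, 1].min())), 0)
    cmax = min(int(np.ceil(v[:, 1].max())), shape[1] - 1)
    for r in range(rmin, rmax + 1):
        for c in range(cmin, cmax + 1):
            mask[r, c] = point_in_polygon((r, c), v)
    return mask


def load_toi_set(
    path: str | Path,
    spatial_shape: tuple[int, int, int] | None = None,
) -> list[TOI]:
    """Load TOIs from a polygon JSON file or an integer label raster.

    A ``.json`` file holds ``{"tois": [{label, tissue_class, slice_index,
    vertices}, ...]}`` with vertices in (row, col) voxel coordinates.  A NIfTI
    label raster needs a sidecar JSON mapping label values to tissue classes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".json":
        if spatial_shape is None:
            raise ValueError("spatial_shape required to rasterize polygon TOIs")
        spec = json.loads(path.read_text())
        tois = []
        for entry in spec["tois"]:
            mask = rasterize_polygon(entry["vertices"], spatial_shape[1:])
            tois.append(
                TOI(
                    label=entry["label"],
                    tissue_class=entry["tissue_class"],
                    mask=mask,
                    slice_index=int(entry.get("slice_index", 0)),
                    definition_interval=entry.get("definition_interval"),
                )
            )
        return tois
    # label raster
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    labels = np.transpose(data, tuple(range(data.ndim - 1, -1, -1))).astype(int)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(f"label raster {path} needs a JSON sidecar with class mapping")
    mapping = json.loads(sidecar.read_text())
    tois = []
    for value in np.unique(labels):
        if value == 0:
            continue
        key = str(int(value))
        if key not in mapping:
            raise ValueError(f"label {value} in raster missing from sidecar mapping")
        entry = mapping[key]
        if isinstance(entry, str):
            cls, name = entry, f"toi_{value}"
        else:
            cls, name = entry["tissue_class"], entry.get("label", f"toi_{value}")
        tois.append(TOI(label=name, tissue_class=cls, mask=labels == value))
    return tois


def write_toi_set(tois: list[TOI], path: str | Path, spatial_shape: tuple[int, int, int]) -> None:
    """Write TOIs as an integer label raster (NIfTI) plus a JSON sidecar."""
    import nibabel as nib

    path = Path(path)
    labels = np.zeros(spatial_shape, dtype=np.int16)
    mapping = {}
    for i, toi in enumerate(tois, start=1):
        m = toi.mask3d(spatial_shape)
        if np.any(labels[m] != 0):
            warnings.warn(f"TOI {toi.label!r} overlaps a previous TOI in the label raster")
        labels[m] = i
        mapping[str(i)] = {"label": toi.label, "tissue_class": toi.tissue_class}
    data = np.transpose(labels, (2, 1, 0))
    nib.save(nib.Nifti1Image(data.astype(np.int16), np.eye(4)), str(path))
    _sidecar_path(path).write_text(json.dumps(mapping, indent=1))


# ---------------------------------------------------------------------------
# report I/O

_FLOAT_FMT = "%.12g"


def write_stats_report(report: StatReport, path: str | Path) -> None:
    """Write the analysis grid (and, when present, test results and Δ-markers)
    as tab-separated text files.

    ``path`` names the records table; test results and Δ-markers go to
    sibling files with ``_tests`` / ``_deltas`` suffixes.  Config keys in
    ``report.header`` are written as ``# key = value`` comment lines so a run
    is reproducible from its report alone.
    """
    path = Path(path)
    if report.records is None or len(report.records) == 0:
        raise ValueError("refusing to write an empty report")
    _write_table(report.records, path, report.header)
    if report.test_results is not None and len(report.test_results):
        _write_table(report.test_results, _suffixed(path, "_tests"), report.header)
    if report.delta_markers is not None and len(report.delta_markers):
        _write_table(report.delta_markers, _suffixed(path, "_deltas"), report.header)


def _suffixed(path: Path, suffix: str) -> Path:
    return path.with_name(path.stem + suffix + path.suffix)


def _write_table(df: pd.DataFrame, path: Path, header: dict) -> None:
    with open(path, "w") as fh:
        for key, value in header.items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_stats_report(path: str | Path) -> StatReport:
    """Read a report previously written by :func:`write_stats_report`."""
    path = Path(path)
    records, header = _read_table(path)
    tests_path = _suffixed(path, "_tests")
    deltas_path = _suffixed(path, "_deltas")
    tests = _read_table(tests_path)[0] if tests_path.exists() else None
    deltas = _read_table(deltas_path)[0] if deltas_path.exists() else None
    return StatReport(records=records, test_results=tests, delta_markers=deltas, header=header)


def _read_table(path: Path) -> tuple[pd.DataFrame, dict]:
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].partition("=")
            header[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return df, header
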