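"""Per-tissue-of-interest statistics over the texture parameter maps.

For each TOI and each TPM the six region statistics -- mean, standard
deviation, variance, variance-of-the-variance (``m4 - m2**2``, the variance of
the squared deviations), skewness and excess kurtosis -- are evaluated per
time point over the valid voxels, then averaged within each bolus-passage
interval.  With the canonical grid of three tissue classes this yields
6 statistics x 4 intervals x 3 classes = 72 parameter cells per TPM, and
8 x 72 = 576 cells over the full battery.

Degenerate values (empty TOI/validity intersection, zero variance for the
standardized moments) are carried as explicit *undetermined* flags -- never
as zeros -- and excluded from interval averages and group tests.

The Δ surrogate markers are interval differences of the TOI-mean time
courses, ``Δ = value(RPP) - value(IFP)``, proposed as continuous grades of
leakage (ΔTPM-DIFF, ΔTPM-AVER) and heterogeneity change (ΔTPM-VAVA,
ΔTPM-STDEV, ΔTPM-VARI).
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .io import TOI
from .normalization import DifferenceSeries
from .phases import INTERVALS, BolusPhases
from .texture import DEGENERACY_REL, TPMSeries

logger = logging.getLogger(__name__)

STATISTICS = ("mean", "stdev", "var", "vava", "skew", "kurt")

#: Δ-marker name -> underlying TPM type
DELTA_MARKERS = {
    "dTPM_DIFF": "DIFF",
    "dTPM_AVER": "AVER",
    "dTPM_VAVA": "VAVA",
    "dTPM_STDEV": "STDEV",
    "dTPM_VARI": "VARI",
}

RECORD_COLUMNS = [
    "toi_label", "tissue_class", "tpm_type", "statistic", "interval",
    "value", "n_voxels", "n_timepoints", "undetermined",
]


def region_statistics(values: np.ndarray) -> dict[str, float]:
    """The six population statistics of a flat set of region values.

    Returns NaN (undetermined) for skew/kurt when the variance is degenerate
    relative to the value range, and for everything when the set is empty.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        return {s: np.nan for s in STATISTICS}
    mean = values.mean()
    dev = values - mean
    m2 = np.mean(dev**2)
    m3 = np.mean(dev**3)
    m4 = np.mean(dev**4)
    out = {
        "mean": mean,
        "stdev": np.sqrt(m2),
        "var": m2,
        "vava": m4 - m2**2,
    }
    eps = DEGENERACY_REL * float(np.ptp(values)) ** 2
    if m2 > eps:
        out["skew"] = m3 / m2**1.5
        out["kurt"] = m4 / m2**2 - 3.0
    else:
        out["skew"] = np.nan
        out["kurt"] = np.nan
    return out


def toi_time_course(tpm: TPMSeries, toi: TOI) -> pd.DataFrame:
    """Six statistics per time point over the TOI's valid voxels.

    Returns a DataFrame indexed by time with one column per statistic plus
    ``n_voxels``; time points with an empty TOI/validity intersection are
    fully undetermined (NaN).  Vectorized over time; agrees with
    :func:`region_statistics` applied frame by frame.
    """
    mask = toi.mask3d(tpm.values.shape[1:])
    vals = tpm.values[:, mask]          # (n_time, n_toi_voxels)
    valid = tpm.valid[:, mask]
    n = valid.sum(axis=1).astype(float)
    empty = n == 0
    if empty.any():
        logger.warning(
            "TOI %r has no valid voxels in %s at %d of %d time points",
            toi.label, tpm.tpm_type, int(empty.sum()), tpm.n_time,
        )
    safe_n = np.where(empty, 1.0, n)

    masked = np.where(valid, vals, 0.0)
    mean = masked.sum(axis=1) / safe_n
    dev = np.where(valid, vals - mean[:, None], 0.0)
    d2 = dev * dev
    m2 = d2.sum(axis=1) / safe_n
    m3 = (d2 * dev).sum(axis=1) / safe_n
    m4 = (d2 * d2).sum(axis=1) / safe_n

    vmax = np.where(valid, vals, -np.inf).max(axis=1)
    vmin = np.where(valid, vals, np.inf).min(axis=1)
    eps = DEGENERACY_REL * np.where(empty, 0.0, vmax - vmin) ** 2
    nondegenerate = m2 > eps
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(nondegenerate, m3 / np.where(nondegenerate, m2, 1.0) ** 1.5, np.nan)
        kurt = np.where(nondegenerate, m4 / np.where(nondegenerate, m2, 1.0) ** 2 - 3.0, np.nan)

    df = pd.DataFrame(
        {
            "mean": np.where(empty, np.nan, mean),
            "stdev": np.where(empty, np.nan, np.sqrt(m2)),
            "var": np.where(empty, np.nan, m2),
            "vava": np.where(empty, np.nan, m4 - m2**2),
            "skew": skew,
            "kurt": kurt,
            "n_voxels": valid.sum(axis=1),
        }
    )
    return df


def interval_average(
    time_course: pd.DataFrame,
    phases: BolusPhases,
    toi: TOI,
    tpm_type: str,
) -> pd.DataFrame:
    """Average the per-time-point statistics within each interval.

    Only finite per-time-point values enter each mean (degenerate frames are
    dropped and the surviving count recorded).  Produces the 6 x 4 record
    block for one (TOI, TPM).
    """
    records = []
    for interval in INTERVALS:
        members = phases.interval_members(interval)
        block = time_course.iloc[members]
        for statistic in STATISTICS:
            vals = block[statistic].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            undetermined = finite.size == 0
            records.append(
                {
                    "toi_label": toi.label,
                    "tissue_class": toi.tissue_class,
                    "tpm_type": tpm_type,
                    "statistic": statistic,
                    "interval": interval,
                    "value": float(finite.mean()) if not undetermined else np.nan,
                    "n_voxels": int(block["n_voxels"].max()),
                    "n_timepoints": int(finite.size),
                    "undetermined": undetermined,
                }
            )
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


def build_record_table(
    tpms: dict[str, TPMSeries],
    tois: Iterable[TOI],
    phases: BolusPhases,
) -> pd.DataFrame:
    """The full analysis grid: every (TOI, TPM, statistic, interval) record.

    The same TOI masks are reused verbatim across all TPMs.
    """
    blocks = []
    for tpm_type, tpm in tpms.items():
        for toi in tois:
            course = toi_time_course(tpm, toi)
            blocks.append(interval_average(course, phases, toi, tpm_type))
    return pd.concat(blocks, ignore_index=True)


def direct_toi_texture(diff: DifferenceSeries, toi: TOI) -> pd.DataFrame:
    """Texture statistics straight from the raw difference voxels of a TOI.

    No kernel, no border loss, no validity restriction: the region itself is
    the sample at every time point.  This is the kernel-free alternative for
    small lesions where a fixed kernel sacrifices too much resolution.
    """
    mask = toi.mask3d(diff.spatial_shape)
    rows = []
    for k in range(diff.n_time):
        stats = region_statistics(diff.diff[k][mask])
        stats["n_voxels"] = int(mask.sum())
        rows.append(stats)
    return pd.DataFrame(rows)


def delta_markers(records: pd.DataFrame) -> pd.DataFrame:
    """Δ surrogate markers: RPP minus IFP of the TOI-mean statistic.

    One marker per (TOI, underlying TPM); a missing or undetermined interval
    entry yields an undetermined marker (NaN).
    """
    out = []
    for (toi_label, tissue_class), group in records.groupby(
        ["toi_label", "tissue_class"], sort=False
    ):
        for marker, tpm_type in DELTA_MARKERS.items():
            sub = group[(group.tpm_type == tpm_type) & (group.statistic == "mean")]
            ifp = sub[sub.interval == "IFP"]["value"]
            rpp = sub[sub.interval == "RPP"]["value"]
            if len(ifp) == 1 and len(rpp) == 1:
                value = float(rpp.iloc[0]) - float(ifp.iloc[0])
            else:
                value = np.nan
            out.append(
                {
                    "toi_label": toi_label,
                    "tissue_class": tissue_class,
                    "marker": marker,
                    "value": value,
                }
            )
    return pd.DataFrame(out)
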