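"""Difference-image construction and the twofold series normalization.

Two multiplicative nuisance factors prevent inter-patient comparison of DSCE
voxel intensities: the RF coil load (head size/position, field strength) and
the cardiac output (which scales the amount of contrast agent delivered per
unit time).  Both are removed against a user-defined reference region in
normal-appearing white matter (NAWM):

* *coil-load normalization* divides the raw series by the factor that maps the
  reference-region mean of the baseline image to a fixed constant ``c_ideal``;
* *cardiac-output normalization* divides the difference series by the factor
  that maps the reference-region difference-curve area under the curve over
  the inflow+outflow phases to a fixed constant ``auc_ref`` (default 200).

The difference series is ``D_k = S_baseline - S_k``: positive where contrast
agent darkens the signal (susceptibility effect, intact blood-brain barrier),
negative where late T1 enhancement from leakage lifts the signal above
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import DSCESeries, TOI


@dataclass
class DifferenceSeries:
    """Baseline-minus-current difference images, same shape as the source."""

    diff: np.ndarray
    baseline_index: int
    te_ms: float
    tr_ms: float

    @property
    def n_time(self) -> int:
        return self.diff.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.diff.shape[1:]


@dataclass
class NormalizationState:
    """Factors applied by the twofold normalization, for the report header."""

    coil_factor: float | None = None
    c_ideal: float | None = None
    auc_factor: float | None = None
    auc_ref: float | None = None
    reference_region: str | None = None


@dataclass
class ConcentrationCurve:
    """Region-mean contrast concentration over time (arbitrary units).

    Computed with the standard dynamic susceptibility contrast relation
    ``C(t) = -(1/TE) * ln(S(t)/S(baseline))``; the baseline value is exactly 0.
    """

    values: np.ndarray
    region_label: str
    te_ms: float


def _region_means(raster4d: np.ndarray, toi: TOI) -> np.ndarray:
    mask = toi.mask3d(raster4d.shape[1:])
    return raster4d[:, mask].mean(axis=1)


def coil_load_normalize(
    series: DSCESeries,
    region: TOI,
    c_ideal: float = 100.0,
    baseline_index: int = 0,
) -> tuple[DSCESeries, NormalizationState]:
    """Divide the whole series by ``mean(region at baseline) / c_ideal``.

    After the call the reference-region mean of the baseline image equals
    ``c_ideal`` to floating-point rounding.
    """
    if c_ideal <= 0:
        raise ValueError("c_ideal must be positive")
    mask = region.mask3d(series.spatial_shape)
    ref_mean = series.signal[baseline_index][mask].mean()
    if ref_mean <= 0:
        raise ValueError("degenerate reference region: non-positive baseline mean")
    factor = ref_mean / c_ideal
    normalized = replace(series, signal=series.signal / factor)
    state = NormalizationState(
        coil_factor=factor, c_ideal=c_ideal, reference_region=region.label
    )
    return normalized, state


def compute_difference_series(series: DSCESeries, baseline_index: int = 0) -> DifferenceSeries:
    """``D_k = S_baseline - S_k`` for every time point k."""
    if not 0 <= baseline_index < series.n_time:
        raise ValueError("baseline_index out of range")
    diff = series.signal[baseline_index][None] - series.signal
    return DifferenceSeries(
        diff=diff, baseline_index=baseline_index, te_ms=series.te_ms, tr_ms=series.tr_ms
    )


def concentration_curve(
    series: DSCESeries, region: TOI, baseline_index: int = 0
) -> ConcentrationCurve:
    """Region-mean concentration ``-(1/TE) ln(S_k/S_baseline)`` over time."""
    means = _region_means(series.signal, region)
    if np.any(means <= 0):
        raise ValueError("log of non-positive signal: region mean <= 0 at some time point")
    values = -np.log(means / means[baseline_index]) / series.te_ms
    values[baseline_index] = 0.0
    return ConcentrationCurve(values=values, region_label=region.label, te_ms=series.te_ms)


def region_difference_auc(diff: DifferenceSeries, region: TOI, indices: np.ndarray) -> float:
    """Trapezoidal area under the region-mean difference curve over ``indices``.

    Time indices are taken at unit spacing, endpoints inclusive.
    """
    means = _region_means(diff.diff, region)
    idx = np.sort(np.asarray(indices))
    return float(np.trapezoid(means[idx], idx))


def cardiac_output_normalize(
    diff: DifferenceSeries,
    region: TOI,
    phases,
    auc_ref: float = 200.0,
) -> tuple[DifferenceSeries, NormalizationState]:
    """Divide the difference series by ``AUC(IFP+OFP) / auc_ref``.

    ``phases`` is the detected :class:`~dtpa.phases.BolusPhases`; the same
    NAWM region used for the coil-load step must be passed.  After the call
    the recomputed inflow+outflow AUC equals ``auc_ref`` to rounding.
    """
    if auc_ref <= 0:
        raise ValueError("auc_ref must be positive")
    indices = np.concatenate([phases.interval_members("IFP"), phases.interval_members("OFP")])
    auc = region_difference_auc(diff, region, indices)
    if auc <= 0:
        raise ValueError("no detectable bolus in reference region (AUC <= 0)")
    factor = auc / auc_ref
    normalized = replace(diff, diff=diff.diff / factor)
    state = NormalizationState(
        auc_factor=factor, auc_ref=auc_ref, reference_region=region.label
    )
    return normalized, state
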