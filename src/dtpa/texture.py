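"""Time-resolved texture parameter maps (TPMs) over a sliding voxel kernel.

Eight map types are produced per examination:

========  ==================================================================
ORIG      the coil-load-normalized signal itself
DIFF      the (cardiac-normalized) baseline-minus-current difference images
AVER      moving average of DIFF over the kernel
VARI      local population variance of DIFF
STDEV     square root of VARI
SKEW      local skewness ``m3 / m2**1.5``
KURT      local *excess* kurtosis ``m4 / m2**2 - 3`` (Gaussian -> 0)
VAVA      variance-of-the-variance: the local variance filter applied a
          second time to the VARI map (not the within-kernel closed form
          ``m4 - m2**2``, which behaves like an edge detector)
========  ==================================================================

Kernels are 2D and never cross slice boundaries (5 mm slices make
through-plane neighborhoods strongly anisotropic).  Local moments use the
population (divide-by-n) convention.  A validity mask marks the border band
of half the kernel width, and voxels whose local variance falls below a
degeneracy threshold are invalidated for SKEW/KURT rather than forced to 0
-- on near-constant baseline difference images these ratios are meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .io import DSCESeries
from .normalization import DifferenceSeries

TPM_TYPES = ("ORIG", "DIFF", "AVER", "VARI", "STDEV", "SKEW", "KURT", "VAVA")

#: relative factor on the squared dynamic range below which the local
#: variance is treated as degenerate for the standardized moments
DEGENERACY_REL = 1e-12


@dataclass
class TPMSeries:
    """One texture parameter map time series with its validity mask."""

    tpm_type: str
    values: np.ndarray
    kernel: int
    valid: np.ndarray

    @property
    def n_time(self) -> int:
        return self.values.shape[0]


def local_moments(
    image: np.ndarray, kernel: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Local population central moments of a 2D image over a w*w kernel.

    Returns ``(mean, m2, m3, m4, valid)`` as full-size maps; the border band
    of width ``(w-1)//2``, where the kernel does not fit, is zero-filled and
    flagged invalid.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("local_moments expects a 2D image")
    w = int(kernel)
    if w % 2 == 0 or w < 3:
        raise ValueError("kernel side length must be odd and >= 3")
    if w > min(image.shape):
        raise ValueError("kernel larger than the image")

    # Raw power sums via a C-speed box filter; centering on the frame mean
    # first keeps the raw->central moment conversion numerically benign
    # (central moments are translation invariant).
    x = image - image.mean()
    e1 = uniform_filter(x, w)
    e2 = uniform_filter(x * x, w)
    e3 = uniform_filter(x**3, w)
    e4 = uniform_filter(x**4, w)
    mean = e1
    m2 = e2 - e1**2
    m3 = e3 - 3.0 * e1 * e2 + 2.0 * e1**3
    m4 = e4 - 4.0 * e1 * e3 + 6.0 * e1**2 * e2 - 3.0 * e1**4

    half = (w - 1) // 2
    valid = np.zeros(image.shape, dtype=bool)
    valid[half : image.shape[0] - half, half : image.shape[1] - half] = True
    for arr in (mean, m2, m3, m4):
        arr[~valid] = 0.0
    np.clip(m2, 0.0, None, out=m2)  # guard tiny negative rounding
    np.clip(m4, 0.0, None, out=m4)
    return mean + image.mean() * valid, m2, m3, m4, valid


def _degeneracy_threshold(image: np.ndarray, degeneracy_eps: float | None) -> float:
    if degeneracy_eps is not None:
        return degeneracy_eps
    dynamic_range = float(np.ptp(image))
    return DEGENERACY_REL * dynamic_range**2


_KERNEL_TYPES = ("AVER", "VARI", "STDEV", "SKEW", "KURT", "VAVA")


def _frame_kernel_maps(
    frame: np.ndarray,
    kernel: int,
    degeneracy_eps: float | None,
    vava_mode: str,
    types: tuple[str, ...],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """All requested kernel maps of one 2D frame, sharing one moment pass."""
    mean, m2, m3, m4, v = local_moments(frame, kernel)
    eps = _degeneracy_threshold(frame, degeneracy_eps)
    half = (kernel - 1) // 2
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for tpm_type in types:
        if tpm_type == "AVER":
            out[tpm_type] = (mean, v)
        elif tpm_type == "VARI":
            out[tpm_type] = (m2, v)
        elif tpm_type == "STDEV":
            out[tpm_type] = (np.sqrt(m2), v)
        elif tpm_type in ("SKEW", "KURT"):
            ok = v & (m2 > eps)
            res = np.zeros_like(m2)
            if tpm_type == "SKEW":
                np.divide(m3, m2**1.5, out=res, where=ok)
            else:
                np.divide(m4, m2**2, out=res, where=ok)
                res[ok] -= 3.0
            out[tpm_type] = (res, ok)
        elif tpm_type == "VAVA":
            if vava_mode == "closed_form":
                out[tpm_type] = (m4 - m2**2, v)
            else:
                # second local-variance pass over the interior of the VARI map
                interior = m2[half : m2.shape[0] - half, half : m2.shape[1] - half]
                _, vv, _, _, _ = local_moments(interior, kernel)
                vv_core = vv[half : vv.shape[0] - half, half : vv.shape[1] - half]
                res = np.zeros_like(m2)
                ok = np.zeros(m2.shape, dtype=bool)
                sl = (slice(2 * half, m2.shape[0] - 2 * half),
                      slice(2 * half, m2.shape[1] - 2 * half))
                res[sl] = vv_core
                ok[sl] = True
                out[tpm_type] = (res, ok)
        else:
            raise ValueError(f"unknown or non-kernel TPM type {tpm_type!r}")
    return out


def compute_tpm(
    diff: DifferenceSeries,
    tpm_type: str,
    kernel: int = 3,
    degeneracy_eps: float | None = None,
    vava_mode: str = "two_pass",
) -> TPMSeries:
    """Compute one kernel-derived TPM time series from the difference images.

    ``degeneracy_eps`` is the absolute local-variance threshold below which
    SKEW/KURT are invalidated; when ``None`` it defaults to
    ``1e-12 * (dynamic range)**2`` per frame.  ``vava_mode`` selects the
    two-pass variance-of-variance map (default) or the within-kernel closed
    form ``m4 - m2**2``.
    """
    if tpm_type not in _KERNEL_TYPES:
        raise ValueError(f"unknown or non-kernel TPM type {tpm_type!r}")
    if vava_mode not in ("two_pass", "closed_form"):
        raise ValueError(f"unknown vava_mode {vava_mode!r}")
    data = diff.diff
    n_time, n_slice = data.shape[:2]
    values = np.zeros_like(data)
    valid = np.zeros(data.shape, dtype=bool)
    for k in range(n_time):
        for s in range(n_slice):
            maps = _frame_kernel_maps(
                data[k, s], kernel, degeneracy_eps, vava_mode, (tpm_type,)
            )
            values[k, s], valid[k, s] = maps[tpm_type]
    return TPMSeries(tpm_type=tpm_type, values=values, kernel=kernel, valid=valid)


def compute_all_tpms(
    series: DSCESeries,
    diff: DifferenceSeries,
    kernel: int = 3,
    degeneracy_eps: float | None = None,
    vava_mode: str = "two_pass",
) -> dict[str, TPMSeries]:
    """All eight TPM series: ORIG from the normalized signal, DIFF verbatim,
    and the six kernel maps derived from DIFF with one shared kernel."""
    if series.signal.shape != diff.diff.shape:
        raise ValueError("series and difference series are not aligned")
    all_valid = np.ones(diff.diff.shape, dtype=bool)
    tpms: dict[str, TPMSeries] = {
        "ORIG": TPMSeries("ORIG", series.signal, kernel, all_valid),
        "DIFF": TPMSeries("DIFF", diff.diff, kernel, all_valid.copy()),
    }
    data = diff.diff
    for tpm_type in _KERNEL_TYPES:
        tpms[tpm_type] = TPMSeries(
            tpm_type, np.zeros_like(data), kernel, np.zeros(data.shape, dtype=bool)
        )
    for k in range(data.shape[0]):
        for s in range(data.shape[1]):
            maps = _frame_kernel_maps(
                data[k, s], kernel, degeneracy_eps, vava_mode, _KERNEL_TYPES
            )
            for tpm_type, (vals, ok) in maps.items():
                tpms[tpm_type].values[k, s] = vals
                tpms[tpm_type].valid[k, s] = ok
    return tpms
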