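"""Seeded synthetic DSCE-MRI phantoms with analytic ground truth.

The phantom emulates an echo-planar time series during gadolinium bolus
passage.  Each voxel of tissue τ follows

    S(t, x) = B(x) * exp(-TE * c_τ(t)) + l_τ * Cum_τ(t) + ε(t, x)

where ``B(x)`` is a per-voxel baseline (tissue mean plus an i.i.d. Gaussian
texture field), ``c_τ(t)`` a gamma-variate first-pass bolus plus a delayed,
broadened recirculation bump, ``Cum_τ`` its cumulative (trapezoidal)
integral modelling cumulative contrast uptake through a leaky blood-brain
barrier (coefficient ``l_τ >= 0``), and ``ε`` additive Gaussian noise.  At
the signal-to-noise ratios simulated, Gaussian noise is an adequate stand-in
for the Rician statistics of magnitude MRI and keeps every oracle analytic.

Lesions are disks stamped on a NAWM background; enhancing lesions get an
earlier bolus onset (contrast reaches a disrupted lesion slightly before
normal white matter), optionally elevated texture variance and a positive
leakage coefficient; non-enhancing lesions get a reduced bolus amplitude
(mild hypoperfusion).  All truth quantities -- tissue label map, noise-free
concentration curves, phase indices, leakage sign map -- are returned
alongside the series.

Defaults describe a 1.5 T protocol: TE 47 ms, TR 1440 ms, 40 time points,
a 25% peak first-pass signal drop in NAWM, baseline 400 with 3.75% texture
standard deviation, and noise sigma 4 (baseline SNR 100).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .io import DSCESeries, TOI, write_dsce_series, write_toi_set


@dataclass
class TissueParams:
    """Signal-model parameters of one tissue class."""

    baseline_mean: float = 400.0
    texture_sd: float = 15.0
    t0: float = 8.0              # bolus onset, time indices
    alpha: float = 3.0           # gamma-variate shape
    beta: float = 1.5            # gamma-variate scale, time indices
    amplitude: float = 0.00612   # peak concentration (1/ms units; 25% drop at TE 47)
    recirc_fraction: float = 0.22
    recirc_delay: float = 9.5    # onset delay of the recirculation bump
    leakage: float = 0.0         # signal units per (concentration * time index)


@dataclass
class PhantomConfig:
    """Full description of one simulated examination."""

    grid: tuple[int, int, int] = (1, 96, 96)  # (slices, rows, cols)
    n_time: int = 40
    tr_ms: float = 1440.0
    te_ms: float = 47.0
    tissues: dict[str, TissueParams] = field(default_factory=dict)
    lesions: list[tuple[tuple[int, int, int], int, str]] = field(default_factory=list)
    noise_sigma: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_time < 10:
            raise ValueError("n_time must be >= 10")
        if not self.tissues:
            self.tissues = {"NAWM": TissueParams()}
        if "NAWM" not in self.tissues:
            raise ValueError("a NAWM background tissue is required")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a simulated series."""

    label_map: np.ndarray                  # tissue name index per voxel
    label_names: list[str]
    concentration: dict[str, np.ndarray]   # noise-free c_τ(t)
    phases: dict[str, dict[str, int]]      # per-tissue onset/peak/minimum indices
    tois: list[TOI]
    reference_toi: TOI
    leakage_sign: np.ndarray               # +1 where the tissue leaks, else 0


def gamma_variate(t, t0: float, alpha: float, beta: float, amplitude: float) -> np.ndarray:
    """Peak-normalized gamma-variate bolus curve.

    ``c(t) = A * ((t-t0)/(alpha*beta))**alpha * exp(alpha - (t-t0)/beta)`` for
    ``t > t0`` and 0 before onset; the peak value is exactly ``A`` at
    ``t = t0 + alpha*beta``.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    m = t > t0
    x = (t[m] - t0) / (alpha * beta)
    out[m] = amplitude * x**alpha * np.exp(alpha - (t[m] - t0) / beta)
    return out


def tissue_concentration(params: TissueParams, t: np.ndarray) -> np.ndarray:
    """First pass plus recirculation bump (delayed, twice the scale)."""
    first = gamma_variate(t, params.t0, params.alpha, params.beta, params.amplitude)
    recirc = gamma_variate(
        t,
        params.t0 + params.recirc_delay,
        params.alpha,
        2.0 * params.beta,
        params.recirc_fraction * params.amplitude,
    )
    return first + recirc


def _cumulative_trapezoid(values: np.ndarray) -> np.ndarray:
    out = np.zeros_like(values)
    out[1:] = np.cumsum((values[1:] + values[:-1]) / 2.0)
    return out


def _truth_phases(curve: np.ndarray, t0: float) -> dict[str, int]:
    """Phase indices of a noise-free sampled curve, by the detection rules."""
    from .phases import detect_phases

    ph = detect_phases(curve, k_sigma=3.0, smooth_width=3)
    return {
        "t0": int(np.ceil(t0)),
        "toa": ph.toa,
        "t_peak": ph.t_peak,
        "t_min": ph.t_min,
    }


def simulate_phantom(config: PhantomConfig) -> tuple[DSCESeries, PhantomTruth]:
    """Simulate one examination; bit-identical output under a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n_sl, n_r, n_c = config.grid
    t = np.arange(config.n_time, dtype=float)

    label_names = list(config.tissues.keys())
    label_map = np.zeros(config.grid, dtype=int)  # 0 = NAWM background
    nawm_idx = label_names.index("NAWM")
    label_map[:] = nawm_idx
    for center, radius, tissue in config.lesions:
        if tissue not in config.tissues:
            raise ValueError(f"lesion tissue {tissue!r} has no parameters")
        cs, cr, cc = center
        if not (0 <= cs < n_sl and radius <= cr < n_r - radius and radius <= cc < n_c - radius):
            raise ValueError(f"lesion at {center} r={radius} outside the grid")
        rr, cc_grid = np.mgrid[0:n_r, 0:n_c]
        disk = (rr - cr) ** 2 + (cc_grid - cc) ** 2 <= radius**2
        label_map[cs][disk] = label_names.index(tissue)

    concentration = {}
    cumulative = {}
    phase_truth = {}
    for name in label_names:
        c = tissue_concentration(config.tissues[name], t)
        concentration[name] = c
        cumulative[name] = _cumulative_trapezoid(c)
        phase_truth[name] = _truth_phases(c, config.tissues[name].t0)

    signal = np.empty((config.n_time,) + config.grid, dtype=float)
    baseline = np.empty(config.grid, dtype=float)
    leak_sign = np.zeros(config.grid, dtype=int)
    decay = np.empty((config.n_time,) + config.grid, dtype=float)
    leak_term = np.zeros((config.n_time,) + config.grid, dtype=float)
    for idx, name in enumerate(label_names):
        params = config.tissues[name]
        where = label_map == idx
        baseline[where] = params.baseline_mean + rng.normal(
            0.0, params.texture_sd, int(where.sum())
        )
        decay[:, where] = np.exp(-config.te_ms * concentration[name])[:, None]
        leak_term[:, where] = (params.leakage * cumulative[name])[:, None]
        if params.leakage > 0:
            leak_sign[where] = 1
    signal = baseline[None] * decay + leak_term
    if config.noise_sigma > 0:
        signal = signal + rng.normal(0.0, config.noise_sigma, signal.shape)
    signal = np.clip(signal, 0.0, None)

    tois, reference = _phantom_tois(config, label_map, label_names)
    series = DSCESeries(
        signal=signal,
        te_ms=config.te_ms,
        tr_ms=config.tr_ms,
        provenance=f"dtpa phantom seed={config.seed}",
    )
    truth = PhantomTruth(
        label_map=label_map,
        label_names=label_names,
        concentration=concentration,
        phases=phase_truth,
        tois=tois,
        reference_toi=reference,
        leakage_sign=leak_sign,
    )
    return series, truth


def _phantom_tois(config, label_map, label_names) -> tuple[list[TOI], TOI]:
    """One TOI per lesion plus the NAWM reference strip."""
    n_sl, n_r, n_c = config.grid
    tois = []
    counters: dict[str, int] = {}
    for center, radius, tissue in config.lesions:
        counters[tissue] = counters.get(tissue, 0) + 1
        cs, cr, cc = center
        rr, cc_grid = np.mgrid[0:n_r, 0:n_c]
        disk = (rr - cr) ** 2 + (cc_grid - cc) ** 2 <= radius**2
        cls = {"NAWM_toi": "NAWM"}.get(tissue, tissue if tissue in ("EL", "NEL", "NAWM") else "OTHER")
        tois.append(
            TOI(
                label=f"{tissue}_{counters[tissue]:02d}",
                tissue_class=cls,
                mask=disk,
                slice_index=cs,
            )
        )
    reference = TOI(
        label="NAWM_reference",
        tissue_class="NAWM",
        mask=_reference_mask(config, label_map, label_names),
        slice_index=0,
    )
    return tois, reference


def _reference_mask(config, label_map, label_names) -> np.ndarray:
    """A background strip untouched by lesions, away from the image border."""
    n_sl, n_r, n_c = config.grid
    nawm_idx = label_names.index("NAWM")
    background = label_map[0] == nawm_idx
    for center, radius, _ in config.lesions:
        _, cr, cc = center
        rr, cc_grid = np.mgrid[0:n_r, 0:n_c]
        near = (rr - cr) ** 2 + (cc_grid - cc) ** 2 <= (radius + 2) ** 2
        background &= ~near
    strip = np.zeros((n_r, n_c), dtype=bool)
    strip[2:5, 4 : n_c - 4] = True
    mask = strip & background
    if mask.sum() < 8:
        raise ValueError("could not place a reference region clear of lesions")
    return mask


# ---------------------------------------------------------------------------
# canonical fixtures

#: lesion disk radius (voxels) used by the canonical fixtures
FIXTURE_RADIUS = 4
#: TOIs per tissue class in the canonical fixtures
FIXTURE_TOIS_PER_CLASS = 12


def _fixture_lesions() -> list[tuple[tuple[int, int, int], int, str]]:
    # 6x6 disk grid below the reference strip (rows 2-4); 12 TOIs per class
    row_centers = [14, 28, 42, 56, 70, 84]
    col_centers = [12, 26, 40, 54, 68, 82]
    classes = ("EL", "NEL", "NAWM_toi")
    lesions = []
    i = 0
    for r in row_centers:
        for c in col_centers:
            lesions.append(((0, r, c), FIXTURE_RADIUS, classes[i % 3]))
            i += 1
    return lesions


def null_phantom_config(seed: int = 0) -> PhantomConfig:
    """Fixture F1: three tissue classes with *identical* distributions.

    Lesion disks carry EL/NEL/NAWM labels but share every signal-model
    parameter with the background, so any detected group difference is a
    false positive.
    """
    base = TissueParams()
    tissues = {
        "NAWM": base,
        "EL": replace(base),
        "NEL": replace(base),
        "NAWM_toi": replace(base),
    }
    return PhantomConfig(tissues=tissues, lesions=_fixture_lesions(), seed=seed)


def effect_phantom_config(seed: int = 0, el_leakage: float = 600.0) -> PhantomConfig:
    """Fixture F2: enhancing lesions with elevated texture variance, earlier
    bolus onset and leakage; non-enhancing lesions mildly hypoperfused."""
    base = TissueParams()
    tissues = {
        "NAWM": base,
        "EL": replace(base, texture_sd=2 * base.texture_sd, t0=base.t0 - 1.5,
                      leakage=el_leakage),
        "NEL": replace(base, amplitude=0.75 * base.amplitude),
        "NAWM_toi": replace(base),
    }
    return PhantomConfig(tissues=tissues, lesions=_fixture_lesions(), seed=seed)


def cardiac_pair_configs(seed: int = 0, amplitude_scale: float = 1.5):
    """Fixture F3: the same anatomy with the bolus amplitude scaled, a
    surrogate for a different cardiac output.

    The pair is noise-free so the two series differ *only* in the bolus
    amplitude; what remains after cardiac-output normalization is the
    systematic residual of the exponential signal model, the quantity the
    paired comparison is meant to isolate.
    """
    lo = null_phantom_config(seed)
    lo = replace(lo, noise_sigma=0.0)
    hi_tissues = {
        name: replace(p, amplitude=amplitude_scale * p.amplitude)
        for name, p in lo.tissues.items()
    }
    hi = PhantomConfig(
        tissues=hi_tissues, lesions=list(lo.lesions), seed=seed, noise_sigma=0.0
    )
    return lo, hi


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the canonical fixture series, label rasters and manifests."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    configs = {
        "F1_null": null_phantom_config(seed),
        "F2_effect": effect_phantom_config(seed),
    }
    lo, hi = cardiac_pair_configs(seed)
    configs["F3_cardiac_lo"] = lo
    configs["F3_cardiac_hi"] = hi
    for name, config in configs.items():
        series, truth = simulate_phantom(config)
        nii = out_dir / f"{name}.nii"
        write_dsce_series(series, nii)
        write_toi_set(
            truth.tois + [truth.reference_toi], out_dir / f"{name}_labels.nii", config.grid
        )
        manifest = {
            "seed": config.seed,
            "grid": list(config.grid),
            "n_time": config.n_time,
            "noise_sigma": config.noise_sigma,
            "tissues": {k: asdict(v) for k, v in config.tissues.items()},
            "truth_phases": truth.phases,
        }
        (out_dir / f"{name}_manifest.json").write_text(json.dumps(manifest, indent=1))
        written[name] = nii
    return written
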