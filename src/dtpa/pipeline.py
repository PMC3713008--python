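"""End-to-end workflow: load, normalize, segment phases, map textures, test.

The stages mirror how the analysis is run on a real examination:

1. load the series and the TOI set (one NAWM reference region plus the
   analysis TOIs);
2. coil-load normalize the signal against the reference region;
3. build the difference series and the reference concentration curve;
4. detect the four bolus-passage intervals;
5. cardiac-output normalize the difference series;
6. compute the eight texture parameter maps;
7. extract the TOI record grid and the Δ-markers;
8. run the gated Wilcoxon battery and the significance-count summary.

Every configuration key is echoed into the report header so a run is fully
reproducible from its report plus the input files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .io import DSCESeries, StatReport, TOI, load_dsce_series, load_toi_set, write_stats_report
from .normalization import (
    cardiac_output_normalize,
    coil_load_normalize,
    compute_difference_series,
    concentration_curve,
)
from .phases import BolusPhases, detect_phases
from .texture import compute_all_tpms
from .toi_stats import build_record_table, delta_markers
from .group_stats import run_full_battery, summarize_counts


@dataclass
class RunConfig:
    """All tunable parameters of a workflow run."""

    input_path: str | None = None
    input_format: str = "nifti4d"
    toi_path: str | None = None
    reference_label: str = "NAWM_reference"
    c_ideal: float = 100.0
    auc_ref: float = 200.0
    baseline_index: int = 0
    kernel: int = 3
    degeneracy_eps: float | None = None
    vava_mode: str = "two_pass"
    k_sigma: float = 3.0
    smooth_width: int = 3
    gate_alpha: float = 0.05
    alpha: float = 0.05
    bh_scope: str = "per_cell"
    wilcoxon_mode: str = "normal_approx"
    te_ms: float | None = None
    tr_ms: float | None = None
    output_dir: str | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class WorkflowResult:
    """Everything a run produces, for programmatic use."""

    report: StatReport
    phases: BolusPhases
    counts: dict
    tpms: dict
    records: pd.DataFrame


def run_workflow(
    config: RunConfig,
    series: DSCESeries | None = None,
    tois: list[TOI] | None = None,
) -> WorkflowResult:
    """Execute the full analysis; ``series``/``tois`` may be passed in-memory
    (e.g. from the phantom generator) instead of being loaded from disk."""
    if series is None:
        if config.input_path is None:
            raise ValueError("stage load: no input path and no in-memory series")
        series = load_dsce_series(
            config.input_path, config.input_format, te_ms=config.te_ms, tr_ms=config.tr_ms
        )
    if tois is None:
        if config.toi_path is None:
            raise ValueError("stage load: no TOI path and no in-memory TOI set")
        tois = load_toi_set(config.toi_path, spatial_shape=series.spatial_shape)

    reference = [t for t in tois if t.label == config.reference_label]
    if len(reference) != 1:
        raise ValueError(
            f"stage normalize: need exactly one reference TOI labelled "
            f"{config.reference_label!r}, found {len(reference)}"
        )
    reference = reference[0]
    analysis_tois = [t for t in tois if t.label != config.reference_label]
    if not analysis_tois:
        raise ValueError("stage normalize: no analysis TOIs besides the reference region")

    normalized, coil_state = coil_load_normalize(
        series, reference, c_ideal=config.c_ideal, baseline_index=config.baseline_index
    )
    diff = compute_difference_series(normalized, baseline_index=config.baseline_index)
    curve = concentration_curve(normalized, reference, baseline_index=config.baseline_index)
    phases = detect_phases(curve, k_sigma=config.k_sigma, smooth_width=config.smooth_width)
    diff, auc_state = cardiac_output_normalize(diff, reference, phases, auc_ref=config.auc_ref)

    tpms = compute_all_tpms(
        normalized, diff, kernel=config.kernel,
        degeneracy_eps=config.degeneracy_eps, vava_mode=config.vava_mode,
    )
    records = build_record_table(tpms, analysis_tois, phases)
    deltas = delta_markers(records)
    tests = run_full_battery(
        records,
        gate_alpha=config.gate_alpha,
        alpha=config.alpha,
        bh_scope=config.bh_scope,
        wilcoxon_mode=config.wilcoxon_mode,
    )
    counts = summarize_counts(tests, alpha=config.alpha)

    header = {k: v for k, v in asdict(config).items() if k != "extra"}
    header.update(
        coil_factor=coil_state.coil_factor,
        auc_factor=auc_state.auc_factor,
        toa=phases.toa,
        t_peak=phases.t_peak,
        t_min=phases.t_min,
    )
    report = StatReport(
        records=records, test_results=tests, delta_markers=deltas, header=header
    )
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_stats_report(report, out / "records.tsv")
        counts["counts"].to_csv(out / "significance_counts.tsv", sep="\t")
        with open(out / "summary.txt", "w") as fh:
            fh.write(
                f"cells_per_tpm\t{counts['cells_per_tpm']}\n"
                f"n_tests_possible\t{counts['n_tests_possible']}\n"
                f"expected_false_positives\t{counts['expected_false_positives']}\n"
                f"n_significant\t{counts['n_significant']}\n"
            )
    return WorkflowResult(
        report=report, phases=phases, counts=counts, tpms=tpms, records=records
    )
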