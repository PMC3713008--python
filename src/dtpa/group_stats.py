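"""ANOVA-gated pairwise Wilcoxon rank-sum battery with BH correction.

Every cell of the analysis grid -- one (TPM type, statistic, interval)
combination -- holds one value per TOI.  Grouped by tissue class, a cell is
first screened with a one-way fixed-effects ANOVA F-test (used purely as a
gate despite the non-normality of texture parameters); when the gate passes,
the three pairwise two-sided Wilcoxon rank-sum tests (NAWM vs EL, NAWM vs
NEL, NEL vs EL) are run and Benjamini-Hochberg adjusted.  The default BH
family is the three pairwise tests of one cell; per-TPM (72 p-values) and
global (576) scopes are selectable.

The exact rank-sum p-value enumerates all assignments of the pooled sample
(mid-ranks under ties), so it doubles as a permutation test; the normal
approximation uses the tie-corrected variance with continuity correction.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

from .phases import INTERVALS
from .toi_stats import STATISTICS
from .texture import TPM_TYPES

PAIRS = (("NAWM", "EL"), ("NAWM", "NEL"), ("NEL", "EL"))
PAIR_NAMES = tuple(f"{a}_vs_{b}" for a, b in PAIRS)

TEST_COLUMNS = (
    ["tpm_type", "statistic", "interval", "anova_p", "gated"]
    + [f"p_raw_{p}" for p in PAIR_NAMES]
    + [f"p_adj_{p}" for p in PAIR_NAMES]
    + [f"significant_{p}" for p in PAIR_NAMES]
)


def anova_gate(groups: list[np.ndarray]) -> float:
    """One-way fixed-effects ANOVA F-test p-value across the groups.

    Returns NaN (undetermined, test skipped) when any group has fewer than
    two finite values.
    """
    clean = [np.asarray(g, dtype=float) for g in groups]
    clean = [g[np.isfinite(g)] for g in clean]
    if any(len(g) < 2 for g in clean):
        return np.nan
    if all(np.ptp(g) == 0 for g in clean) and len({g[0] for g in clean}) == 1:
        return 1.0  # all values identical: F = 0/0
    k = len(clean)
    N = sum(len(g) for g in clean)
    grand = np.concatenate(clean).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in clean)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in clean)
    if ss_within == 0:
        return 0.0 if ss_between > 0 else 1.0
    f_stat = (ss_between / (k - 1)) / (ss_within / (N - k))
    return float(stats.f.sf(f_stat, k - 1, N - k))


def wilcoxon_rank_sum(a, b, mode: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    ``mode='exact'`` enumerates all C(n+m, n) group assignments of the pooled
    mid-ranks (feasible for n+m <= 12); ``'normal_approx'`` uses the normal
    approximation with tie-corrected variance and continuity correction;
    ``'auto'`` picks exact when feasible.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    if mode == "auto":
        mode = "exact" if a.size + b.size <= 12 else "normal_approx"
    if mode == "exact":
        return _exact_rank_sum_p(a, b)
    if mode == "normal_approx":
        return _approx_rank_sum_p(a, b)
    raise ValueError(f"unknown mode {mode!r}")


def _approx_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Normal approximation with tie-corrected variance and continuity
    correction; matches the conventional large-sample rank-sum test."""
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = ranks[:n].sum()
    mu = n * (n + m + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    N = n + m
    var = n * m / 12.0 * (N + 1 - tie_term / (N * (N - 1)))
    if var <= 0:
        return 1.0
    d = w - mu
    z = (abs(d) - 0.5) / math.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    n, m = len(a), len(b)
    if n + m > 16:
        raise ValueError("exact enumeration limited to n+m <= 16")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # mid-ranks under ties
    w_obs = ranks[:n].sum()
    count_le = count_ge = total = 0
    for combo in itertools.combinations(range(n + m), n):
        w = ranks[list(combo)].sum()
        total += 1
        if w <= w_obs + 1e-9:
            count_le += 1
        if w >= w_obs - 1e-9:
            count_ge += 1
    return min(1.0, 2.0 * min(count_le, count_ge) / total)


def bh_adjust(pvals, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    ``m`` is the family size (defaults to the number of p-values); adjusted
    values are ``min over j >= i of min(1, m * p_(j) / j)`` on the sorted
    sequence.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty_like(adj)
    out[order] = adj
    return out


def run_full_battery(
    records: pd.DataFrame,
    gate_alpha: float = 0.05,
    alpha: float = 0.05,
    bh_scope: str = "per_cell",
    wilcoxon_mode: str = "normal_approx",
) -> pd.DataFrame:
    """Run the gated test battery over every cell of the record grid.

    Undetermined records are excluded before grouping; cells whose gate is
    undetermined or not passed carry NaN pairwise entries.  ``bh_scope`` is
    one of ``per_cell`` (the three pairwise p-values of a cell), ``per_tpm``
    or ``global``.
    """
    if bh_scope not in ("per_cell", "per_tpm", "global"):
        raise ValueError(f"unknown bh_scope {bh_scope!r}")
    usable = records[~records["undetermined"].astype(bool)]
    rows = []
    for (tpm_type, statistic, interval), cell in usable.groupby(
        ["tpm_type", "statistic", "interval"], sort=False
    ):
        by_class = {
            cls: cell[cell.tissue_class == cls]["value"].to_numpy(dtype=float)
            for cls in ("NAWM", "EL", "NEL")
        }
        anova_p = anova_gate(list(by_class.values()))
        gated = bool(np.isfinite(anova_p) and anova_p < gate_alpha)
        row = {
            "tpm_type": tpm_type,
            "statistic": statistic,
            "interval": interval,
            "anova_p": anova_p,
            "gated": gated,
        }
        for (ca, cb), name in zip(PAIRS, PAIR_NAMES):
            if gated and by_class[ca].size and by_class[cb].size:
                row[f"p_raw_{name}"] = wilcoxon_rank_sum(
                    by_class[ca], by_class[cb], mode=wilcoxon_mode
                )
            else:
                row[f"p_raw_{name}"] = np.nan
        rows.append(row)
    results = pd.DataFrame(rows)
    if results.empty:
        return pd.DataFrame(columns=TEST_COLUMNS)

    raw_cols = [f"p_raw_{p}" for p in PAIR_NAMES]
    adj_cols = [f"p_adj_{p}" for p in PAIR_NAMES]
    results[adj_cols] = np.nan
    if bh_scope == "per_cell":
        for i in results.index:
            raw = results.loc[i, raw_cols].to_numpy(dtype=float)
            finite = np.isfinite(raw)
            if finite.any():
                adj = np.full(3, np.nan)
                adj[finite] = bh_adjust(raw[finite])
                results.loc[i, adj_cols] = adj
    else:
        if bh_scope == "per_tpm":
            groups = [g.index for _, g in results.groupby("tpm_type", sort=False)]
        else:
            groups = [results.index]
        for idx in groups:
            raw = results.loc[idx, raw_cols].to_numpy(dtype=float)
            finite = np.isfinite(raw)
            if finite.any():
                adj = np.full(raw.shape, np.nan)
                adj[finite] = bh_adjust(raw[finite])
                results.loc[idx, adj_cols] = adj
    for name in PAIR_NAMES:
        results[f"significant_{name}"] = results[f"p_adj_{name}"] < alpha
    return results[TEST_COLUMNS]


def summarize_counts(results: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Significance counts in the TPM-by-interval layout, plus the battery size.

    Returns a dict with the counts table (rows = TPM types, columns = the
    four intervals and their total), the number of analysis cells per TPM,
    the number of possible pairwise tests, and the expected false-positive
    count ``n_tests_possible * alpha`` under a global null.
    """
    if results is None or len(results) == 0:
        raise ValueError("empty results table")
    sig_cols = [f"significant_{p}" for p in PAIR_NAMES]
    counts = pd.DataFrame(0, index=list(TPM_TYPES), columns=list(INTERVALS) + ["Total"])
    for _, row in results.iterrows():
        n_sig = int(sum(bool(row[c]) for c in sig_cols))
        counts.loc[row.tpm_type, row.interval] += n_sig
    counts["Total"] = counts[list(INTERVALS)].sum(axis=1)
    counts.loc["Total"] = counts.sum(axis=0)

    n_classes = 3
    cells_per_tpm = len(STATISTICS) * len(INTERVALS) * n_classes
    n_tests_possible = len(TPM_TYPES) * len(STATISTICS) * len(INTERVALS) * len(PAIRS)
    return {
        "counts": counts,
        "cells_per_tpm": cells_per_tpm,
        "n_tests_possible": n_tests_possible,
        "expected_false_positives": n_tests_possible * alpha,
        "n_significant": int(counts.loc["Total", "Total"]),
    }
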