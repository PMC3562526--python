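"""Two-group differential expression and mask-threshold optimization.

DE calling follows the conventional heterologous-chip analysis: per
probe-set log2 fold change between condition means, a one-way ANOVA F-test
(identical to a two-sided pooled-variance t-test for two groups),
Benjamini-Hochberg FDR adjustment, and a joint fold-change + p cut
(default: fold > 1.25, p <= 0.05 on the adjusted scale).

The mask threshold itself is chosen by the number of DE probe-sets it
yields: too low and diverged probes dilute real signal, too high and too
few probes remain — the count peaks at an intermediate threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from xspecies.chip_model import ChipLayout, DETable, ExpressionMatrix, ProbeIntensityTable
from xspecies.masking import apply_mask, build_mask
from xspecies.summarize import RmaOptions, rma

VARIANCE_FLOOR = 1e-12  # pooled within-group variance floor for noiseless fixtures


@dataclass
class DEOptions:
    """Selection rule: ``|log2fc| > log2(fc_min)`` and ``p <= p_max``.

    ``use_adjusted`` switches the p cut between BH-adjusted (default) and
    raw p-values; ``group_labels`` = (reference condition, treatment
    condition), fold changes are treatment minus reference on log2.
    """

    fc_min: float = 1.25
    p_max: float = 0.05
    use_adjusted: bool = True
    group_labels: tuple[str, str] = ("unripe", "ripe")

    def __post_init__(self) -> None:
        if not self.fc_min > 1:
            raise ValueError(f"fc_min must be > 1, got {self.fc_min}")
        if not 0 < self.p_max < 1:
            raise ValueError(f"p_max must be in (0, 1), got {self.p_max}")

    @property
    def log2fc_cut(self) -> float:
        return float(np.log2(self.fc_min))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} p_(j) * m / j``, capped at 1, mapped back to the
    input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def de_test(expr: ExpressionMatrix, options: DEOptions | None = None) -> DETable:
    """Per-probe-set two-group DE calling on a log2 expression matrix."""
    options = options or DEOptions()
    ref, trt = options.group_labels
    present = set(expr.conditions)
    if not {ref, trt} <= present:
        raise ValueError(f"conditions {options.group_labels} not both present in {sorted(present)}")
    a = expr.group_columns(ref)
    b = expr.group_columns(trt)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 arrays, got {n1} and {n2}")

    mean1, mean2 = a.mean(axis=1), b.mean(axis=1)
    log2fc = mean2 - mean1
    # one-way ANOVA with 2 groups == pooled-variance two-sided t-test
    ss_within = ((a - mean1[:, None]) ** 2).sum(axis=1) + ((b - mean2[:, None]) ** 2).sum(axis=1)
    df_within = n1 + n2 - 2
    msw = ss_within / df_within
    floored = msw < VARIANCE_FLOOR
    msw = np.maximum(msw, VARIANCE_FLOOR)
    ss_between = (n1 * n2 / (n1 + n2)) * log2fc ** 2
    f_stat = ss_between / msw
    p_raw = stats.f.sf(f_stat, 1, df_within)
    p_adj = bh_adjust(p_raw)

    p_for_cut = p_adj if options.use_adjusted else p_raw
    selected = (np.abs(log2fc) > options.log2fc_cut) & (p_for_cut <= options.p_max)
    direction = np.where(selected & (log2fc > 0), "up", np.where(selected & (log2fc < 0), "down", "flat"))

    frame = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": direction,
            "selected": selected,
            "variance_floored": floored,
        },
        index=pd.Index(expr.probe_set_ids, name="probe_set_id"),
    )
    return DETable(frame)


@dataclass
class OptimizationResult:
    """DE counts along a mask-threshold sweep and the winning threshold."""

    thresholds: list[float]
    de_counts: list[int]
    best_threshold: float = field(init=False)
    best_count: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.de_counts) or not self.thresholds:
            raise ValueError("thresholds and de_counts must be non-empty and equal length")
        best = int(np.argmax(self.de_counts))  # argmax takes the first (smallest) on ties
        self.best_count = int(self.de_counts[best])
        self.best_threshold = float(self.thresholds[best])


def optimize_mask_threshold(
    gdna: Sequence[ProbeIntensityTable],
    rna: Sequence[ProbeIntensityTable],
    layout: ChipLayout,
    thresholds: Sequence[float],
    options: DEOptions | None = None,
    rma_options: RmaOptions | None = None,
) -> OptimizationResult:
    """Count DE probe-sets at each mask threshold; pick the maximizer.

    A threshold that eliminates every probe-set contributes a count of 0.
    Ties resolve to the smallest threshold (most probes retained).
    """
    thresholds = [float(t) for t in thresholds]
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    counts = []
    for t in thresholds:
        mask = build_mask(gdna, layout, t)
        if not mask.retained_sets:
            counts.append(0)
            continue
        masked = apply_mask(layout, mask)
        expr = rma(list(rna), masked, rma_options)
        counts.append(de_test(expr, options).n_selected)
    return OptimizationResult(thresholds=thresholds, de_counts=counts)
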