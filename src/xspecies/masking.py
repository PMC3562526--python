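"""Genomic-DNA-based probe masking.

A probe-pair is retained when its PM signal on the gDNA hybridization
exceeds a threshold (strict ``>``); a probe-set is retained when at least
two of its pairs survive.  Several gDNA arrays are combined by the
arithmetic mean of their PM intensities before thresholding.  Sweeping the
threshold yields retention curves: pair counts fall fast as diverged probes
drop out, set counts fall more slowly because a set only dies once it is
down to fewer than two pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from xspecies.chip_model import ChipLayout, ProbeIntensityTable, ProbeMask


@dataclass
class RetentionCurve:
    """Counts of retained probe-pairs and probe-sets along a threshold sweep."""

    thresholds: list[float]
    n_pairs_retained: list[int]
    n_sets_retained: list[int]

    def __post_init__(self) -> None:
        if not (len(self.thresholds) == len(self.n_pairs_retained) == len(self.n_sets_retained)):
            raise ValueError("retention curve series must have equal length")
        if any(b > a for a, b in zip(self.n_pairs_retained, self.n_pairs_retained[1:])):
            raise ValueError("pair counts must be non-increasing in threshold")
        if any(b > a for a, b in zip(self.n_sets_retained, self.n_sets_retained[1:])):
            raise ValueError("set counts must be non-increasing in threshold")


DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(float(t) for t in range(0, 501, 25))
"""Conventional sweep lattice 0, 25, ..., 500."""


def _mean_gdna(gdna: Sequence[ProbeIntensityTable], pm_indices: Sequence[int]) -> np.ndarray:
    if not gdna:
        raise ValueError("at least one gDNA intensity table is required")
    stack = np.stack([t.values_for(pm_indices) for t in gdna])
    return stack.mean(axis=0)


def build_mask(
    gdna: Sequence[ProbeIntensityTable], layout: ChipLayout, threshold: float
) -> ProbeMask:
    """Mask the layout at one gDNA intensity threshold.

    A pair survives iff its mean-across-arrays PM intensity is strictly
    greater than ``threshold`` (ties at the threshold are dropped); a set
    survives iff it keeps >= 2 pairs.  Invariant to gDNA array order.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    pm_indices = layout.pm_indices()
    mean_signal = _mean_gdna(gdna, pm_indices)
    keep = dict(zip(pm_indices, mean_signal > threshold))
    retained_pairs = {
        ps_id: [p.pair_rank for p in pairs if keep[p.pm_index]]
        for ps_id, pairs in layout.probe_sets.items()
    }
    return ProbeMask(threshold=float(threshold), retained_pairs=retained_pairs)


def retention_curve(
    gdna: Sequence[ProbeIntensityTable],
    layout: ChipLayout,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> RetentionCurve:
    """Pair/set retention counts at each threshold of a strictly increasing sweep."""
    thresholds = [float(t) for t in thresholds]
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    pm_indices = layout.pm_indices()
    mean_signal = _mean_gdna(gdna, pm_indices)
    set_sizes = np.array([len(p) for p in layout.probe_sets.values()])
    bounds = np.cumsum(np.concatenate([[0], set_sizes]))
    n_pairs, n_sets = [], []
    for t in thresholds:
        keep = mean_signal > t
        per_set = np.add.reduceat(keep.astype(int), bounds[:-1])
        n_pairs.append(int(keep.sum()))
        n_sets.append(int((per_set >= 2).sum()))
    return RetentionCurve(thresholds, n_pairs, n_sets)


def apply_mask(layout: ChipLayout, mask: ProbeMask) -> ChipLayout:
    """Filtered copy of ``layout`` keeping exactly the mask's retained sets/pairs.

    Pair order and original pair ranks are preserved, so retained pairs stay
    identifiable by rank (ranks may be non-contiguous after masking).
    """
    unknown = set(mask.retained_pairs) - set(layout.probe_sets)
    if unknown:
        raise ValueError(f"mask references probe-set(s) absent from layout: {sorted(unknown)[:3]}")
    if not mask.retained_sets:
        raise ValueError(
            f"mask at threshold {mask.threshold} retains no probe-set; refusing to build an empty layout"
        )
    probe_sets = {}
    for ps_id in layout.probe_sets:
        if ps_id not in mask.retained_sets:
            continue
        wanted = set(mask.retained_pairs[ps_id])
        probe_sets[ps_id] = [p for p in layout.probe_sets[ps_id] if p.pair_rank in wanted]
    return ChipLayout(probe_sets=probe_sets, chip_name=f"{layout.chip_name}|mask>{mask.threshold:g}")
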