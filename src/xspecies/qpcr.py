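"""Relative-standard-curve qPCR quantification.

For each gene a dilution series of known (relative) template quantity gives
a standard curve ``Ct = slope * log10(quantity) + intercept``; amplification
efficiency is ``E = 10**(-1/slope) - 1`` (100% means perfect doubling per
cycle; slope -3.3219 = -1/log10(2)).  Unknown samples are quantified by
inverting the curve, normalized to the geometric mean of the reference-gene
quantities (dual references, e.g. actin + 18S rRNA), and scaled so the
calibrator sample (first day after harvest) is exactly 1.  Significance
across time points comes from one-way ANOVA with Tukey's HSD (Tukey-Kramer
for unbalanced groups) at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class StandardCurve:
    slope: float
    intercept: float
    r2: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, fraction: 1.0 means 100% (doubling)."""
        return float(10.0 ** (-1.0 / self.slope) - 1.0)


@dataclass(frozen=True)
class QpcrMeasurement:
    gene: str
    sample: str
    replicate: int
    ct: float

    def __post_init__(self) -> None:
        if not self.ct > 0:
            raise ValueError(f"Ct must be > 0, got {self.ct}")


def fit_standard_curve(dilutions: Sequence[tuple[float, float]]) -> StandardCurve:
    """OLS fit of Ct on log10 quantity over a dilution series (>= 3 distinct points)."""
    pts = np.asarray(dilutions, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("dilutions must be (log10_quantity, ct) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct dilution points")
    res = stats.linregress(x, y)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r2=float(res.rvalue ** 2))


def quantify(ct: float | np.ndarray, curve: StandardCurve) -> float | np.ndarray:
    """Invert the standard curve: ``quantity = 10**((ct - intercept)/slope)``."""
    if curve.slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {curve.slope}")
    q = 10.0 ** ((np.asarray(ct, dtype=float) - curve.intercept) / curve.slope)
    return float(q) if np.isscalar(ct) else q


def average_technical_replicates(measurements: Sequence[QpcrMeasurement]) -> dict[tuple[str, str], float]:
    """Mean Ct per (gene, sample); technical replicates are averaged at the Ct level."""
    acc: dict[tuple[str, str], list[float]] = {}
    for m in measurements:
        acc.setdefault((m.gene, m.sample), []).append(m.ct)
    for key, cts in acc.items():
        if len(cts) < 2:
            raise ValueError(f"(gene, sample) {key} has {len(cts)} replicate(s); need >= 2")
    return {key: float(np.mean(cts)) for key, cts in acc.items()}


def relative_expression(
    target: Mapping[str, float],
    references: Mapping[str, Mapping[str, float]],
    calibrator: str,
) -> dict[str, float]:
    """Normalize target quantities by reference genes and scale to the calibrator.

    ``normalized(s) = target(s) / geometric_mean(reference quantities at s)``;
    ``relative(s) = normalized(s) / normalized(calibrator)`` so the
    calibrator is exactly 1.  Invariant to rescaling any one gene's
    quantities by a constant (arbitrary units cancel).
    """
    if calibrator not in target:
        raise ValueError(f"calibrator sample {calibrator!r} missing from target quantities")
    normalized: dict[str, float] = {}
    for sample, q in target.items():
        refs = []
        for gene, per_sample in references.items():
            if sample not in per_sample:
                raise ValueError(f"reference gene {gene!r} has no quantity for sample {sample!r}")
            r = per_sample[sample]
            if r <= 0:
                raise ValueError(f"non-positive reference quantity for {gene!r} at {sample!r}")
            refs.append(r)
        if not refs:
            raise ValueError("at least one reference gene is required")
        normalized[sample] = q / float(np.exp(np.mean(np.log(refs))))
    cal = normalized[calibrator]
    out = {s: v / cal for s, v in normalized.items()}
    out[calibrator] = 1.0
    return out


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    pairwise_p: dict[tuple[str, str], float]
    significant: dict[tuple[str, str], bool]
    differs_from_calibrator: dict[str, bool]


def anova_tukey(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    calibrator: str | None = None,
) -> AnovaTukeyResult:
    """One-way ANOVA across samples plus Tukey HSD pairwise comparisons.

    ``differs_from_calibrator`` flags each sample whose Tukey p against the
    calibrator (default: the first group) is below ``alpha``.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs >= 2 replicates")
    if calibrator is None:
        calibrator = names[0]
    if calibrator not in names:
        raise ValueError(f"calibrator {calibrator!r} not among groups")

    if np.ptp(np.concatenate(arrays)) == 0:
        f_stat, p_val = 0.0, 1.0
        pairwise = {tuple(sorted((a, b))): 1.0 for a in names for b in names if a < b}
    else:
        f_stat, p_val = stats.f_oneway(*arrays)
        hsd = stats.tukey_hsd(*arrays)
        pairwise = {}
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    pairwise[(a, b)] = float(hsd.pvalue[i, j])
    significant = {pair: p < alpha for pair, p in pairwise.items()}
    differs = {}
    for n in names:
        if n == calibrator:
            differs[n] = False
        else:
            pair = (n, calibrator) if (n, calibrator) in pairwise else (calibrator, n)
            differs[n] = significant[pair]
    return AnovaTukeyResult(float(f_stat), float(p_val), pairwise, significant, differs)


# ---------------------------------------------------------------------------
# CSV I/O: `gene,sample,replicate,ct` and `gene,log10_quantity,ct`
# ---------------------------------------------------------------------------

def read_ct_table(path: str | Path) -> list[QpcrMeasurement]:
    df = pd.read_csv(path)
    expected = {"gene", "sample", "replicate", "ct"}
    if not expected <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(expected)}, got {list(df.columns)}")
    return [
        QpcrMeasurement(gene=str(r.gene), sample=str(r.sample), replicate=int(r.replicate), ct=float(r.ct))
        for r in df.itertuples(index=False)
    ]


def read_dilutions(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    df = pd.read_csv(path)
    expected = {"gene", "log10_quantity", "ct"}
    if not expected <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(expected)}, got {list(df.columns)}")
    out: dict[str, list[tuple[float, float]]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.gene), []).append((float(r.log10_quantity), float(r.ct)))
    return out
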