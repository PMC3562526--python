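"""Downstream analysis of the DE probe-sets.

* chord-distance complete-linkage hierarchical clustering of expression
  profiles (the distance between unit-normalized vectors, so only the
  *shape* of a profile matters, not its level);
* partition of the selected probe-sets into up- and down-regulated halves;
* Wilcoxon (Mann-Whitney) rank-sum enrichment of functional bins: are a
  bin's members shifted in log2 fold change relative to everything else;
* cross-platform comparison of up-regulated gene sets (Venn cells) at a
  log2 fold-change threshold.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy import stats

from xspecies.chip_model import AnnotationMap, DETable
from xspecies.diffexpr import bh_adjust

EXACT_MAX_N = 8  # exact rank-sum enumeration up to this group size (no ties)


def chord_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance between the unit-normalized vectors.

    Equals ``sqrt(2 - 2 cos(theta))``; range [0, 2]; invariant to positive
    rescaling of either argument.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("chord distance is undefined for a zero vector")
    return float(np.linalg.norm(x / nx - y / ny))


@dataclass
class ClusterResult:
    probe_set_ids: list[str]
    labels: list[int]
    k: int
    merge_history: list[tuple[int, int, float]]

    def members(self, label: int) -> list[str]:
        return [p for p, l in zip(self.probe_set_ids, self.labels) if l == label]


def hcluster(expr_rows: np.ndarray, probe_set_ids: list[str], k: int) -> ClusterResult:
    """Complete-linkage agglomeration under chord distance, cut at ``k`` clusters.

    Deterministic given the input row order (scipy's nearest-neighbor-chain
    agglomeration order breaks distance ties reproducibly).
    """
    rows = np.asarray(expr_rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] != len(probe_set_ids):
        raise ValueError("expr_rows must be 2-D with one row per probe-set ID")
    n = rows.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    norms = np.linalg.norm(rows, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero row vector: chord distance undefined")
    unit = rows / norms[:, None]
    if n == 1:
        return ClusterResult(list(probe_set_ids), [1], 1, [])
    dist = pdist(unit, metric="euclidean")
    linkage = hierarchy.linkage(dist, method="complete")
    labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    history = [(int(a), int(b), float(h)) for a, b, h, _ in linkage]
    return ClusterResult(list(probe_set_ids), [int(l) for l in labels], int(labels.max()), history)


def partition_direction(de: DETable) -> tuple[set[str], set[str]]:
    """Selected probe-sets split by fold-change sign: ``(up, down)``."""
    f = de.frame
    up = set(f.index[f["selected"] & (f["log2fc"] > 0)])
    down = set(f.index[f["selected"] & (f["log2fc"] < 0)])
    return up, down


@dataclass
class BinEnrichment:
    bin: str
    n_members: int
    statistic: float
    p_raw: float
    p_adj: float
    direction: str


def wilcoxon_bin_enrichment(
    log2fc: dict[str, float],
    annotation: AnnotationMap,
    min_bin_size: int = 3,
) -> list[BinEnrichment]:
    """Rank-sum enrichment of every functional bin with >= ``min_bin_size`` members.

    Two-sided Mann-Whitney U of member log2 fold changes against all
    non-member values; exact enumeration when the smaller group has <= 8
    values and there are no ties, otherwise the tie-corrected normal
    approximation with continuity correction.  BH adjustment across bins.
    """
    ids = list(log2fc)
    values = np.array([log2fc[i] for i in ids], dtype=float)
    bins: dict[str, list[int]] = {}
    for pos, ps_id in enumerate(ids):
        for b in annotation.bins_of(ps_id):
            bins.setdefault(b, []).append(pos)

    results: list[BinEnrichment] = []
    raw_ps: list[float] = []
    for b in sorted(bins):
        members = np.array(bins[b], dtype=int)
        if members.size < min_bin_size:
            continue
        other = np.setdiff1d(np.arange(len(ids)), members)
        if other.size == 0:
            raise ValueError(f"bin {b!r} contains every annotated gene; enrichment undefined")
        mv, ov = values[members], values[other]
        no_ties = np.unique(np.concatenate([mv, ov])).size == mv.size + ov.size
        method = "exact" if (min(mv.size, ov.size) <= EXACT_MAX_N and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(mv, ov, alternative="two-sided", method=method, use_continuity=True)
        direction = "up" if np.median(mv) > np.median(ov) else "down"
        results.append(BinEnrichment(b, int(mv.size), float(res.statistic), float(res.pvalue), np.nan, direction))
        raw_ps.append(float(res.pvalue))

    if results:
        for r, q in zip(results, bh_adjust(raw_ps)):
            r.p_adj = float(q)
    return results


@dataclass
class VennResult:
    """Per-species up-regulated gene sets and all Venn cell counts.

    ``cells`` maps each non-empty species combination (a sorted tuple) to
    the number of genes up-regulated in exactly those species.
    """

    up_sets: dict[str, set[str]]
    cells: dict[tuple[str, ...], int]

    def exclusive(self, species: str) -> int:
        return self.cells.get((species,), 0)


def compare_up_sets(
    tables: dict[str, dict[str, float]],
    log2_threshold: float = 0.3,
) -> VennResult:
    """Venn decomposition of up-regulated gene sets across platforms.

    A gene is up-regulated for a species when its log2 fold change is
    >= ``log2_threshold``.  Genes are matched across platforms by shared
    identifier.  If no identifier is shared by all tables a warning is
    emitted and the (all-zero intersection) counts are still returned.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 species tables")
    up_sets = {
        sp: {g for g, fc in table.items() if fc >= log2_threshold}
        for sp, table in tables.items()
    }
    shared = set.intersection(*(set(t) for t in tables.values()))
    if not shared:
        warnings.warn("no gene identifier is shared by all platforms; intersections will be empty",
                      stacklevel=2)
    species = list(tables)
    cells: dict[tuple[str, ...], int] = {}
    for r in range(1, len(species) + 1):
        for combo in itertools.combinations(species, r):
            inside = set.intersection(*(up_sets[s] for s in combo))
            outside = set.union(set(), *(up_sets[s] for s in species if s not in combo))
            cells[tuple(combo)] = len(inside - outside)
    return VennResult(up_sets=up_sets, cells=cells)
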