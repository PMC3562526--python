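"""Domain types and plain-text I/O for chip data.

The Affymetrix binary containers are replaced by documented TSV dialects:
a *layout* file stands in for the CDF (probe-set -> ordered probe-pairs),
an *intensity* file stands in for a CEL (probe index -> fluorescence), and
expression matrices, annotation maps, probe masks and DE tables are TSV as
well.  All files are UTF-8, tab-delimited, with ``NA`` for absent values.
Probe indices are 0-based; pair ranks are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ChipFormatError(ValueError):
    """A file violates the documented TSV dialect or a type invariant."""


class CoverageError(ValueError):
    """An intensity table does not cover every PM probe of its layout."""


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbePair:
    """One PM/MM probe pair; ``mm_index`` is ``None`` when the chip has no MM."""

    pm_index: int
    mm_index: int | None
    pair_rank: int

    def __post_init__(self) -> None:
        if self.pair_rank < 1:
            raise ChipFormatError(f"pair_rank must be >= 1, got {self.pair_rank}")


@dataclass
class ChipLayout:
    """Mapping from probe-set IDs to their ordered probe-pairs (the CDF stand-in)."""

    probe_sets: dict[str, list[ProbePair]]
    chip_name: str = "synthetic-chip"

    def __post_init__(self) -> None:
        seen_pm: set[int] = set()
        for ps_id, pairs in self.probe_sets.items():
            if not pairs:
                raise ChipFormatError(f"probe-set {ps_id!r} has no probe-pairs")
            ranks = [p.pair_rank for p in pairs]
            # strictly increasing from >=1; masked layouts keep original,
            # possibly non-contiguous, ranks
            if ranks[0] < 1 or any(b <= a for a, b in zip(ranks, ranks[1:])):
                raise ChipFormatError(
                    f"probe-set {ps_id!r}: pair_ranks {ranks} not strictly increasing from >= 1"
                )
            for p in pairs:
                if p.pm_index in seen_pm:
                    raise ChipFormatError(
                        f"pm_index {p.pm_index} referenced by more than one probe-pair"
                    )
                seen_pm.add(p.pm_index)

    @property
    def n_probe_sets(self) -> int:
        return len(self.probe_sets)

    @property
    def n_pairs(self) -> int:
        return sum(len(v) for v in self.probe_sets.values())

    def pm_indices(self) -> list[int]:
        """All PM probe indices in layout order."""
        return [p.pm_index for pairs in self.probe_sets.values() for p in pairs]


@dataclass
class ProbeIntensityTable:
    """Per-array probe-level intensities (the CEL stand-in).

    ``kind`` is ``"gdna"`` for a genomic-DNA hybridization, ``"rna"`` for a
    cRNA hybridization; ``condition`` labels the biological group of an RNA
    array (empty for gDNA).
    """

    array_id: str
    kind: str
    condition: str
    intensities: dict[int, float]

    def __post_init__(self) -> None:
        if self.kind not in ("gdna", "rna"):
            raise ChipFormatError(f"kind must be 'gdna' or 'rna', got {self.kind!r}")
        for idx, v in self.intensities.items():
            if v < 0:
                raise ChipFormatError(
                    f"array {self.array_id!r}: negative intensity {v} at probe {idx}"
                )

    def values_for(self, indices: Sequence[int]) -> np.ndarray:
        """Intensities at ``indices`` as a float array; missing probes raise."""
        try:
            return np.array([self.intensities[i] for i in indices], dtype=float)
        except KeyError as exc:
            raise CoverageError(
                f"array {self.array_id!r} missing probe index {exc.args[0]}"
            ) from None

    def check_covers(self, layout: ChipLayout) -> None:
        missing = [i for i in layout.pm_indices() if i not in self.intensities]
        if missing:
            raise CoverageError(
                f"array {self.array_id!r} missing {len(missing)} PM probe(s) of "
                f"layout {layout.chip_name!r}; first missing index {missing[0]}"
            )


@dataclass
class ProbeMask:
    """Per-threshold record of probe-pairs and probe-sets retained by gDNA masking."""

    threshold: float
    retained_pairs: dict[str, list[int]]
    retained_sets: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        expected = {s for s, ranks in self.retained_pairs.items() if len(ranks) >= 2}
        if not self.retained_sets:
            self.retained_sets = expected
        elif self.retained_sets != expected:
            raise ChipFormatError(
                "retained_sets must equal the probe-sets keeping >= 2 pairs"
            )


@dataclass
class ExpressionMatrix:
    """Probe-set x array matrix of log2 expression with condition labels."""

    probe_set_ids: list[str]
    array_ids: list[str]
    conditions: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_set_ids), len(self.array_ids)):
            raise ChipFormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_set_ids)} probe-sets x {len(self.array_ids)} arrays"
            )
        if len(self.conditions) != len(self.array_ids):
            raise ChipFormatError("one condition label required per array")
        if not np.all(np.isfinite(self.values)):
            raise ChipFormatError("expression matrix contains non-finite cells")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_set_ids, columns=self.array_ids)

    def group_columns(self, condition: str) -> np.ndarray:
        cols = [j for j, c in enumerate(self.conditions) if c == condition]
        return self.values[:, cols]


@dataclass
class AnnotationRecord:
    gene_id: str
    bins: list[str]
    go_terms: list[str] | None = None


class AnnotationMap(dict):
    """probe-set ID -> :class:`AnnotationRecord`; annotation may be partial."""

    def bins_of(self, probe_set_id: str) -> list[str]:
        rec = self.get(probe_set_id)
        return rec.bins if rec is not None else []


@dataclass
class DETable:
    """Per-probe-set differential-expression results.

    Backed by a DataFrame indexed by probe-set ID with columns
    ``log2fc, p_raw, p_adj, direction, selected``.
    """

    frame: pd.DataFrame

    REQUIRED = ("log2fc", "p_raw", "p_adj", "direction", "selected")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ChipFormatError(f"DE table missing column {col!r}")
        f = self.frame
        if ((f["p_adj"] + 1e-12) < f["p_raw"]).any():
            raise ChipFormatError("adjusted p smaller than raw p")
        bad_up = (f["direction"] == "up") & (f["log2fc"] <= 0)
        bad_dn = (f["direction"] == "down") & (f["log2fc"] >= 0)
        if bad_up.any() or bad_dn.any():
            raise ChipFormatError("direction flag inconsistent with log2fc sign")

    @property
    def selected_ids(self) -> list[str]:
        return list(self.frame.index[self.frame["selected"]])

    @property
    def n_selected(self) -> int:
        return int(self.frame["selected"].sum())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_layout(path: str | Path) -> ChipLayout:
    """Read a chip layout TSV: ``probe_set_id  pair_rank  pm_index  mm_index``.

    Row order within a probe-set defines pair order; ``mm_index`` may be NA.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    expected = ["probe_set_id", "pair_rank", "pm_index", "mm_index"]
    if list(df.columns) != expected:
        raise ChipFormatError(f"{path}: header {list(df.columns)} != {expected}")
    probe_sets: dict[str, list[ProbePair]] = {}
    seen_ranks: set[tuple[str, int]] = set()
    for row in df.itertuples(index=False):
        ps_id = row.probe_set_id
        try:
            rank = int(row.pair_rank)
            pm = int(row.pm_index)
            mm = None if row.mm_index in ("NA", "", None) else int(row.mm_index)
        except (TypeError, ValueError) as exc:
            raise ChipFormatError(f"{path}: non-integer index in record {tuple(row)}") from exc
        if (ps_id, rank) in seen_ranks:
            raise ChipFormatError(f"{path}: duplicate pair_rank {rank} in probe-set {ps_id!r}")
        seen_ranks.add((ps_id, rank))
        probe_sets.setdefault(ps_id, []).append(ProbePair(pm, mm, rank))
    chip_name = path.stem
    return ChipLayout(probe_sets=probe_sets, chip_name=chip_name)


def write_layout(layout: ChipLayout, path: str | Path) -> None:
    rows = []
    for ps_id, pairs in layout.probe_sets.items():
        for p in pairs:
            rows.append((ps_id, p.pair_rank, p.pm_index, "NA" if p.mm_index is None else p.mm_index))
    df = pd.DataFrame(rows, columns=["probe_set_id", "pair_rank", "pm_index", "mm_index"])
    df.to_csv(path, sep="\t", index=False)


def read_intensities(path: str | Path, layout: ChipLayout | None = None) -> ProbeIntensityTable:
    """Read an intensity TSV with ``#array_id= #kind= #condition=`` metadata lines.

    When ``layout`` is given, the table must cover every PM probe of it.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key] = val
            body_start = i + 1
        else:
            break
    header = lines[body_start].rstrip("\n").split("\t")
    if header != ["probe_index", "intensity"]:
        raise ChipFormatError(f"{path}: header {header} != ['probe_index', 'intensity']")
    intensities: dict[int, float] = {}
    for line in lines[body_start + 1:]:
        line = line.rstrip("\n")
        if not line:
            continue
        idx_s, _, val_s = line.partition("\t")
        try:
            idx, val = int(idx_s), float(val_s)
        except ValueError as exc:
            raise ChipFormatError(f"{path}: bad record {line!r}") from exc
        if val < 0:
            raise ChipFormatError(f"{path}: negative intensity {val} at probe {idx}")
        intensities[idx] = val
    table = ProbeIntensityTable(
        array_id=meta.get("array_id", path.stem),
        kind=meta.get("kind", "rna"),
        condition=meta.get("condition", ""),
        intensities=intensities,
    )
    if layout is not None:
        table.check_covers(layout)
    return table


def write_intensities(table: ProbeIntensityTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#array_id={table.array_id}\n#kind={table.kind}\n#condition={table.condition}\n")
        fh.write("probe_index\tintensity\n")
        for idx in sorted(table.intensities):
            fh.write(f"{idx}\t{table.intensities[idx]:.17g}\n")


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix TSV; values keep >= 12 significant digits."""
    if not matrix.probe_set_ids:
        raise ChipFormatError("refusing to write an empty expression matrix")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#conditions=" + ",".join(matrix.conditions) + "\n")
        fh.write("probe_set_id\t" + "\t".join(matrix.array_ids) + "\n")
        for ps_id, row in zip(matrix.probe_set_ids, matrix.values):
            fh.write(ps_id + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#conditions="):
            raise ChipFormatError(f"{path}: missing #conditions= metadata line")
        conditions = first[len("#conditions="):].split(",")
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "probe_set_id":
            raise ChipFormatError(f"{path}: first column must be probe_set_id")
        array_ids = header[1:]
        if len(conditions) != len(array_ids):
            raise ChipFormatError(f"{path}: {len(conditions)} conditions for {len(array_ids)} arrays")
        ids: list[str] = []
        rows: list[list[float]] = []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise ChipFormatError(f"{path}: row {parts[0]!r} has {len(parts) - 1} values, expected {len(array_ids)}")
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return ExpressionMatrix(ids, array_ids, conditions, np.array(rows, dtype=float))


def read_annotation(path: str | Path) -> AnnotationMap:
    """Read ``probe_set_id  gene_id  bins(semicolon)  go(optional, semicolon)``."""
    df = pd.read_csv(path, sep="\t", comment=None, dtype=str, keep_default_na=False)
    if list(df.columns)[:3] != ["probe_set_id", "gene_id", "bins"]:
        raise ChipFormatError(f"{path}: unexpected annotation header {list(df.columns)}")
    amap = AnnotationMap()
    for row in df.itertuples(index=False):
        bins = [b for b in row.bins.split(";") if b]
        go = None
        if "go" in df.columns:
            go = [g for g in row.go.split(";") if g] or None
        amap[row.probe_set_id] = AnnotationRecord(gene_id=row.gene_id, bins=bins, go_terms=go)
    return amap


def write_annotation(amap: AnnotationMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_set_id\tgene_id\tbins\tgo\n")
        for ps_id, rec in amap.items():
            go = ";".join(rec.go_terms) if rec.go_terms else ""
            fh.write(f"{ps_id}\t{rec.gene_id}\t{';'.join(rec.bins)}\t{go}\n")


def write_mask(mask: ProbeMask, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#threshold={mask.threshold:.17g}\n")
        fh.write("probe_set_id\tretained_ranks\n")
        for ps_id, ranks in mask.retained_pairs.items():
            fh.write(f"{ps_id}\t{';'.join(str(r) for r in ranks)}\n")


def read_mask(path: str | Path) -> ProbeMask:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
        if not first.startswith("#threshold="):
            raise ChipFormatError(f"{path}: missing #threshold= line")
        threshold = float(first[len("#threshold="):])
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["probe_set_id", "retained_ranks"]:
            raise ChipFormatError(f"{path}: bad mask header {header}")
        retained: dict[str, list[int]] = {}
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ps_id, _, ranks_s = line.partition("\t")
            retained[ps_id] = [int(r) for r in ranks_s.split(";") if r]
    return ProbeMask(threshold=threshold, retained_pairs=retained)


def write_de_table(de: DETable, path: str | Path) -> None:
    out = de.frame.copy()
    out.index.name = "probe_set_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_de_table(path: str | Path) -> DETable:
    df = pd.read_csv(path, sep="\t", index_col="probe_set_id")
    df["selected"] = df["selected"].astype(bool)
    return DETable(df)
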