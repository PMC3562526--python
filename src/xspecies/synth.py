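"""Synthetic cross-species hybridization simulator.

Emulates the design of a heterologous GeneChip study: one or more genomic-DNA
hybridization arrays, replicated cRNA arrays for two ripening stages
(*unripe*, *ripe*), probe-level signal attenuation caused by cross-species
sequence divergence, and planted differential expression — so every
downstream stage of the pipeline has a known ground truth.

Generative model (all effects on the log2 scale unless noted):

* each probe ``i`` draws an affinity ``a_i ~ Normal(0, 0.5)`` shared by every
  array — affinity is a sequence property, absorbed later by median polish;
* probe ``i`` is *diverged* with probability ``divergence_fraction``; a
  diverged probe's signal is multiplied by ``attenuation`` on **both** gDNA
  and RNA arrays (the shared probe/target mismatch is the premise of
  gDNA-based masking);
* gDNA signal:  ``2**(gdna_level + a_i + eps) * b_i + bg``,
  ``eps ~ Normal(0, noise_sd)``;
* RNA signal of probe ``i`` in probe-set ``s`` under condition ``c``:
  ``2**(baseline_log2 + mu_s + delta_s*[c == ripe] + a_i + eps) * b_i + bg``
  with set abundance ``mu_s ~ Normal(0, 1)`` and planted log2 fold change
  ``delta_s`` (half the planted sets go up, half down);
* ``bg = nonspecific_scale * 2**eta``, ``eta ~ Normal(0, nonspecific_sd)``,
  drawn independently per probe and array, is the additive raw-scale
  optical-background / nonspecific-hybridization floor.  It is what makes
  diverged probes harmful rather than merely dim: their attenuated specific
  signal drops below the floor, so their measured intensity is
  background-dominated noise carrying no fold-change information.  Setting
  ``nonspecific_scale = 0`` recovers the purely multiplicative model.

Identical config and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from xspecies.chip_model import (
    AnnotationMap,
    AnnotationRecord,
    ChipLayout,
    ProbeIntensityTable,
    ProbePair,
    write_annotation,
    write_intensities,
    write_layout,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic hybridization experiment.

    Defaults follow the emulated study design: 11 probe-pairs per set
    (ATH1-like), 3 replicate RNA arrays per ripening stage, one gDNA array,
    strong cross-species divergence (half the probes attenuated to 5% of
    their binding), 10% of probe-sets differentially expressed at one log2
    unit, and a mean gDNA signal of 2**7 = 128 fluorescence units so the
    useful masking thresholds fall inside the conventional 0-500 sweep.
    """

    n_probe_sets: int = 1000
    pairs_per_set: int = 11
    n_reps: int = 3
    n_gdna: int = 1
    divergence_fraction: float = 0.5
    attenuation: float = 0.05
    de_fraction: float = 0.1
    de_log2fc: float = 1.0
    noise_sd: float = 0.2
    baseline_log2: float = 8.0
    gdna_level: float = 7.0
    nonspecific_scale: float = 32.0
    nonspecific_sd: float = 0.5
    seed: int = 0
    conditions: tuple[str, str] = ("unripe", "ripe")

    def __post_init__(self) -> None:
        for name in ("divergence_fraction", "de_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.attenuation <= 1.0:
            raise ConfigError(f"attenuation must be in (0, 1], got {self.attenuation}")
        if self.n_reps < 2:
            raise ConfigError(f"n_reps must be >= 2, got {self.n_reps}")
        if self.pairs_per_set < 2:
            raise ConfigError(f"pairs_per_set must be >= 2, got {self.pairs_per_set}")
        if self.n_probe_sets < 1 or self.n_gdna < 1:
            raise ConfigError("n_probe_sets and n_gdna must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.nonspecific_scale < 0 or self.nonspecific_sd < 0:
            raise ConfigError("nonspecific_scale and nonspecific_sd must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        return d


@dataclass
class GroundTruth:
    """What the simulator planted: diverged probes and true log2 fold changes."""

    diverged_probes: set[int]
    de_sets: dict[str, float]
    probe_affinity: dict[int, float] = field(default_factory=dict)

    @property
    def true_de_ids(self) -> list[str]:
        return [s for s, fc in self.de_sets.items() if fc != 0.0]


def _probe_set_id(i: int, width: int) -> str:
    return f"PS{i:0{width}d}_at"


def simulate(
    config: SimulationConfig,
) -> tuple[ChipLayout, list[ProbeIntensityTable], list[ProbeIntensityTable], GroundTruth]:
    """Generate one synthetic experiment.

    Returns ``(layout, gdna_tables, rna_tables, truth)``.  RNA tables carry
    ``condition`` labels; arrays are ordered unripe replicates first.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    n_sets, n_pairs = cfg.n_probe_sets, cfg.pairs_per_set
    n_probes = n_sets * n_pairs
    width = max(5, len(str(n_sets)))
    ps_ids = [_probe_set_id(i, width) for i in range(n_sets)]

    # layout: PM at even indices, MM at odd, filled probe-set by probe-set
    probe_sets: dict[str, list[ProbePair]] = {}
    pm_idx = np.arange(n_probes) * 2
    for i, ps_id in enumerate(ps_ids):
        probe_sets[ps_id] = [
            ProbePair(pm_index=int(pm_idx[i * n_pairs + r]), mm_index=int(pm_idx[i * n_pairs + r]) + 1,
                      pair_rank=r + 1)
            for r in range(n_pairs)
        ]
    layout = ChipLayout(probe_sets=probe_sets, chip_name=f"synth-{cfg.seed}")

    affinity = rng.normal(0.0, 0.5, size=n_probes)
    diverged = rng.random(n_probes) < cfg.divergence_fraction
    binding = np.where(diverged, cfg.attenuation, 1.0)

    # planted differential expression: round(de_fraction * n) sets, half up half down
    n_de = int(round(cfg.de_fraction * n_sets))
    de_order = rng.permutation(n_sets)[:n_de]
    delta = np.zeros(n_sets)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    delta[de_order] = signs * cfg.de_log2fc
    mu = rng.normal(0.0, 1.0, size=n_sets)

    def _background() -> np.ndarray:
        if cfg.nonspecific_scale == 0:
            return np.zeros(n_probes)
        eta = rng.normal(0.0, cfg.nonspecific_sd, size=n_probes)
        return cfg.nonspecific_scale * np.exp2(eta)

    def _table(array_id: str, kind: str, condition: str, log2_signal: np.ndarray) -> ProbeIntensityTable:
        values = np.exp2(log2_signal) * binding + _background()
        return ProbeIntensityTable(
            array_id=array_id, kind=kind, condition=condition,
            intensities={int(pm): float(v) for pm, v in zip(pm_idx, values)},
        )

    gdna_tables = []
    for g in range(cfg.n_gdna):
        eps = rng.normal(0.0, cfg.noise_sd, size=n_probes)
        gdna_tables.append(_table(f"gdna_{g + 1}", "gdna", "", cfg.gdna_level + affinity + eps))

    set_effect = cfg.baseline_log2 + mu  # per probe-set abundance
    per_probe_set = np.repeat(np.arange(n_sets), n_pairs)
    rna_tables = []
    for condition in cfg.conditions:
        shift = delta if condition == cfg.conditions[1] else np.zeros(n_sets)
        probe_mean = (set_effect + shift)[per_probe_set] + affinity
        for rep in range(cfg.n_reps):
            eps = rng.normal(0.0, cfg.noise_sd, size=n_probes)
            rna_tables.append(
                _table(f"rna_{condition}_{rep + 1}", "rna", condition, probe_mean + eps)
            )

    truth = GroundTruth(
        diverged_probes={int(pm) for pm, d in zip(pm_idx, diverged) if d},
        de_sets={ps_ids[i]: float(delta[i]) for i in range(n_sets)},
        probe_affinity={int(pm): float(a) for pm, a in zip(pm_idx, affinity)},
    )
    return layout, gdna_tables, rna_tables, truth


def make_annotation(
    layout: ChipLayout,
    truth: GroundTruth,
    config: SimulationConfig,
    enriched_bin: str = "cell_wall",
    n_background_bins: int = 10,
) -> AnnotationMap:
    """Functional-bin annotation with one planted enriched bin.

    Every up-regulated planted set joins ``enriched_bin`` (its members
    therefore sit high in the log2fc ranking — the positive control for the
    rank-sum enrichment stage); a further 5% of non-planted sets join it as
    dilution.  Remaining sets get one of ``n_background_bins`` generic bins.
    Deterministic given the config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA11]))
    amap = AnnotationMap()
    ps_ids = list(layout.probe_sets)
    up_ids = {s for s, fc in truth.de_sets.items() if fc > 0}
    non_planted = [s for s in ps_ids if truth.de_sets.get(s, 0.0) == 0.0]
    n_extra = max(1, int(0.05 * len(non_planted)))
    extra = set(rng.choice(non_planted, size=min(n_extra, len(non_planted)), replace=False))
    for i, ps_id in enumerate(ps_ids):
        bins = [f"bin_{rng.integers(1, n_background_bins + 1):02d}"]
        if ps_id in up_ids or ps_id in extra:
            bins.append(enriched_bin)
        amap[ps_id] = AnnotationRecord(gene_id=f"AT{i % 5 + 1}G{i:05d}", bins=bins)
    return amap


def write_dataset(
    dataset: tuple[ChipLayout, list[ProbeIntensityTable], list[ProbeIntensityTable], GroundTruth],
    directory: str | Path,
    config: SimulationConfig,
    overwrite: bool = False,
    enriched_bin: str = "cell_wall",
) -> Path:
    """Write layout, intensities, annotation, ground truth and a manifest.

    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set.  Returns the manifest path.  Reruns with the same
    config and seed produce byte-identical files.
    """
    layout, gdna, rna, truth = dataset
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{directory} exists and is not empty; pass overwrite=True to replace"
        )
    directory.mkdir(parents=True, exist_ok=True)

    files: dict[str, object] = {}
    write_layout(layout, directory / "layout.tsv")
    files["layout"] = "layout.tsv"
    for t in gdna + rna:
        write_intensities(t, directory / f"{t.array_id}.tsv")
    files["gdna"] = [f"{t.array_id}.tsv" for t in gdna]
    files["rna"] = [f"{t.array_id}.tsv" for t in rna]

    amap = make_annotation(layout, truth, config, enriched_bin=enriched_bin)
    write_annotation(amap, directory / "annotation.tsv")
    files["annotation"] = "annotation.tsv"

    with open(directory / "truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("probe_set_id\ttrue_log2fc\n")
        for ps_id, fc in truth.de_sets.items():
            fh.write(f"{ps_id}\t{fc:.17g}\n")
    with open(directory / "diverged_probes.tsv", "w", encoding="utf-8") as fh:
        fh.write("pm_index\n")
        for pm in sorted(truth.diverged_probes):
            fh.write(f"{pm}\n")
    files["truth"] = "truth.tsv"
    files["diverged_probes"] = "diverged_probes.tsv"

    manifest_path = directory / "manifest.yaml"
    manifest = {"config": config.to_dict(), "seed": config.seed, "files": files,
                "enriched_bin": enriched_bin}
    with open(manifest_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path
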