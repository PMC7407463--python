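"""Scale presets, run configuration, seed plumbing and table writers.

Three scale presets are provided:

* ``full`` - the study scale: 18 chromosomes x 120 cM, 72,000 markers,
  7,200 QTL (2,500 carrying the trait), historical population of 2,500
  with a 1,000-generation bottleneck to 300, breed formation over 20
  generations, and a 12-sire x 204-dam x litter-12 breeding scheme.
* ``desk`` - the same demography and family structure on a reduced
  genome (3 chromosomes, 12,000 markers, 1,200 QTL, 417 trait QTL).
  Breed-formation selection is recalibrated for the smaller genome (see
  docs/methods.md) so that the founder-structure statistics - LD decay,
  between-breed relationship, marker homozygosity, QTL frequency
  divergence - match the full-scale study.
* ``mini`` - a toy scale (2 chromosomes, 500 markers, 4 sires x 20 dams)
  for fast property tests of whole-scheme behaviour.

All randomness flows from one master seed through named substreams
(:mod:`crossbredsim._rng`), so that scenarios sharing a master seed share
genomes, trait effects and purebred mating draws, and differ only where
the scenario itself differs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ScalePreset", "PRESETS", "ScenarioConfig", "load_config", "write_metrics", "make_fixture"]

SCENARIOS = ("S1", "S2", "S3", "S4", "S4star")


@dataclass(frozen=True)
class ScalePreset:
    """Everything that depends on the simulation scale."""

    name: str
    # genome
    n_chrom: int
    chrom_cM: float
    n_markers: int
    n_qtl: int
    mutation_rate: float = 2.5e-4
    # historical demography
    hist_constant: int = 1000
    hist_decline: int = 1000
    hist_expand: int = 10
    hist_size: int = 2500
    hist_bottleneck: int = 300
    # breed formation
    bf_generations: int = 20
    bf_base_males: int = 80
    bf_base_females: int = 400
    bf_sel_males: int = 40
    bf_sel_females: int = 400
    bf_litter: int = 10
    bf_dummy_h2: float = 0.5
    # trait
    n_trait_qtl: int = 2500
    # breeding-scheme family structure
    n_males: int = 12
    n_females: int = 204
    litter_size: int = 12
    females_per_litter: int = 10
    # marker QC
    maf_min: float = 0.05
    hwe_t: float = 0.15
    # solver
    dense_limit: int = 5000

    @property
    def quota(self) -> int:
        return self.n_females // self.n_males


PRESETS: dict[str, ScalePreset] = {
    "full": ScalePreset(
        name="full", n_chrom=18, chrom_cM=120.0, n_markers=72_000, n_qtl=7_200,
        n_trait_qtl=2_500,
    ),
    "desk": ScalePreset(
        name="desk", n_chrom=3, chrom_cM=120.0, n_markers=12_000, n_qtl=1_200,
        n_trait_qtl=417, bf_sel_males=22, bf_dummy_h2=0.03,
    ),
    "mini": ScalePreset(
        name="mini", n_chrom=2, chrom_cM=120.0, n_markers=500, n_qtl=100,
        hist_constant=200, hist_decline=100, hist_expand=10,
        hist_size=200, hist_bottleneck=30,
        bf_generations=10, bf_base_males=16, bf_base_females=40,
        bf_sel_males=8, bf_sel_females=40, bf_litter=6, bf_dummy_h2=0.05,
        n_trait_qtl=30,
        n_males=4, n_females=20, litter_size=6, females_per_litter=5,
    ),
}


@dataclass
class ScenarioConfig:
    """A complete run specification."""

    scenario: str = "S1"
    case: int = 1
    r_qtl: float = 0.5
    n_generations: int = 10
    replicates: int = 10
    preset: str = "full"
    seed: int = 1
    scale_override: ScalePreset | None = None
    # control run: replace the selection criterion with random scores
    # (drift-only trajectories; evaluations are skipped)
    random_selection: bool = False

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; allowed: {', '.join(SCENARIOS)}"
            )
        if self.case not in (1, 2, 3):
            raise ValueError("case must be 1, 2 or 3")
        if self.preset not in PRESETS:
            raise ValueError(
                f"unknown preset {self.preset!r}; allowed: {', '.join(PRESETS)}"
            )

    @property
    def scale(self) -> ScalePreset:
        return self.scale_override if self.scale_override is not None else PRESETS[self.preset]

    @property
    def uses_crossbred_data(self) -> bool:
        return self.scenario in ("S3", "S4", "S4star")

    @property
    def cb_mating(self) -> str:
        return {
            "S1": "random", "S3": "random",
            "S2": "min_EFI", "S4": "max_ETGV", "S4star": "max_ETGV_true",
        }[self.scenario]


_CONFIG_KEYS = {f.name for f in dataclasses.fields(ScenarioConfig)}
_PRESET_KEYS = {f.name for f in dataclasses.fields(ScalePreset)} - {"name"}


def load_config(source) -> ScenarioConfig:
    """Build a config from a mapping or a YAML file path.

    Keys follow the ``ScenarioConfig`` fields; preset fields may be
    overridden under an optional ``scale:`` sub-mapping.  Unknown keys
    are rejected.
    """
    if isinstance(source, (str, Path)):
        import yaml

        with open(source) as fh:
            mapping = yaml.safe_load(fh) or {}
    else:
        mapping = dict(source or {})

    scale_over = mapping.pop("scale", {}) or {}
    unknown = set(mapping) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    unknown = set(scale_over) - _PRESET_KEYS
    if unknown:
        raise ValueError(f"unknown scale keys: {sorted(unknown)}")

    cfg = ScenarioConfig(**mapping)
    if scale_over:
        base = PRESETS[cfg.preset]
        custom = dataclasses.replace(base, name=base.name + "-custom", **scale_over)
        if custom.n_females % custom.n_males:
            raise ValueError(
                "inconsistent quotas: n_females must be a multiple of n_males "
                f"(got n_females={custom.n_females}, n_males={custom.n_males})"
            )
        cfg.scale_override = custom
    return cfg


def write_metrics(metrics: pd.DataFrame, out_dir, replicate_tables: list[pd.DataFrame] | None = None) -> dict[str, Path]:
    """Write per-generation metric tables as TSV with stable column order.

    Emits the averaged table, per-replicate tables, a founder-vs-last
    rPC summary and a final-response summary for direct comparison with
    published tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    main = out / "metrics.tsv"
    metrics.to_csv(main, sep="\t", index=False)
    files["metrics"] = main

    if replicate_tables:
        for i, tbl in enumerate(replicate_tables):
            p = out / f"metrics_rep{i}.tsv"
            tbl.to_csv(p, sep="\t", index=False)
            files[f"rep{i}"] = p

    if "rpc_mean" in metrics.columns:
        rpc = metrics.dropna(subset=["rpc_mean"])
        if len(rpc):
            summary = pd.DataFrame(
                {
                    "founder_rpc": [rpc["rpc_mean"].iloc[0]],
                    "last_rpc": [rpc["rpc_mean"].iloc[-1]],
                }
            )
            p = out / "rpc_summary.tsv"
            summary.to_csv(p, sep="\t", index=False)
            files["rpc_summary"] = p

    if "cb_ttgv_rel" in metrics.columns:
        resp = metrics.dropna(subset=["cb_ttgv_rel"])
        if len(resp):
            cols = ["cb_ttgv_rel"] + (["cb_ttgv_rel_sd"] if "cb_ttgv_rel_sd" in resp else [])
            p = out / "final_response.tsv"
            resp.iloc[[-1]][["generation"] + cols].to_csv(p, sep="\t", index=False)
            files["final_response"] = p
    return files


def make_fixture(kind: str, seed: int = 0):
    """Deterministic small datasets for the test suite.

    * ``tiny-genome``: a 2-chromosome, 200-marker / 20-QTL genome map
      with a 40-individual haplotype pool.
    * ``toy-mating``: an 8-dam, 3-sire score matrix whose optimum is
      checkable by exhaustive enumeration.
    * ``toy-evaluation``: a 30-animal single-population GBLUP instance.
    """
    from . import genome as G

    rng = np.random.default_rng([seed, 0xF1D])
    if kind == "tiny-genome":
        gmap = G.GenomeMap.random(2, 100.0, 200, 20, rng)
        packed = rng.integers(0, 256, size=(40, 2, gmap.n_bytes), dtype=np.uint8)
        G._zero_pad_bits(packed, gmap.n_loci)
        sex = G._balanced_sexes(40, rng)
        pool = G.HaplotypePool(0, packed, sex, gmap.n_loci)
        return gmap, pool
    if kind == "toy-mating":
        scores = rng.uniform(0.0, 1.0, size=(3, 8)).round(3)
        return scores
    if kind == "toy-evaluation":
        n, p = 30, 50
        z = rng.integers(0, 3, size=(n, p)).astype(np.uint8)
        u = (z - z.mean(axis=0)) @ rng.normal(0, 0.15, p)
        y = 10.0 + u + rng.normal(0, 1.0, n)
        fg = (z != 1).mean(axis=1)
        return z, y, fg
    raise ValueError(f"unknown fixture kind {kind!r}")
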