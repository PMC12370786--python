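"""End-to-end pipeline: simulate -> traits -> dispersion -> niche -> match.

A single YAML (or dict) configuration drives every stage; each stage reads
its input CSVs from and writes its outputs to one output directory, so
stages can be re-run independently as long as their upstream artifacts
exist.  A JSON manifest with SHA-256 content hashes is written after every
run, making end-to-end determinism checkable with a file-level diff.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dispersion, feeding, io, synthetic, trait_metrics

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "STAGES"]

logger = logging.getLogger("hoppertraits")

STAGES = ("simulate", "traits", "dispersion", "niche", "match")


class PipelineError(RuntimeError):
    """User-correctable pipeline failure (bad config, missing artifact)."""


@dataclass
class PipelineConfig:
    """Everything needed to run the full analysis from one seed.

    Defaults mirror the study design: 14 grasshopper species in 4
    subfamilies measured on ~20 individuals each, 30 sites x 2 sampling
    periods, 16 plant species, ~12 cafeteria replicates per species, 999
    null communities and 999 label permutations.
    """

    outdir: str = "output"
    seed: int = 0
    # pool / specimens
    n_species: int = 14
    n_per_species: int = 20
    subfamily_assignment: str = "random"
    # assembly
    assembly_mode: str = "neutral"
    assembly_strength: float | None = None  # None -> calibrated default for mode
    n_sites: int = 30
    n_periods: int = 2
    richness_range: tuple[int, int] = (2, 8)
    # plants / feeding
    n_plants: int = 16
    beta_matching: float = 0.8
    beta_cn: float = -0.5
    beta_bv: float = 0.4
    n_replicates_per_species: int = 12
    total_consumption_scale: float = 8.0
    feeding_noise_sd: float = 0.5
    # dispersion
    n_null: int = 999
    trait_sets: tuple[str, ...] = dispersion.TRAIT_SETS
    per_row_shuffle: bool = False
    presence_only: bool = False
    include_subfamily_in_all: bool = False
    # niche tests
    n_perm: int = 999

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        valid = set(cls.__dataclass_fields__)
        unknown = set(raw) - valid
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.richness_range = tuple(cfg.richness_range)
        cfg.trait_sets = tuple(cfg.trait_sets)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.assembly_mode not in ("neutral", "filtering", "competition"):
            raise PipelineError(f"invalid assembly_mode {self.assembly_mode!r}")
        for ts in self.trait_sets:
            if ts not in dispersion.TRAIT_SETS:
                raise PipelineError(
                    f"invalid trait_set {ts!r}; valid: {dispersion.TRAIT_SETS}"
                )
        lo, hi = self.richness_range
        if not (1 <= lo <= hi <= self.n_species):
            raise PipelineError("richness_range must satisfy 1 <= lo <= hi <= n_species")
        if self.seed is None:
            raise PipelineError("seed is required")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["richness_range"] = list(self.richness_range)
        d["trait_sets"] = list(self.trait_sets)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @property
    def strength(self) -> float:
        if self.assembly_strength is not None:
            return self.assembly_strength
        return synthetic.CALIBRATED_STRENGTH[self.assembly_mode]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(out: Path, names: list[str], stage: str, needed_by: str) -> None:
    missing = [n for n in names if not (out / n).exists()]
    if missing:
        raise PipelineError(
            f"stage '{needed_by}' needs {missing}; run stage '{stage}' first"
        )


def _stage_simulate(cfg: PipelineConfig, out: Path) -> list[str]:
    ss = np.random.SeedSequence(cfg.seed)
    s_pool, s_spec, s_comm, s_plant, s_feed = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)
    ]
    pool = synthetic.make_species_pool(
        cfg.n_species, seed=s_pool, subfamily_assignment=cfg.subfamily_assignment
    )
    specimens = synthetic.gen_specimens(pool, cfg.n_per_species, seed=s_spec)
    io.write_specimens(specimens, out / "specimens.csv")

    latent = pool.trait_table()  # latent species means drive assembly & feeding
    acfg = synthetic.AssemblyConfig(
        mode=cfg.assembly_mode,
        strength=cfg.strength,
        n_sites=cfg.n_sites,
        n_periods=cfg.n_periods,
        richness_range=cfg.richness_range,
        seed=s_comm,
    )
    comm = synthetic.gen_communities(pool, latent, acfg)
    io.write_communities(comm, out / "communities.csv")

    plants = synthetic.gen_plants(cfg.n_plants, seed=s_plant)
    io.write_plants(plants, out / "plants.csv")

    fcfg = synthetic.FeedingConfig(
        beta_matching=cfg.beta_matching,
        beta_cn=cfg.beta_cn,
        beta_bv=cfg.beta_bv,
        n_replicates_per_species=cfg.n_replicates_per_species,
        total_consumption_scale=cfg.total_consumption_scale,
        noise_sd=cfg.feeding_noise_sd,
        seed=s_feed,
    )
    fd = synthetic.gen_feeding(latent, plants, fcfg)
    io.write_feeding(fd, out / "feeding.csv")
    return ["specimens.csv", "communities.csv", "plants.csv", "feeding.csv"]


def _stage_traits(cfg: PipelineConfig, out: Path) -> list[str]:
    _require(out, ["specimens.csv"], "simulate", "traits")
    specimens = io.read_specimens(out / "specimens.csv")
    # subfamily map travels with feeding.csv when simulating; fall back to
    # any traits.csv already present for measured-data runs
    subfamily = None
    if (out / "feeding.csv").exists():
        fd = pd.read_csv(out / "feeding.csv")
        subfamily = fd.drop_duplicates("species_id").set_index("species_id")[
            "subfamily"
        ]
    table = trait_metrics.species_means(specimens, subfamily=subfamily)
    io.write_traits(table, out / "traits.csv")
    corr = trait_metrics.pairwise_correlations(table)
    corr.to_csv(out / "correlations.csv", index=False)
    pca = trait_metrics.trait_pca(table)
    summary = pca.loadings.copy()
    summary.loc["variance_explained"] = pca.variance_explained
    summary.to_csv(out / "pca_summary.csv", index_label="trait")
    return ["traits.csv", "correlations.csv", "pca_summary.csv"]


def _stage_dispersion(cfg: PipelineConfig, out: Path) -> list[str]:
    _require(out, ["communities.csv"], "simulate", "dispersion")
    _require(out, ["traits.csv"], "traits", "dispersion")
    traits = io.read_traits(out / "traits.csv")
    comm = io.read_communities(out / "communities.csv", species=traits.index)
    ses_seed = int(
        np.random.SeedSequence([cfg.seed, 101]).generate_state(1)[0] % (2**31)
    )
    res = dispersion.ses_all_rows(
        comm,
        traits,
        trait_sets=cfg.trait_sets,
        n_null=cfg.n_null,
        seed=ses_seed,
        per_row_shuffle=cfg.per_row_shuffle,
        presence_only=cfg.presence_only,
        include_subfamily_in_all=cfg.include_subfamily_in_all,
    )
    res.to_csv(out / "ses_results.csv", index=False)
    summary = dispersion.summarize_ses(res, group_by=("trait_set",))
    by_period = dispersion.summarize_ses(res, group_by=("trait_set", "period"))
    summary.to_csv(out / "ses_summary.csv", index=False)
    by_period.to_csv(out / "ses_summary_by_period.csv", index=False)
    return ["ses_results.csv", "ses_summary.csv", "ses_summary_by_period.csv"]


def _stage_niche(cfg: PipelineConfig, out: Path) -> list[str]:
    _require(out, ["feeding.csv", "plants.csv"], "simulate", "niche")
    fd = io.read_feeding(out / "feeding.csv")
    plants = io.read_plants(out / "plants.csv")
    cwms = feeding.cwm_table(fd, plants)
    cwms.to_csv(out / "cwm.csv", index_label="individual_id")
    pd.concat(
        [
            feeding.niche_summary(cwms, "species").assign(level="species"),
            feeding.niche_summary(cwms, "subfamily").assign(level="subfamily"),
        ]
    ).to_csv(out / "niche_summary.csv", index_label="group")
    perm_seed = int(
        np.random.SeedSequence([cfg.seed, 202]).generate_state(1)[0] % (2**31)
    )
    rows = []
    for factor in ("species", "subfamily"):
        for pt in feeding.PLANT_TRAITS:
            res = feeding.diet_difference_test(
                cwms, factor=factor, plant_trait=pt, n_perm=cfg.n_perm, seed=perm_seed
            )
            rows.append({"factor": factor, "plant_trait": pt, **res})
    pd.DataFrame(rows).to_csv(out / "diet_tests.csv", index=False)
    return ["cwm.csv", "niche_summary.csv", "diet_tests.csv"]


def _stage_match(cfg: PipelineConfig, out: Path) -> list[str]:
    _require(out, ["cwm.csv"], "niche", "match")
    _require(out, ["traits.csv"], "traits", "match")
    traits = io.read_traits(out / "traits.csv")
    cwms = pd.read_csv(out / "cwm.csv", index_col="individual_id")
    rows = []
    for pair in feeding.MATCHING_PAIRS:
        r = feeding.trait_matching(traits, cwms, pair)
        rows.append(
            {
                "herbivore_trait": r.herbivore_trait,
                "plant_trait": r.plant_trait,
                "slope": r.slope,
                "slope_se": r.slope_se,
                "ci_low": r.conf_int[0],
                "ci_high": r.conf_int[1],
                "p_value": r.p_value,
                "r2": r.r2,
                "n_obs": r.n_obs,
            }
        )
    pd.DataFrame(rows).to_csv(out / "trait_matching.csv", index=False)
    return ["trait_matching.csv"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "traits": _stage_traits,
    "dispersion": _stage_dispersion,
    "niche": _stage_niche,
    "match": _stage_match,
}


def run_pipeline(
    cfg: PipelineConfig, stages: list[str] | tuple[str, ...] | str = "all"
) -> dict:
    """Run the requested stages in dependency order.

    Returns a manifest dict: per output file its SHA-256 content hash, plus
    the seed and per-stage timings.  The manifest is also written to
    ``manifest.json`` in the output directory.
    """
    cfg.validate()
    if stages == "all":
        stages = list(STAGES)
    elif isinstance(stages, str):
        stages = [stages]
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stages {unknown}; valid: {list(STAGES)}")
    stages = [s for s in STAGES if s in stages]  # dependency order

    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cfg.seed, "stages": {}, "files": {}}
    for stage in stages:
        t0 = time.perf_counter()
        logger.info("running stage %s", stage)
        files = _STAGE_FUNCS[stage](cfg, out)
        dt = time.perf_counter() - t0
        manifest["stages"][stage] = {"seconds": round(dt, 3), "outputs": files}
        for f in files:
            manifest["files"][f] = _sha256(out / f)
        logger.info("stage %s done in %.2fs (%d files)", stage, dt, len(files))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
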