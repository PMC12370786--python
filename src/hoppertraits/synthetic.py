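"""Synthetic data generators for the trait-based herbivore community pipeline.

The raw field and lab data behind the analysis are not publicly deposited, so
every downstream stage is exercised on simulated inputs whose statistical
structure is known by construction:

* a **species pool** of grasshopper species with correlated trait syndromes
  (log body volume, log incisor strength, C:N ratio) spanning four
  subfamilies;
* **specimen tables** of raw morphometrics back-solved from latent trait
  draws, so the trait equations recover the drawn values exactly;
* **site x species communities** assembled under neutral, environmental-
  filtering (trait under-dispersion) or limiting-similarity (trait
  over-dispersion) rules;
* a **plant pool** with a built-in negative LDMC-SLA association; and
* cafeteria-style **consumption matrices** governed by a known
  trait-matching kernel linking incisor strength to LDMC and body volume /
  C:N to plant C:N.

Every generator takes an explicit seed and is byte-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trait_metrics import NUMERIC_TRAITS

__all__ = [
    "DEFAULT_TRAIT_CORRELATIONS",
    "CALIBRATED_STRENGTH",
    "SUBFAMILIES",
    "SpeciesPool",
    "AssemblyConfig",
    "FeedingConfig",
    "make_species_pool",
    "gen_specimens",
    "gen_communities",
    "gen_plants",
    "gen_feeding",
]

#: Across-species correlation targets for (log body volume, log incisor
#: strength, C:N): incisor strength rises with body volume and both fall
#: with C:N, the trait-syndrome structure reported for SE-US pine-savanna
#: grasshopper assemblages.  Order matches ``NUMERIC_TRAITS``.
DEFAULT_TRAIT_CORRELATIONS = np.array(
    [
        [1.00, 0.78, -0.74],
        [0.78, 1.00, -0.69],
        [-0.74, -0.69, 1.00],
    ]
)

#: The four acridid subfamilies of the study system.
SUBFAMILIES = ("Gomphocerinae", "Melanoplinae", "Cyrtacanthacridinae", "Oedipodinae")

#: Assembly strengths at which the filtering / competition modes produce a
#: clearly signed mean SES at the field design size (60 rows, 14 species).
#: Fixed once by pilot simulation over a strength grid (see docs/methods.md).
CALIBRATED_STRENGTH = {"neutral": 0.0, "filtering": 2.0, "competition": 0.7}

_POOL_MEANS = {"log_body_volume": 6.0, "log_incisor_strength": 1.5, "cn_ratio": 4.5}
_POOL_SDS = {"log_body_volume": 0.9, "log_incisor_strength": 0.7, "cn_ratio": 0.8}


def _check_correlation(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (3, 3):
        raise ValueError("trait correlation matrix must be 3x3")
    if not np.allclose(corr, corr.T):
        raise ValueError("trait correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValueError("trait correlation matrix must have unit diagonal")
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ValueError("trait correlation matrix is not positive semi-definite")
    return corr


@dataclass
class SpeciesPool:
    """Latent species-level trait means for a simulated grasshopper pool.

    ``species`` is indexed by ``species_id`` and carries ``subfamily``,
    ``mean_log_body_volume`` (log mm^3), ``mean_log_incisor_strength``
    (log relative-force units) and ``mean_cn_ratio``.  ``within_species_sd``
    gives the per-trait SD of individual deviations around species means, on
    the same (log, log, raw) scales.
    """

    species: pd.DataFrame
    within_species_sd: tuple[float, float, float] = (0.20, 0.20, 0.35)

    def __post_init__(self):
        if self.species.index.duplicated().any():
            raise ValueError("species_id must be unique")
        if any(s < 0 for s in self.within_species_sd):
            raise ValueError("within-species SDs must be non-negative")
        if len(self.species) >= 4:
            if self.species["subfamily"].nunique() < 4:
                raise ValueError("pools of >=4 species must span 4 subfamilies")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def trait_table(self) -> pd.DataFrame:
        """Species trait table on natural scales (what `species_means` yields
        from noiseless specimens)."""
        t = pd.DataFrame(index=self.species.index)
        t["subfamily"] = self.species["subfamily"]
        t["body_volume"] = np.exp(self.species["mean_log_body_volume"])
        t["incisor_strength"] = np.exp(self.species["mean_log_incisor_strength"])
        t["cn_ratio"] = self.species["mean_cn_ratio"]
        return t


def make_species_pool(
    n_species: int = 14,
    seed: int = 0,
    trait_correlations: np.ndarray | None = None,
    subfamily_assignment: str = "random",
    within_species_sd: tuple[float, float, float] = (0.20, 0.20, 0.35),
) -> SpeciesPool:
    """Draw a species pool with correlated trait syndromes.

    Species-mean (log body volume, log incisor strength, C:N) vectors are
    drawn from a multivariate normal whose correlation matrix defaults to
    ``DEFAULT_TRAIT_CORRELATIONS``.

    ``subfamily_assignment``:

    * ``"random"`` (default) — subfamilies assigned independently of traits,
      appropriate when subfamily should carry no trait signal;
    * ``"by_trait"`` — species blocked into subfamilies along the first trait
      axis, emulating the real guild structure in which subfamily predicts
      feeding strategy.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    corr = _check_correlation(
        DEFAULT_TRAIT_CORRELATIONS if trait_correlations is None else trait_correlations
    )
    rng = np.random.default_rng(seed)
    sds = np.array([_POOL_SDS[k] for k in _POOL_MEANS])
    cov = corr * np.outer(sds, sds)
    mu = np.array(list(_POOL_MEANS.values()))
    draws = rng.multivariate_normal(mu, cov, size=n_species, method="cholesky")
    ids = [f"sp{i + 1:02d}" for i in range(n_species)]
    species = pd.DataFrame(
        draws,
        index=pd.Index(ids, name="species_id"),
        columns=["mean_log_body_volume", "mean_log_incisor_strength", "mean_cn_ratio"],
    )
    k = min(4, n_species)
    blocks = np.array_split(np.arange(n_species), k) if k else []
    sub = np.empty(n_species, dtype=object)
    if subfamily_assignment == "random":
        order = rng.permutation(n_species)
    elif subfamily_assignment == "by_trait":
        order = np.argsort(species["mean_log_incisor_strength"].to_numpy())
    else:
        raise ValueError("subfamily_assignment must be 'random' or 'by_trait'")
    for b, idx in enumerate(blocks):
        sub[order[idx]] = SUBFAMILIES[b]
    species["subfamily"] = sub
    return SpeciesPool(species=species, within_species_sd=within_species_sd)


def gen_specimens(
    pool: SpeciesPool,
    n_per_species: int = 20,
    trait_correlations: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate raw morphometric specimen records for every pool species.

    Individual latent traits are drawn from a per-species multivariate normal
    on (log body volume, log incisor strength, C:N) centred on the species
    means, with ``pool.within_species_sd`` marginal SDs and the supplied
    within-species correlation matrix (defaults to the across-species
    targets).  Raw morphometrics are then back-solved so that the trait
    equations recover the latent draws exactly:

    * all four diameters 1 mm and ``L = 4 V / pi`` (so the cylinder equation
      returns ``V``);
    * ``L_in = L_out = R_i = 1`` and head volume set to the incisor-strength
      value (so the lever equation returns it unchanged);
    * ``%N = 10`` and ``%C = 10 * C:N``.
    """
    if n_per_species < 1:
        raise ValueError("n_per_species must be >= 1")
    corr = _check_correlation(
        DEFAULT_TRAIT_CORRELATIONS if trait_correlations is None else trait_correlations
    )
    rng = np.random.default_rng(seed)
    sds = np.asarray(pool.within_species_sd, dtype=float)
    cov = corr * np.outer(sds, sds)
    # zero within-species SD (degenerate but allowed) makes cov singular
    mvn_method = "cholesky" if sds.min() > 0 else "eigh"
    records = []
    for sp, row in pool.species.iterrows():
        mu = row[
            ["mean_log_body_volume", "mean_log_incisor_strength", "mean_cn_ratio"]
        ].to_numpy(dtype=float)
        latent = rng.multivariate_normal(
            mu, cov, size=n_per_species, method=mvn_method
        )
        bv = np.exp(latent[:, 0])
        strength = np.exp(latent[:, 1])
        cn = np.maximum(latent[:, 2], 0.1)  # C:N cannot go non-positive
        for i in range(n_per_species):
            records.append(
                {
                    "species_id": sp,
                    "sex": "M" if i % 2 == 0 else "F",
                    "body_length_mm": 4.0 * bv[i] / np.pi,
                    "diam_head_mm": 1.0,
                    "diam_thorax_mm": 1.0,
                    "diam_abdomen_base_mm": 1.0,
                    "diam_abdomen_tip_mm": 1.0,
                    "head_volume_mm3": strength[i],
                    "lever_in_mm": 1.0,
                    "lever_out_mm": 1.0,
                    "incisive_region_mm": 1.0,
                    "percent_c": 10.0 * cn[i],
                    "percent_n": 10.0,
                }
            )
    return pd.DataFrame.from_records(records)


@dataclass
class AssemblyConfig:
    """Parameters of the community assembly simulator.

    ``mode`` selects the assembly rule: ``neutral`` (species drawn uniformly),
    ``filtering`` (species drawn towards a per-site trait optimum — produces
    trait under-dispersion) or ``competition`` (sequential limiting-similarity
    rejection — produces over-dispersion).  ``strength`` scales the kernel:
    0 reduces either non-neutral mode to neutral.  The default design mirrors
    the field survey: 30 sites x 2 sampling periods.
    """

    mode: str = "neutral"
    strength: float = 0.0
    n_sites: int = 30
    n_periods: int = 2
    richness_range: tuple[int, int] = (2, 8)
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("neutral", "filtering", "competition"):
            raise ValueError("mode must be neutral, filtering or competition")
        if self.strength < 0:
            raise ValueError("strength must be non-negative")
        lo, hi = self.richness_range
        if lo < 1 or hi < lo:
            raise ValueError("richness_range must satisfy 1 <= lo <= hi")


def _trait_z(traits: pd.DataFrame) -> np.ndarray:
    """Standardised (z-scored) species traits on the analysis scales."""
    z = np.column_stack(
        [
            np.log(traits["body_volume"].to_numpy(dtype=float)),
            np.log(traits["incisor_strength"].to_numpy(dtype=float)),
            traits["cn_ratio"].to_numpy(dtype=float),
        ]
    )
    sd = z.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (z - z.mean(axis=0)) / sd


def _geometric_abundances(rng: np.random.Generator, k: int, p: float = 0.35) -> np.ndarray:
    """Log-series-like abundances: geometric draws, at least 1 per species."""
    return rng.geometric(p, size=k)


def gen_communities(
    pool: SpeciesPool, traits: pd.DataFrame, cfg: AssemblyConfig
) -> pd.DataFrame:
    """Assemble a site x species abundance matrix under the configured rule.

    Returns a wide integer DataFrame with a (site, period) MultiIndex and one
    column per pool species.  Each row draws a richness uniformly from
    ``cfg.richness_range`` and selects that many species:

    * **neutral** — uniform sampling without replacement;
    * **filtering** — sampling weights ``exp(-s^2 ||z_i - z_site||^2 / 2)``
      around a per-row optimum ``z_site`` drawn uniformly over the pool's
      standardised trait range;
    * **competition** — greedy sequential assembly rejecting any candidate
      whose minimum standardised trait distance to the residents falls below
      ``s``, and choosing among admissible candidates with softmax weight
      ``exp(2 s d_min)`` so trait-distant species are favoured; infeasible
      rows are retried up to 50 times before failing.

    Abundances over selected species are geometric (log-series-like skew).
    """
    missing = traits.index.difference(pool.species.index)
    if len(missing) or len(pool.species.index.difference(traits.index)):
        raise ValueError("traits table must cover exactly the pool species")
    traits = traits.loc[pool.species.index]
    rng = np.random.default_rng(cfg.seed)
    z = _trait_z(traits)
    n_sp = pool.n_species
    lo, hi = cfg.richness_range
    if hi > n_sp:
        raise ValueError("richness_range exceeds pool size")
    s = cfg.strength
    zmin, zmax = z.min(axis=0), z.max(axis=0)

    rows = []
    index = []
    for site in range(1, cfg.n_sites + 1):
        for period in range(1, cfg.n_periods + 1):
            richness = int(rng.integers(lo, hi + 1))
            if cfg.mode == "neutral" or s == 0:
                chosen = rng.choice(n_sp, size=richness, replace=False)
            elif cfg.mode == "filtering":
                opt = rng.uniform(zmin, zmax)
                w = np.exp(-0.5 * s**2 * ((z - opt) ** 2).sum(axis=1))
                w = w / w.sum()
                chosen = rng.choice(n_sp, size=richness, replace=False, p=w)
            else:  # competition: limiting-similarity rejection
                chosen = None
                for _ in range(50):
                    picked = [int(rng.integers(n_sp))]
                    while len(picked) < richness:
                        rest = np.setdiff1d(np.arange(n_sp), picked)
                        dmin = np.sqrt(
                            ((z[rest, None, :] - z[picked][None, :, :]) ** 2).sum(
                                axis=2
                            )
                        ).min(axis=1)
                        admissible = rest[dmin >= s]
                        if len(admissible) == 0:
                            break
                        # among admissible candidates, prefer trait-distant
                        # ones: softmax in the minimum distance, gain 2s
                        w = np.exp(2.0 * s * dmin[dmin >= s])
                        picked.append(int(rng.choice(admissible, p=w / w.sum())))
                    if len(picked) == richness:
                        chosen = np.array(picked)
                        break
                if chosen is None:
                    raise RuntimeError(
                        f"competition assembly infeasible at site {site} period "
                        f"{period}: could not place {richness} species with "
                        f"min trait distance >= {s}; lower strength or richness"
                    )
            counts = np.zeros(n_sp, dtype=int)
            counts[chosen] = _geometric_abundances(rng, len(chosen))
            rows.append(counts)
            index.append((site, period))
    comm = pd.DataFrame(
        np.vstack(rows),
        index=pd.MultiIndex.from_tuples(index, names=["site", "period"]),
        columns=pool.species.index,
    )
    return comm


#: Default plant trait ranges: LDMC in mg g^-1, SLA in mm^2 mg^-1, C:N
#: dimensionless — spanning soft forbs through tough bunchgrasses.
DEFAULT_PLANT_RANGES = {
    "ldmc": (150.0, 450.0),
    "sla": (5.0, 30.0),
    "cn_ratio": (10.0, 60.0),
}

_PLANT_GROUP_FRACTIONS = {"grass": 3 / 16, "forb": 11 / 16, "woody": 2 / 16}


def gen_plants(
    n_species: int = 16,
    trait_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    ldmc_sla_correlation: float = -0.7,
) -> pd.DataFrame:
    """Generate a plant species x trait table.

    LDMC and SLA are drawn through a Gaussian copula with the given (negative)
    correlation and mapped uniformly onto their ranges, building in the
    leaf-economics association in which high-LDMC (tough) leaves have low SLA.
    Plant C:N is independent uniform.  Functional groups (grass / forb /
    woody) are assigned at the field proportions, with grasses placed on the
    toughest (highest-LDMC) species.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    ranges = dict(DEFAULT_PLANT_RANGES if trait_ranges is None else trait_ranges)
    for name, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if hi == lo:
            warnings.warn(f"degenerate range for {name}: column will be constant")
    rng = np.random.default_rng(seed)
    rho = float(ldmc_sla_correlation)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    zz = rng.multivariate_normal([0.0, 0.0], cov, size=n_species, method="cholesky")
    u = stats.norm.cdf(zz)
    lo, hi = ranges["ldmc"]
    ldmc = lo + u[:, 0] * (hi - lo)
    lo, hi = ranges["sla"]
    sla = lo + u[:, 1] * (hi - lo)
    lo, hi = ranges["cn_ratio"]
    cn = rng.uniform(lo, hi, size=n_species)

    ids = [f"pl{i + 1:02d}" for i in range(n_species)]
    plants = pd.DataFrame(
        {"ldmc": ldmc, "sla": sla, "cn_ratio": cn},
        index=pd.Index(ids, name="plant_species_id"),
    )
    n_grass = max(1, round(_PLANT_GROUP_FRACTIONS["grass"] * n_species))
    n_woody = max(1, round(_PLANT_GROUP_FRACTIONS["woody"] * n_species))
    n_grass = min(n_grass, n_species - 1)
    n_woody = min(n_woody, n_species - n_grass)
    group = np.array(["forb"] * n_species, dtype=object)
    by_ldmc = np.argsort(-plants["ldmc"].to_numpy())
    group[by_ldmc[:n_grass]] = "grass"
    group[by_ldmc[-n_woody:]] = "woody"
    plants.insert(0, "functional_group", group)
    return plants


@dataclass
class FeedingConfig:
    """Parameters of the cafeteria-assay consumption simulator.

    The preference kernel acts on standardised (z-scored) traits:

    * ``beta_matching`` — incisor strength <-> plant LDMC (positive means
      strong-mandibled species prefer tough leaves);
    * ``beta_cn`` — grasshopper C:N <-> plant C:N (default negative);
    * ``beta_bv`` — body volume <-> plant C:N (default positive).

    ``total_consumption_scale`` is the total leaf area (cm^2) one individual
    removes over a 48-h trial; recorded areas are quantised to the 0.05-cm^2
    measurement grid.
    """

    beta_matching: float = 0.8
    beta_cn: float = -0.5
    beta_bv: float = 0.4
    n_replicates_per_species: int = 12
    total_consumption_scale: float = 8.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for b in (self.beta_matching, self.beta_cn, self.beta_bv):
            if not np.isfinite(b):
                raise ValueError("kernel slopes must be finite")
        if self.n_replicates_per_species < 1:
            raise ValueError("n_replicates_per_species must be >= 1")
        if self.total_consumption_scale <= 0:
            raise ValueError("total_consumption_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


QUANTUM = 0.05  # cm^2 measurement grid of the damage assessment


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def gen_feeding(
    g_traits: pd.DataFrame, p_traits: pd.DataFrame, cfg: FeedingConfig
) -> pd.DataFrame:
    """Simulate individual-level consumption across the offered plant array.

    For individual *k* of grasshopper species *s*, the leaf area eaten from
    plant *p* is proportional to::

        exp( beta_matching * z(log IS_s) * z(LDMC_p)
           + beta_cn       * z(CN_s)     * z(CN_p)
           + beta_bv       * z(log BV_s) * z(CN_p)
           + eps_kp ),   eps_kp ~ N(0, noise_sd^2)

    scaled to ``total_consumption_scale`` cm^2 and quantised to the 0.05-cm^2
    grid.  A row that quantises to all zeros is regenerated once; if it
    zeroes out again the individual is kept with ``no_feeding = True``.

    Returns a DataFrame with one row per individual: ``species_id``,
    ``subfamily``, ``no_feeding``, then one column per plant species.
    """
    rng = np.random.default_rng(cfg.seed)
    z_is = _zscore(np.log(g_traits["incisor_strength"].to_numpy(dtype=float)))
    z_bv = _zscore(np.log(g_traits["body_volume"].to_numpy(dtype=float)))
    z_gcn = _zscore(g_traits["cn_ratio"].to_numpy(dtype=float))
    z_ldmc = _zscore(p_traits["ldmc"].to_numpy(dtype=float))
    z_pcn = _zscore(p_traits["cn_ratio"].to_numpy(dtype=float))

    pref = (
        cfg.beta_matching * np.outer(z_is, z_ldmc)
        + cfg.beta_cn * np.outer(z_gcn, z_pcn)
        + cfg.beta_bv * np.outer(z_bv, z_pcn)
    )  # species x plants

    n_plants = len(p_traits)
    rows, meta = [], []
    for si, (sp, trow) in enumerate(g_traits.iterrows()):
        for rep in range(1, cfg.n_replicates_per_species + 1):
            for _attempt in range(2):
                eps = rng.normal(0.0, cfg.noise_sd, size=n_plants)
                w = np.exp(pref[si] + eps)
                area = w / w.sum() * cfg.total_consumption_scale
                area = np.round(area / QUANTUM) * QUANTUM
                if area.sum() > 0:
                    break
            meta.append(
                {
                    "individual_id": f"{sp}_r{rep:02d}",
                    "species_id": sp,
                    "subfamily": trow.get("subfamily", ""),
                    "no_feeding": bool(area.sum() == 0),
                }
            )
            rows.append(area)
    out = pd.DataFrame(meta).set_index("individual_id")
    mat = pd.DataFrame(np.vstack(rows), index=out.index, columns=p_traits.index)
    return pd.concat([out, mat], axis=1)
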