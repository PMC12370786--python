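"""Diet niches from cafeteria assays and plant-herbivore trait matching.

Each grasshopper individual's diet is summarised by consumption-weighted
means (CWMs) of the plant traits it ate: with ``p_i`` the proportion of the
total leaf area taken from plant species *i*,

    CWM = sum_i p_i * trait_i,

a weighted mean lying inside the range of the consumed plants' trait values.
Diet differentiation among grasshopper species or subfamilies is tested per
plant trait with one-way F statistics whose p-values come from permuting
group labels.  Trait matching — does a consumer trait predict the plant
traits it prefers? — is quantified by regressing individual CWMs on the
species-mean herbivore trait with subfamily fixed intercepts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PLANT_TRAITS",
    "MATCHING_PAIRS",
    "cwm",
    "cwm_table",
    "niche_summary",
    "diet_difference_test",
    "trait_matching",
    "TraitMatchResult",
]

PLANT_TRAITS = ("ldmc", "sla", "cn_ratio")

#: The hypothesised consumer-resource trait linkages:
#: strong incisors <-> tough (high-LDMC) leaves; grasshopper C:N and body
#: volume <-> plant C:N.
MATCHING_PAIRS = (
    ("incisor_strength", "ldmc"),
    ("cn_ratio", "cn_ratio"),
    ("body_volume", "cn_ratio"),
)

#: Herbivore traits entering trait-matching on the log scale.
_LOG_HERBIVORE = {"incisor_strength": True, "body_volume": True, "cn_ratio": False}


def cwm(consumption: pd.Series, plant_trait: pd.Series) -> float:
    """Consumption-weighted mean of one plant trait for one individual.

    ``consumption`` maps plant species to leaf area eaten (cm^2); weights are
    the within-individual proportions.  Undefined (NaN) when nothing was
    eaten.
    """
    c = consumption.reindex(plant_trait.index)
    if c.isna().any():
        raise ValueError("consumption row missing plant species present in trait table")
    a = c.to_numpy(dtype=float)
    if (a < 0).any():
        raise ValueError("consumption must be non-negative")
    total = a.sum()
    if total == 0:
        warnings.warn("zero total consumption; CWM undefined")
        return float("nan")
    return float(a @ plant_trait.to_numpy(dtype=float) / total)


def cwm_table(feeding: pd.DataFrame, plants: pd.DataFrame) -> pd.DataFrame:
    """Per-individual CWMs of all plant traits.

    ``feeding`` is the wide consumption table (index individual_id, metadata
    columns ``species_id``/``subfamily`` plus one column per plant).
    Individuals with zero total consumption are excluded with a warning.

    Returns a DataFrame indexed by individual with ``species_id``,
    ``subfamily``, ``cwm_ldmc``, ``cwm_sla``, ``cwm_cn`` and
    ``total_consumed``.
    """
    plant_cols = [c for c in feeding.columns if c in plants.index]
    if len(plant_cols) != len(plants):
        missing = plants.index.difference(feeding.columns)
        raise ValueError(f"feeding table missing plant columns: {list(missing)}")
    mat = feeding[plant_cols].to_numpy(dtype=float)
    totals = mat.sum(axis=1)
    keep = totals > 0
    if (~keep).any():
        warnings.warn(
            f"excluding {int((~keep).sum())} individual(s) with zero total consumption"
        )
    p = mat[keep] / totals[keep, None]
    tr = plants.loc[plant_cols, list(PLANT_TRAITS)].to_numpy(dtype=float)
    cwms = p @ tr
    out = feeding.loc[keep, ["species_id", "subfamily"]].copy()
    out[["cwm_ldmc", "cwm_sla", "cwm_cn"]] = cwms
    out["total_consumed"] = totals[keep]
    return out


_CWM_COLS = ("cwm_ldmc", "cwm_sla", "cwm_cn")


def niche_summary(cwms: pd.DataFrame, level: str = "species") -> pd.DataFrame:
    """Group mean, SD, SE and n of each diet CWM trait.

    ``level`` is ``"species"`` (group by grasshopper species) or
    ``"subfamily"``.  Groups of one individual report an undefined (NaN) SD.
    The mean columns double as coordinates for plotting niches in plant trait
    space.
    """
    key = {"species": "species_id", "subfamily": "subfamily"}.get(level)
    if key is None:
        raise ValueError("level must be 'species' or 'subfamily'")
    g = cwms.groupby(key, sort=True)
    out = {"n": g.size()}
    for col in _CWM_COLS:
        out[f"{col}_mean"] = g[col].mean()
        out[f"{col}_sd"] = g[col].std(ddof=1)  # NaN when n = 1
        out[f"{col}_se"] = out[f"{col}_sd"] / np.sqrt(out["n"])
    return pd.DataFrame(out)


def _f_oneway_stat(values: np.ndarray, codes: np.ndarray, k: int) -> float:
    """One-way ANOVA F; NaN when the within-group variance is zero."""
    n = len(values)
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(k):
        v = values[codes == g]
        m = v.mean()
        ss_between += len(v) * (m - grand) ** 2
        ss_within += ((v - m) ** 2).sum()
    if ss_within == 0:
        return np.nan if ss_between == 0 else np.inf
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def diet_difference_test(
    cwms: pd.DataFrame,
    factor: str = "species",
    plant_trait: str = "ldmc",
    n_perm: int = 999,
    seed: int | None = 0,
) -> dict:
    """Permutation one-way F test of CWM differences among groups.

    The observed F compares group means of ``cwm_<plant_trait>`` across
    levels of ``factor`` (species or subfamily); the reference distribution
    permutes group labels ``n_perm`` times and the p-value is
    ``(b + 1) / (n_perm + 1)`` with ``b`` the number of null statistics at or
    above the observed one.  With completely degenerate data (all values
    identical) p = 1.

    Returns ``{"F", "p_value", "n_perm", "df_between", "df_within"}``.
    """
    key = {"species": "species_id", "subfamily": "subfamily"}.get(factor)
    if key is None:
        raise ValueError("factor must be 'species' or 'subfamily'")
    col = {"ldmc": "cwm_ldmc", "sla": "cwm_sla", "cn_ratio": "cwm_cn"}.get(plant_trait)
    if col is None:
        raise ValueError(f"plant_trait must be one of {PLANT_TRAITS}")
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives a coarse p-value resolution")
    counts = cwms[key].value_counts()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 groups with >= 2 individuals")
    codes, levels = pd.factorize(cwms[key])
    k = len(levels)
    values = cwms[col].to_numpy(dtype=float)
    f_obs = _f_oneway_stat(values, codes, k)
    if np.isnan(f_obs):  # zero variance everywhere
        return {
            "F": np.nan,
            "p_value": 1.0,
            "n_perm": n_perm,
            "df_between": k - 1,
            "df_within": len(values) - k,
        }
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        f_null = _f_oneway_stat(values, codes[rng.permutation(len(codes))], k)
        if not np.isnan(f_null) and f_null >= f_obs:
            b += 1
    return {
        "F": float(f_obs),
        "p_value": (b + 1) / (n_perm + 1),
        "n_perm": n_perm,
        "df_between": k - 1,
        "df_within": len(values) - k,
    }


@dataclass
class TraitMatchResult:
    """OLS fit of individual diet CWMs on a species-mean herbivore trait."""

    herbivore_trait: str
    plant_trait: str
    slope: float
    slope_se: float
    p_value: float
    r2: float
    intercepts: dict[str, float]
    conf_int: tuple[float, float]
    n_obs: int


def trait_matching(
    g_traits: pd.DataFrame,
    cwms: pd.DataFrame,
    pair: tuple[str, str] = ("incisor_strength", "ldmc"),
) -> TraitMatchResult:
    """Quantify one hypothesised plant-herbivore trait linkage.

    Individual CWM values of the plant trait are regressed on the species-mean
    herbivore trait (log-transformed for body volume and incisor strength)
    with subfamily fixed intercepts absorbing guild-level diet differences.
    Only the three hypothesised linkages in ``MATCHING_PAIRS`` are accepted.
    A subfamily contributing fewer than two species cannot separate its
    intercept from its species' trait values; it is merged into the reference
    level with a warning.
    """
    if tuple(pair) not in MATCHING_PAIRS:
        raise ValueError(f"pair must be one of {MATCHING_PAIRS}")
    h_trait, p_trait = pair
    col = {"ldmc": "cwm_ldmc", "sla": "cwm_sla", "cn_ratio": "cwm_cn"}[p_trait]
    x_sp = g_traits[h_trait].astype(float)
    if _LOG_HERBIVORE[h_trait]:
        x_sp = np.log(x_sp)
    df = cwms[["species_id", "subfamily", col]].copy()
    df["x"] = df["species_id"].map(x_sp)
    if df["x"].isna().any():
        missing = df.loc[df["x"].isna(), "species_id"].unique()
        raise ValueError(f"species missing from trait table: {list(missing)}")

    sp_per_sub = df.groupby("subfamily")["species_id"].nunique()
    small = sp_per_sub[sp_per_sub < 2].index
    if len(small):
        warnings.warn(
            f"subfamilies with <2 species merged into reference: {list(small)}"
        )
        ref = sp_per_sub.idxmax()
        df.loc[df["subfamily"].isin(small), "subfamily"] = ref

    dummies = pd.get_dummies(df["subfamily"], drop_first=True, dtype=float)
    X = pd.concat([df["x"], dummies], axis=1)
    X = sm.add_constant(X)
    fit = sm.OLS(df[col].to_numpy(dtype=float), X.to_numpy(dtype=float)).fit()
    names = list(X.columns)
    ix = names.index("x")
    base = fit.params[0]
    intercepts = {"(reference)": float(base)}
    for j, name in enumerate(names):
        if j not in (0, ix):
            intercepts[str(name)] = float(base + fit.params[j])
    ci = fit.conf_int()[ix]
    return TraitMatchResult(
        herbivore_trait=h_trait,
        plant_trait=p_trait,
        slope=float(fit.params[ix]),
        slope_se=float(fit.bse[ix]),
        p_value=float(fit.pvalues[ix]),
        r2=float(fit.rsquared),
        intercepts=intercepts,
        conf_int=(float(ci[0]), float(ci[1])),
        n_obs=int(fit.nobs),
    )
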