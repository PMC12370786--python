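"""Functional dispersion of communities and trait-shuffling null models.

The core statistic is Rao's quadratic entropy

    Q = sum_i sum_j p_i p_j d_ij,

the expected trait distance between two individuals drawn at random from a
community, computed on a Gower distance matrix over the species trait table.
Departure from random assembly is quantified per community row with a
standardized effect size

    SES = (Q_obs - mean(Q_null)) / sd(Q_null),

where the null ensemble shuffles the species labels of the trait table
(equivalently, permutes the rows/columns of the distance matrix) while
holding abundances and richness fixed.  Negative SES indicates trait
under-dispersion (clustering, the classical signature of environmental
filtering); positive SES indicates over-dispersion (limiting similarity).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trait_metrics import DEFAULT_LOG_TRANSFORM, NUMERIC_TRAITS

__all__ = [
    "TRAIT_SETS",
    "trait_distance",
    "raos_q",
    "shuffle_traits",
    "ses_all_rows",
    "summarize_ses",
]

#: Valid trait-set labels for distance matrices and SES runs.
TRAIT_SETS = ("all", "body_volume", "incisor_strength", "cn_ratio", "subfamily")


def _gower_numeric(values: np.ndarray) -> np.ndarray:
    """Range-normalised absolute-difference matrix for one numeric trait."""
    rng = np.ptp(values)
    if rng == 0:
        warnings.warn("constant trait has zero range; it contributes 0 distance")
        return np.zeros((len(values), len(values)))
    v = values / rng
    return np.abs(v[:, None] - v[None, :])


def trait_distance(
    traits: pd.DataFrame,
    trait_set: str = "all",
    log_transform: bool = True,
    include_subfamily_in_all: bool = False,
) -> pd.DataFrame:
    """Species x species Gower distance matrix for one trait set.

    Numeric traits are (optionally log-transformed then) range-normalised to
    [0, 1] and contribute absolute differences; the categorical subfamily
    contributes 0 (same) or 1 (different).  Multi-trait sets average the
    per-trait contributions with equal weight.  ``trait_set="all"`` uses the
    three numeric traits; subfamily is analysed separately as a coarse
    phylogenetic proxy unless ``include_subfamily_in_all`` is set.
    """
    if trait_set not in TRAIT_SETS:
        raise ValueError(f"unknown trait_set {trait_set!r}; valid: {TRAIT_SETS}")
    parts = []
    if trait_set == "subfamily" or (trait_set == "all" and include_subfamily_in_all):
        sub = traits["subfamily"].to_numpy()
        parts.append((sub[:, None] != sub[None, :]).astype(float))
    if trait_set != "subfamily":
        names = NUMERIC_TRAITS if trait_set == "all" else (trait_set,)
        for name in names:
            v = traits[name].to_numpy(dtype=float)
            if log_transform and DEFAULT_LOG_TRANSFORM.get(name, False):
                if (v <= 0).any():
                    raise ValueError(f"cannot log-transform non-positive {name}")
                v = np.log(v)
            parts.append(_gower_numeric(v))
    d = np.mean(parts, axis=0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=traits.index, columns=traits.index)


def raos_q(abundances: pd.Series | np.ndarray, dist: pd.DataFrame) -> float:
    """Rao's quadratic entropy of one community row.

    ``abundances`` maps species to non-negative counts; relative abundances
    ``p_i`` are formed within the row and ``Q = p' D p`` is returned.  Species
    present in ``dist`` but absent from ``abundances`` count as zero.
    """
    if isinstance(abundances, pd.Series):
        a = abundances.reindex(dist.index, fill_value=0).to_numpy(dtype=float)
        extra = abundances.index.difference(dist.index)
        if len(extra) and (abundances[extra] > 0).any():
            raise ValueError(f"abundances contain species not in distance matrix: {list(extra)}")
    else:
        a = np.asarray(abundances, dtype=float)
        if a.shape[0] != dist.shape[0]:
            raise ValueError("abundance vector length does not match distance matrix")
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total == 0:
        raise ValueError("all-zero community row; filter empty rows first")
    p = a / total
    return float(p @ dist.to_numpy() @ p)


def shuffle_traits(
    traits: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Uniformly permute the species labels over the trait rows.

    The multiset of trait rows is unchanged; only which species carries which
    trait vector is randomised.  Combined with fixed community abundances this
    is the trait-shuffle null: richness and abundance structure are held
    constant within every site.
    """
    if len(traits) < 2:
        raise ValueError("need >= 2 species to shuffle")
    perm = rng.permutation(len(traits))
    out = traits.copy()
    out.index = traits.index[perm]
    return out.loc[traits.index]


def ses_all_rows(
    comm: pd.DataFrame,
    traits: pd.DataFrame,
    trait_sets: Sequence[str] = TRAIT_SETS,
    n_null: int = 999,
    seed: int | None = 0,
    per_row_shuffle: bool = False,
    presence_only: bool = False,
    include_subfamily_in_all: bool = False,
) -> pd.DataFrame:
    """Standardized effect sizes of Rao's Q for every community row.

    For each of ``n_null`` replicates one random species-label permutation of
    the trait table is applied globally — the same shuffled table scores all
    rows, so a replicate is one coherent simulated community set
    (``per_row_shuffle=True`` draws an independent permutation per row
    instead).  Per row and trait set the SES is formed from the null mean and
    SD; rows whose null SD is zero (e.g. single-species rows) get an
    undefined (NaN) SES and are excluded from downstream summaries.

    ``presence_only`` replaces abundance weights with uniform weights over
    the species present.

    Returns a tidy DataFrame with columns ``site``, ``period``,
    ``trait_set``, ``q_obs``, ``null_mean``, ``null_sd``, ``ses``,
    ``n_null``.
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    for ts in trait_sets:
        if ts not in TRAIT_SETS:
            raise ValueError(f"unknown trait_set {ts!r}; valid: {TRAIT_SETS}")
    extra = comm.columns.difference(traits.index)
    if len(extra):
        raise ValueError(f"community species missing from trait table: {list(extra)}")

    # align abundance matrix to trait-table species order
    a = (
        comm.reindex(columns=traits.index, fill_value=0)
        .to_numpy(dtype=float)
    )
    if (a.sum(axis=1) == 0).any():
        raise ValueError("community matrix contains all-zero rows; drop them first")
    if presence_only:
        a = (a > 0).astype(float)
    p = a / a.sum(axis=1, keepdims=True)  # rows x species

    rng = np.random.default_rng(seed)
    n_rows, n_sp = p.shape
    # one shared permutation stream so every trait set sees the same nulls,
    # mirroring a single shuffled trait table feeding all five analyses
    if per_row_shuffle:
        perms = np.stack(
            [
                np.stack([rng.permutation(n_sp) for _ in range(n_rows)])
                for _ in range(n_null)
            ]
        )  # n_null x n_rows x n_sp
    else:
        perms = np.stack([rng.permutation(n_sp) for _ in range(n_null)])

    out = []
    for ts in trait_sets:
        d = trait_distance(
            traits, ts, include_subfamily_in_all=include_subfamily_in_all
        ).to_numpy()
        q_obs = np.einsum("rs,st,rt->r", p, d, p)
        q_null = np.empty((n_null, n_rows))
        for k in range(n_null):
            if per_row_shuffle:
                for r in range(n_rows):
                    pk = perms[k, r]
                    q_null[k, r] = p[r] @ d[np.ix_(pk, pk)] @ p[r]
            else:
                pk = perms[k]
                dn = d[np.ix_(pk, pk)]
                q_null[k] = np.einsum("rs,st,rt->r", p, dn, p)
        mu = q_null.mean(axis=0)
        sd = q_null.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ses = np.where(sd > 0, (q_obs - mu) / sd, np.nan)
        frame = pd.DataFrame(
            {
                "site": comm.index.get_level_values("site"),
                "period": comm.index.get_level_values("period"),
                "trait_set": ts,
                "q_obs": q_obs,
                "null_mean": mu,
                "null_sd": sd,
                "ses": ses,
                "n_null": n_null,
            }
        )
        out.append(frame)
    return pd.concat(out, ignore_index=True)


def summarize_ses(
    results: pd.DataFrame, group_by: Sequence[str] = ("trait_set",)
) -> pd.DataFrame:
    """Group-level SES summaries with one-sample t-tests against zero.

    Undefined (NaN) SES values are dropped first.  Groups with fewer than two
    defined values are omitted with a warning.  A zero-variance group is
    reported with its mean and SE 0 but a NaN (degenerate) t and p.
    """
    defined = results.dropna(subset=["ses"])
    rows = []
    for key, grp in defined.groupby(list(group_by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        vals = grp["ses"].to_numpy()
        if len(vals) < 2:
            warnings.warn(f"group {key} has <2 defined SES values; omitted")
            continue
        mean = vals.mean()
        sd = vals.std(ddof=1)
        se = sd / np.sqrt(len(vals))
        if sd == 0:
            t, pval = np.nan, np.nan
            warnings.warn(f"group {key} has zero SES variance; t-test degenerate")
        else:
            t, pval = stats.ttest_1samp(vals, 0.0)
        rows.append(
            dict(
                zip(group_by, key),
                n=len(vals),
                mean_ses=mean,
                se_ses=se,
                t=t,
                p_value=pval,
            )
        )
    return pd.DataFrame(rows)
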