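"""Grasshopper functional traits from raw morphometrics.

Three focal traits are derived per specimen:

* **body volume** (mm^3) — cylinder approximation ``V = (pi/4) * L * D^2``
  with ``D`` the arithmetic mean of four body diameters (head, thorax,
  abdomen base, abdomen tip);
* **incisor strength** (relative force index) — mandible lever equation
  ``F_in * L_in / (L_out * R_i)`` with head volume standing in for the
  adductor-muscle force ``F_in`` and ``R_i`` the length of the incisive
  region;
* **C:N ratio** (dimensionless mass ratio) — percent carbon over percent
  nitrogen from elemental analysis.

Specimen-level traits are averaged to species level, and the correlation
structure among species-mean traits is summarised with pairwise Pearson
correlations and a PCA on the correlation matrix.  Body volume and incisor
strength are log-transformed by default; C:N enters untransformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SPECIMEN_COLUMNS",
    "DIAMETER_COLUMNS",
    "DEFAULT_LOG_TRANSFORM",
    "NUMERIC_TRAITS",
    "incisor_strength",
    "body_volume",
    "cn_ratio",
    "derive_traits",
    "species_means",
    "pairwise_correlations",
    "trait_pca",
    "PCASummary",
]

#: Numeric trait columns of a species trait table, in canonical order.
NUMERIC_TRAITS = ("body_volume", "incisor_strength", "cn_ratio")

#: Which traits are log-transformed before correlation / ordination / distance
#: computations.  Body volume and incisor strength are right-skewed across
#: species; C:N is already close to symmetric on the raw scale.
DEFAULT_LOG_TRANSFORM: Mapping[str, bool] = {
    "body_volume": True,
    "incisor_strength": True,
    "cn_ratio": False,
}

DIAMETER_COLUMNS = (
    "diam_head_mm",
    "diam_thorax_mm",
    "diam_abdomen_base_mm",
    "diam_abdomen_tip_mm",
)

#: Expected columns of a specimen table (one row per measured individual).
SPECIMEN_COLUMNS = (
    "species_id",
    "sex",
    "body_length_mm",
    *DIAMETER_COLUMNS,
    "head_volume_mm3",
    "lever_in_mm",
    "lever_out_mm",
    "incisive_region_mm",
    "percent_c",
    "percent_n",
)


def incisor_strength(f_in, lever_in, lever_out, incisive_region):
    """Bite-force index from the mandible lever equation.

    Parameters
    ----------
    f_in
        Adductor-muscle force proxy (head volume, mm^3).
    lever_in
        Distance from muscle attachment to the mandible axis of rotation (mm).
    lever_out
        Distance from the incisive region to the axis of rotation (mm).
    incisive_region
        Length of the incisive region (mm).

    Returns
    -------
    float or ndarray
        ``f_in * lever_in / (lever_out * incisive_region)``.  Units only
        partially cancel, so the result is treated as a relative index.
    """
    lever_out = np.asarray(lever_out, dtype=float)
    incisive_region = np.asarray(incisive_region, dtype=float)
    if np.any(lever_out <= 0) or np.any(incisive_region <= 0):
        raise ValueError("lever_out and incisive_region must be positive")
    out = np.asarray(f_in, dtype=float) * np.asarray(lever_in, dtype=float) / (
        lever_out * incisive_region
    )
    return out if out.ndim else float(out)


def body_volume(length, diameters):
    """Body volume (mm^3) from the cylinder approximation ``(pi/4) L D^2``.

    ``diameters`` holds the four body diameters (head, thorax, abdomen base,
    abdomen tip); ``D`` is their arithmetic mean, averaged *before* squaring.
    For vectorised use, ``diameters`` may be an ``(n, 4)`` array paired with a
    length-``n`` ``length``.
    """
    diam = np.asarray(diameters, dtype=float)
    if diam.shape[-1] != 4:
        raise ValueError(f"expected exactly 4 diameters, got shape {diam.shape}")
    if np.any(~np.isfinite(diam)) or np.any(diam <= 0):
        raise ValueError("all four diameters must be positive and finite")
    length = np.asarray(length, dtype=float)
    if np.any(length <= 0):
        raise ValueError("body length must be positive")
    d_mean = diam.mean(axis=-1)
    out = (np.pi / 4.0) * length * d_mean**2
    return out if out.ndim else float(out)


def cn_ratio(percent_c, percent_n):
    """Carbon-to-nitrogen mass ratio ``%C / %N`` from elemental analysis."""
    percent_n = np.asarray(percent_n, dtype=float)
    if np.any(percent_n <= 0):
        raise ValueError("percent_n must be positive")
    out = np.asarray(percent_c, dtype=float) / percent_n
    return out if out.ndim else float(out)


def derive_traits(specimens: pd.DataFrame) -> pd.DataFrame:
    """Compute the three focal traits for every specimen row.

    Returns a copy of ``specimens`` restricted to identifiers plus the derived
    ``body_volume``, ``incisor_strength`` and ``cn_ratio`` columns.
    """
    missing = [c for c in SPECIMEN_COLUMNS if c not in specimens.columns]
    if missing:
        raise ValueError(f"specimen table missing columns: {missing}")
    out = specimens[["species_id", "sex"]].copy()
    out["body_volume"] = body_volume(
        specimens["body_length_mm"].to_numpy(),
        specimens[list(DIAMETER_COLUMNS)].to_numpy(),
    )
    out["incisor_strength"] = incisor_strength(
        specimens["head_volume_mm3"].to_numpy(),
        specimens["lever_in_mm"].to_numpy(),
        specimens["lever_out_mm"].to_numpy(),
        specimens["incisive_region_mm"].to_numpy(),
    )
    out["cn_ratio"] = cn_ratio(
        specimens["percent_c"].to_numpy(), specimens["percent_n"].to_numpy()
    )
    return out


def species_means(
    specimens: pd.DataFrame, subfamily: Mapping[str, str] | pd.Series | None = None
) -> pd.DataFrame:
    """Average derived traits across individuals of each species.

    Parameters
    ----------
    specimens
        Raw specimen table (morphometrics) or a table already carrying the
        derived trait columns.
    subfamily
        Optional mapping ``species_id -> subfamily`` attached to the output.

    Returns
    -------
    DataFrame indexed by ``species_id`` with columns ``body_volume``,
    ``incisor_strength``, ``cn_ratio``, ``n_individuals`` and, when provided,
    ``subfamily``.  Sexes are pooled.
    """
    if not set(NUMERIC_TRAITS).issubset(specimens.columns):
        specimens = derive_traits(specimens)
    grouped = specimens.groupby("species_id", sort=True)
    table = grouped[list(NUMERIC_TRAITS)].mean()
    table["n_individuals"] = grouped.size()
    if subfamily is not None:
        sub = pd.Series(subfamily)
        unknown = table.index.difference(sub.index)
        if len(unknown):
            warnings.warn(f"no subfamily recorded for species: {list(unknown)}")
        table.insert(0, "subfamily", sub.reindex(table.index))
    return table


def _apply_log(
    table: pd.DataFrame, log_transform: Mapping[str, bool] | None
) -> pd.DataFrame:
    log_transform = DEFAULT_LOG_TRANSFORM if log_transform is None else log_transform
    out = table[list(NUMERIC_TRAITS)].astype(float).copy()
    for trait in NUMERIC_TRAITS:
        if log_transform.get(trait, False):
            if (out[trait] <= 0).any():
                raise ValueError(f"cannot log-transform non-positive {trait}")
            out[trait] = np.log(out[trait])
    return out


def pairwise_correlations(
    table: pd.DataFrame, log_transform: Mapping[str, bool] | None = None
) -> pd.DataFrame:
    """Pearson correlations among species-mean traits.

    Natural-log transforms are applied per ``log_transform`` (default: body
    volume and incisor strength logged, C:N raw).  Returns one row per
    unordered trait pair with columns ``trait_a``, ``trait_b``, ``r``,
    ``p_value``, ``n`` and ``transform``.  A constant column yields an
    undefined (NaN) correlation rather than an error.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 species for correlations")
    vals = _apply_log(table, log_transform)
    lt = DEFAULT_LOG_TRANSFORM if log_transform is None else log_transform
    rows = []
    for i, a in enumerate(NUMERIC_TRAITS):
        for b in NUMERIC_TRAITS[i + 1 :]:
            x, y = vals[a].to_numpy(), vals[b].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(f"constant trait column in pair ({a}, {b}); r undefined")
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x, y)
            rows.append(
                {
                    "trait_a": a,
                    "trait_b": b,
                    "r": r,
                    "p_value": p,
                    "n": len(x),
                    "transform": f"{'log' if lt.get(a) else 'raw'}/"
                    f"{'log' if lt.get(b) else 'raw'}",
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PCASummary:
    """Eigendecomposition of the trait correlation matrix.

    Attributes
    ----------
    loadings
        traits x components matrix of unit-norm eigenvectors, sign-fixed so the
        largest-magnitude loading of each component is positive.
    variance_explained
        Proportion of total variance per component (sums to 1 over all
        retained components of a full-rank input).
    eigenvalues
        Eigenvalues of the correlation matrix, descending.
    """

    loadings: pd.DataFrame
    variance_explained: pd.Series
    eigenvalues: np.ndarray = field(repr=False, default=None)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def trait_pca(
    table: pd.DataFrame,
    log_transform: Mapping[str, bool] | None = None,
    scale: bool = True,
) -> PCASummary:
    """PCA of the three species-mean traits.

    Computed as the eigendecomposition of the correlation matrix (``scale=True``,
    the default — the traits carry incommensurate units) or the covariance
    matrix of the optionally log-transformed traits.  Near-zero eigenvalues of
    rank-deficient inputs are dropped, so fewer components than traits may be
    returned; ``variance_explained`` is always normalised by the total
    variance, so the retained proportions still sum to 1 up to round-off for
    full-rank data.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 species for PCA")
    vals = _apply_log(table, log_transform)
    x = vals.to_numpy()
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant trait column; cannot scale to unit variance")
        x = x / sd
    cov = np.cov(x, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    total = eigval.sum()
    keep = eigval > max(1e-10 * total, 0.0)
    if keep.sum() < len(eigval):
        warnings.warn(
            f"rank-deficient trait matrix: retaining {int(keep.sum())} components"
        )
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    # sign convention: dominant loading of each component is positive
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] *= -1
    comps = [f"PC{j + 1}" for j in range(eigvec.shape[1])]
    return PCASummary(
        loadings=pd.DataFrame(eigvec, index=list(NUMERIC_TRAITS), columns=comps),
        variance_explained=pd.Series(eigval / total, index=comps),
        eigenvalues=eigval,
    )
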