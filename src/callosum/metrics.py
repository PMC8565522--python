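"""Per-subject scalars: subregional connection probability and weighted DI.

Connection probability of subject s to network n averages the subject's
probability map over the *template* CC mask: P(s, n) = sum_v P(s, v, n) / V,
with V the fixed template voxel count (voxels without streamline support
contribute zero).

The probability-weighted diffusion index of a subregion is
DI(s, n) = sum_v w(v, n) * DI(s, v) / sum_v w(v, n), over voxels with
positive weight whose *FA* exceeds the exclusion threshold (default 0.2,
screening out gray matter / CSF partial volume; the subject's FA volume
gates all four indices). Weights default to the population atlas channel
(the map a native-space analysis would transform onto the subject); a
config switch selects the subject's own map instead.

Nuisance covariates (TIV, sex, education — never age) are removed by OLS
residualization with the grand mean restored, applied per (network, index)
across subjects; the operation is idempotent and mean-preserving.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .atlas import PopulationAtlas
from .connectivity import ProbabilityMap
from .networks import DIFFUSION_INDICES, network_names

__all__ = ["connection_probability", "weighted_index", "residualize",
           "extract_records", "COVARIATE_COLUMNS"]

COVARIATE_COLUMNS = ("tiv_cm3", "sex", "education_years")


def connection_probability(pmap: ProbabilityMap, template_cc_mask: np.ndarray,
                           ) -> np.ndarray:
    """P(s, n) for all networks: mean of P(s, v, n) over the template mask."""
    mask = np.asarray(template_cc_mask, bool)
    v = int(mask.sum())
    if v == 0:
        raise ValueError("template CC mask is empty")
    if mask.shape != pmap.probs.shape[:3]:
        raise ValueError("mask does not match the probability-map grid")
    return pmap.probs[mask].sum(axis=0) / v


def weighted_index(weights: np.ndarray, index_volume: np.ndarray,
                   fa_volume: np.ndarray, fa_threshold: float = 0.2) -> float:
    """Probability-weighted mean of one index over one subregion channel.

    Voxels contribute iff weight > 0 and FA > ``fa_threshold``. Returns NaN
    (with a warning) when no voxel survives.
    """
    w = np.asarray(weights, float)
    di = np.asarray(index_volume, float)
    fa = np.asarray(fa_volume, float)
    keep = (w > 0) & (fa > fa_threshold)
    if not keep.any():
        warnings.warn("no voxel above the FA threshold with positive weight; "
                      "weighted index undefined", stacklevel=2)
        return float("nan")
    return float((w[keep] * di[keep]).sum() / w[keep].sum())


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(x.shape[1]):
        others = np.delete(x, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, x[:, j], rcond=None)
        if np.allclose(others @ beta, x[:, j], atol=1e-8 * max(1.0, np.abs(x[:, j]).max())):
            bad.append(names[j])
    return bad


def residualize(values, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of values on (intercept + covariates), grand mean restored.

    ``values`` is (n,) or (n, m); covariates are the nuisance columns only
    (age is deliberately not among them). Raises on rank deficiency, naming
    the collinear columns.
    """
    y = np.asarray(values, float)
    flat = y.ndim == 1
    y = y[:, None] if flat else y
    cov = np.asarray(covariates, float)
    if np.isnan(cov).any():
        raise ValueError("covariates contain missing values")
    n, p = cov.shape
    if n < p + 3:
        raise ValueError(f"need at least {p + 3} subjects for {p} covariates, got {n}")
    x = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        names = ["intercept", *map(str, covariates.columns)]
        raise ValueError(f"covariate matrix is rank deficient; collinear columns: "
                         f"{_collinear_columns(x, names)}")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta + y.mean(axis=0, keepdims=True)
    return resid[:, 0] if flat else resid


def extract_records(
    cohort: pd.DataFrame,
    maps: list[ProbabilityMap],
    volumes: list[dict[str, np.ndarray]],
    atlas: PopulationAtlas,
    template_cc_mask: np.ndarray,
    fa_threshold: float = 0.2,
    weight_source: str = "population",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the per-subject record table and the long DI table.

    Returns ``(records, di_long)``: ``records`` is wide (demographics plus
    ``conn_prob_<network>`` columns); ``di_long`` has one row per subject x
    network x index with raw and covariate-residualized values. Undefined DI
    cells (no surviving voxel) stay NaN and are excluded from residualization
    pairwise.
    """
    if weight_source not in ("population", "subject"):
        raise ValueError("weight_source must be 'population' or 'subject'")
    if not len(cohort) == len(maps) == len(volumes):
        raise ValueError("cohort, maps and volumes must align one-to-one")
    names = network_names(atlas.k)

    rec_rows = []
    long_rows = []
    for (_, subj), pmap, vols in zip(cohort.iterrows(), maps, volumes):
        p_sn = connection_probability(pmap, template_cc_mask)
        row = dict(subj)
        for n, name in enumerate(names):
            row[f"conn_prob_{name}"] = p_sn[n]
        rec_rows.append(row)
        for n, name in enumerate(names):
            w = (atlas.probs if weight_source == "population" else pmap.probs)[..., n]
            for index in DIFFUSION_INDICES:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    val = weighted_index(w, vols[index], vols["FA"], fa_threshold)
                long_rows.append({"subject_id": subj["id"], "network": name,
                                  "index": index, "value": val})
    records = pd.DataFrame(rec_rows)
    di_long = pd.DataFrame(long_rows)

    # covariate residualization per (network, index) across subjects
    cov = cohort.set_index("id")[list(COVARIATE_COLUMNS)]
    di_long["value_residual"] = np.nan
    for (_, _), grp in di_long.groupby(["network", "index"], sort=False):
        ok = grp["value"].notna()
        if ok.sum() >= len(COVARIATE_COLUMNS) + 3:
            ids = grp.loc[ok, "subject_id"]
            res = residualize(grp.loc[ok, "value"].to_numpy(), cov.loc[ids])
            di_long.loc[grp.index[ok], "value_residual"] = res
    return records, di_long
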