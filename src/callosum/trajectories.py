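"""Quadratic lifespan trajectories of subregional diffusion indices.

Each (subregion, index) series is fitted with ordinary least squares to

    DI = C + A * age + B * age^2,

reported in the raw-age parameterization. Internally the design is centered
(ages minus their mean) for conditioning and the coefficients and their
covariance are mapped back exactly. Fit quality is the coefficient of
determination with its adjusted form

    R2_adj = 1 - (1 - R2) * (n - 1) / (n - p - 1),  p = 2,

(the regressors age and age^2; the intercept is not counted in p) and the
overall-fit p-value comes from the regression F statistic. The trajectory's
turning point — the age of peak FA, or of minimum diffusivity — is the
analytic extremum -A / (2B), flagged when it falls outside the observed age
range; B = 0 has no turning point.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .networks import DIFFUSION_INDICES
from .generative import COEFF_SCALES

__all__ = ["TrajectoryFit", "adjusted_r2", "fit_quadratic", "turning_age",
           "fit_all", "table2_style", "curve_points"]

N_PREDICTORS = 2  # age and age^2


def adjusted_r2(r2: float, n: int, p: int = N_PREDICTORS) -> float:
    """Adjusted coefficient of determination, 1-(1-R2)(n-1)/(n-p-1)."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass
class TrajectoryFit:
    network: str
    index: str
    C: float
    A: float
    B: float
    se_C: float
    se_A: float
    se_B: float
    r2: float
    r2_adj: float
    p_value: float
    turning_age: float | None
    turning_in_range: bool
    n_subjects: int
    age_min: float
    age_max: float

    def predict(self, ages) -> np.ndarray:
        a = np.asarray(ages, dtype=float)
        return self.C + self.A * a + self.B * a**2


def fit_quadratic(ages, values, network: str = "", index: str = "") -> TrajectoryFit:
    """Least-squares quadratic age fit for one subregion x index series."""
    a = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = np.isfinite(a) & np.isfinite(y)
    a, y = a[keep], y[keep]
    n = a.size
    if n < 4:
        raise ValueError(f"need at least 4 usable subjects, got {n}")
    if np.ptp(a) == 0:
        raise ValueError("degenerate design: all ages identical")

    m = a.mean()
    ac = a - m
    x = np.column_stack([np.ones(n), ac, ac**2])
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    dof = n - 3
    sigma2 = rss / dof if dof > 0 else np.nan
    cov_c = sigma2 * np.linalg.inv(x.T @ x)

    # exact back-transform of centered coefficients to the raw-age scale
    t = np.array([[1.0, -m, m * m], [0.0, 1.0, -2.0 * m], [0.0, 0.0, 1.0]])
    raw = t @ beta
    cov = t @ cov_c @ t.T
    se = np.sqrt(np.diag(cov))

    if r2 >= 1.0:
        f_p = 0.0
    else:
        f = (r2 / N_PREDICTORS) / ((1.0 - r2) / (n - N_PREDICTORS - 1))
        f_p = float(stats.f.sf(f, N_PREDICTORS, n - N_PREDICTORS - 1))

    c, aa, bb = (float(v) for v in raw)
    tp = None if bb == 0.0 else -aa / (2.0 * bb)
    in_range = tp is not None and a.min() <= tp <= a.max()
    return TrajectoryFit(
        network=network, index=index, C=c, A=aa, B=bb,
        se_C=float(se[0]), se_A=float(se[1]), se_B=float(se[2]),
        r2=float(r2), r2_adj=float(adjusted_r2(r2, n)), p_value=f_p,
        turning_age=tp, turning_in_range=bool(in_range), n_subjects=int(n),
        age_min=float(a.min()), age_max=float(a.max()),
    )


def turning_age(fit: TrajectoryFit) -> float | None:
    """Extremum age -A/(2B) of a fitted trajectory; None when B = 0."""
    if fit.B == 0.0:
        return None
    return -fit.A / (2.0 * fit.B)


def fit_all(di_long: pd.DataFrame, cohort: pd.DataFrame,
            value_column: str = "value_residual") -> pd.DataFrame:
    """One quadratic fit per (network, index) from the long DI table.

    Missing DI values are dropped pairwise; any cell with fewer than four
    usable subjects is reported with ``status='failed'`` and the run
    continues. Returns a tidy DataFrame of fit parameters.
    """
    if di_long.empty:
        raise ValueError("empty DI table")
    if value_column not in di_long.columns:
        raise ValueError(f"column {value_column!r} missing from the DI table")
    ages = cohort.set_index("id")["age"]
    rows = []
    for (network, index), grp in di_long.groupby(["network", "index"], sort=False):
        y = grp[value_column].to_numpy(dtype=float)
        a = ages.reindex(grp["subject_id"]).to_numpy(dtype=float)
        try:
            fit = fit_quadratic(a, y, network=network, index=index)
            row = asdict(fit)
            row["status"] = "ok"
        except ValueError as err:
            row = {"network": network, "index": index, "status": f"failed: {err}",
                   "n_subjects": int(np.isfinite(y).sum())}
        rows.append(row)
    out = pd.DataFrame(rows)
    cat = pd.Categorical(out["index"], categories=list(DIFFUSION_INDICES), ordered=True)
    return out.assign(_ord=cat).sort_values(["_ord", "network"]).drop(columns="_ord") \
              .reset_index(drop=True)


def table2_style(fits: pd.DataFrame) -> pd.DataFrame:
    """Rescale fitted coefficients to the conventional printing scales.

    FA: intercept x1, linear x10^-2, quadratic x10^-4; diffusivities:
    x10^-3 / x10^-5 / x10^-7 (absolute units remain mm^2/s).
    """
    rows = []
    for _, r in fits.iterrows():
        if not str(r.get("status", "ok")).startswith("ok"):
            continue
        sc, sa, sb = COEFF_SCALES[r["index"]]
        rows.append({
            "index": r["index"], "network": r["network"],
            "intercept": r["C"] / sc, "linear": r["A"] / sa, "quadratic": r["B"] / sb,
            "r2": r["r2"], "r2_adj": r["r2_adj"], "p_value": r["p_value"],
            "turning_age": r["turning_age"], "turning_in_range": r["turning_in_range"],
            "n_subjects": r["n_subjects"],
        })
    return pd.DataFrame(rows)


def curve_points(fit: TrajectoryFit, n_points: int = 141) -> pd.DataFrame:
    """Fitted-curve coordinates over the observed age range (plotting hook)."""
    a = np.linspace(fit.age_min, fit.age_max, n_points)
    return pd.DataFrame({"network": fit.network, "index": fit.index,
                         "age": a, "value": fit.predict(a)})
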