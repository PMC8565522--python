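"""Covariate-adjusted group comparisons with Bonferroni-corrected post hocs.

Age-group differences in subregional connection probability use an ANCOVA
expressed as an ordinary linear model: P(s, n) ~ age-group indicators + sex +
education + TIV. The omnibus F tests the group factor against the
covariates-only model; post hoc pairwise contrasts compare covariate-adjusted
group means with pooled-error t tests, Bonferroni-corrected over the
m = g(g-1)/2 contrasts.

Between-subregion differences in a diffusion index are a simplification of a
repeated-measures design: values are residualized on age, sex, education and
TIV, then subregion pairs are compared with paired t tests, Bonferroni m =
K(K-1)/2. Sphericity machinery is deliberately not reproduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .metrics import residualize

__all__ = ["GroupComparison", "SubregionComparison", "bonferroni",
           "compare_age_groups", "compare_subregions"]

_COVARIATES = ["sex", "education_years", "tiv_cm3"]


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-corrected p value, min(1, p * m)."""
    return float(min(1.0, p_raw * m))


@dataclass
class GroupComparison:
    network: str
    f_stat: float
    p_omnibus: float
    pairwise: pd.DataFrame  # group_i, group_j, diff, p_raw, p_bonf, significant
    n_groups: int
    n_subjects: int
    dropped_groups: list[str]
    coef_covariates: dict[str, float]


def compare_age_groups(records: pd.DataFrame, network: str,
                       alpha: float = 0.05) -> GroupComparison:
    """ANCOVA-style comparison of P(s, n) across the decade age groups."""
    col = f"conn_prob_{network}"
    if col not in records.columns:
        raise ValueError(f"records lack column {col!r}")
    df = records.dropna(subset=[col, "age_group", *_COVARIATES]).copy()

    sizes = df.groupby("age_group")["id"].count()
    dropped = sorted(sizes.index[sizes < 2])
    if dropped:
        warnings.warn(f"dropping age group(s) with < 2 subjects: {dropped}",
                      stacklevel=2)
        df = df[~df["age_group"].isin(dropped)]
    groups = sorted(df["age_group"].unique())
    g = len(groups)
    if g < 2:
        raise ValueError("need at least two age groups with >= 2 subjects")

    dummies = pd.get_dummies(df["age_group"], drop_first=True, dtype=float)
    dummies = dummies.reindex(columns=groups[1:], fill_value=0.0)
    x_full = sm.add_constant(pd.concat([dummies, df[_COVARIATES]], axis=1))
    y = df[col].astype(float)
    full = sm.OLS(y, x_full.astype(float)).fit()
    restricted = sm.OLS(y, sm.add_constant(df[_COVARIATES].astype(float))).fit()
    f_stat, p_omnibus, _ = full.compare_f_test(restricted)

    # adjusted group means differ by the dummy coefficients (reference = groups[0])
    m = g * (g - 1) // 2
    names = list(x_full.columns)
    rows = []
    for i in range(g):
        for j in range(i + 1, g):
            contrast = np.zeros(len(names))
            if i > 0:
                contrast[names.index(groups[i])] = 1.0
            contrast[names.index(groups[j])] -= 1.0
            tt = full.t_test(contrast)
            p_raw = float(tt.pvalue)
            rows.append({
                "group_i": groups[i], "group_j": groups[j],
                "diff": float(tt.effect[0]),
                "p_raw": p_raw, "p_bonf": bonferroni(p_raw, m),
                "significant": bonferroni(p_raw, m) < alpha,
            })
    return GroupComparison(
        network=network, f_stat=float(f_stat), p_omnibus=float(p_omnibus),
        pairwise=pd.DataFrame(rows), n_groups=g, n_subjects=len(df),
        dropped_groups=[str(d) for d in dropped],
        coef_covariates={c: float(full.params[c]) for c in _COVARIATES},
    )


@dataclass
class SubregionComparison:
    index: str
    pairwise: pd.DataFrame
    means: pd.Series  # residualized subregion means, descending
    n_comparisons: int

    @property
    def ordering(self) -> list[str]:
        """Subregions from highest to lowest residualized mean."""
        return list(self.means.index)


def compare_subregions(di_long: pd.DataFrame, cohort: pd.DataFrame, index: str,
                       alpha: float = 0.05) -> SubregionComparison:
    """Paired between-subregion contrasts of one diffusion index.

    Residualizes the raw values on age + sex + education + TIV across
    subjects, then runs paired t tests for every subregion pair with
    Bonferroni correction. Subjects missing a value in a subregion are
    dropped from the pairs involving it.
    """
    sub = di_long[di_long["index"] == index]
    if sub.empty:
        raise ValueError(f"no rows for diffusion index {index!r}")
    wide = sub.pivot(index="subject_id", columns="network", values="value")
    demo = cohort.set_index("id").loc[wide.index, ["age", *_COVARIATES]]

    resid = pd.DataFrame(index=wide.index, columns=wide.columns, dtype=float)
    for net in wide.columns:
        ok = wide[net].notna()
        if ok.sum() >= len(demo.columns) + 3:
            resid.loc[ok, net] = residualize(wide.loc[ok, net].to_numpy(),
                                             demo.loc[ok])
    nets = list(wide.columns)
    k = len(nets)
    m = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            pair = resid[[nets[i], nets[j]]].dropna()
            d = pair.iloc[:, 0].to_numpy() - pair.iloc[:, 1].to_numpy()
            if len(d) < 3:
                rows.append({"region_i": nets[i], "region_j": nets[j],
                             "diff": np.nan, "p_raw": np.nan, "p_bonf": np.nan,
                             "significant": False, "n": len(d)})
                continue
            if np.allclose(d, d[0]) and np.isclose(d[0], 0.0):
                stat, p_raw = 0.0, 1.0
            else:
                stat, p_raw = sps.ttest_rel(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append({"region_i": nets[i], "region_j": nets[j],
                         "diff": float(d.mean()), "p_raw": float(p_raw),
                         "p_bonf": bonferroni(float(p_raw), m),
                         "significant": bonferroni(float(p_raw), m) < alpha,
                         "n": len(d)})
    means = resid.mean().sort_values(ascending=False)
    return SubregionComparison(index=index, pairwise=pd.DataFrame(rows),
                               means=means, n_comparisons=m)
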