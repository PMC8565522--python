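"""Synthetic cohort tables: age, sex, education, TIV, decade age groups.

Ages are integer years in [21, 90], partitioned into seven decade bins
(21-30, ..., 81-90). Two sampling modes are provided: ``"uniform"`` draws
ages uniformly over [21, 90]; ``"table1"`` reproduces the age-group sizes of
the study population the generative model was calibrated on
(73, 41, 42, 413, 305, 188, 24 for n = 1086; proportionally scaled
otherwise). Education (years) and total intracranial volume (cm^3) are drawn
per age group from Gaussian distributions whose means/SDs decline with age
the way the reference demographics do; sex is Bernoulli(1/2), coded 0/1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "AGE_MIN", "AGE_MAX", "AGE_GROUP_LABELS", "TABLE1_GROUP_SIZES",
    "age_group_of", "make_cohort", "read_cohort", "write_cohort",
]

AGE_MIN, AGE_MAX = 21, 90

AGE_GROUP_LABELS: tuple[str, ...] = (
    "21-30", "31-40", "41-50", "51-60", "61-70", "71-80", "81-90",
)

TABLE1_GROUP_SIZES: tuple[int, ...] = (73, 41, 42, 413, 305, 188, 24)

# per age group: (education mean, sd), (TIV mean, sd) — reference demographics
_EDU_STATS = ((17.40, 1.72), (18.15, 3.45), (13.93, 3.61), (9.90, 4.33),
              (7.87, 5.65), (3.49, 4.61), (4.38, 4.12))
_TIV_STATS = ((1477.32, 127.35), (1424.89, 113.63), (1423.28, 117.98),
              (1410.87, 124.59), (1385.47, 121.57), (1343.54, 113.32),
              (1307.07, 101.67))


def age_group_of(age) -> np.ndarray | str:
    """Decade age-group label(s) for integer age(s) in [21, 90]."""
    arr = np.atleast_1d(np.asarray(age))
    if ((arr < AGE_MIN) | (arr > AGE_MAX)).any():
        raise ValueError(f"ages must lie in [{AGE_MIN}, {AGE_MAX}]")
    idx = (arr - AGE_MIN) // 10
    out = np.asarray(AGE_GROUP_LABELS, dtype=object)[idx.astype(int)]
    return out if np.ndim(age) else out[0]


def _group_sizes(n: int) -> np.ndarray:
    """Group sizes for table1 mode: exact at n=1086, largest-remainder otherwise."""
    ref = np.asarray(TABLE1_GROUP_SIZES, dtype=float)
    if n == ref.sum():
        return ref.astype(int)
    quota = ref / ref.sum() * n
    sizes = np.floor(quota).astype(int)
    rem = n - sizes.sum()
    order = np.argsort(-(quota - sizes))
    sizes[order[:rem]] += 1
    return sizes


def make_cohort(
    n_subjects: int,
    age_distribution: str = "uniform",
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Sample a cohort table.

    Returns a DataFrame with columns ``id, age, sex, education_years,
    tiv_cm3, age_group``; ``age_group`` is a deterministic function of age.
    """
    if n_subjects < 1:
        raise ValueError("cohort must contain at least one subject")
    rng = np.random.default_rng(seed)

    if age_distribution == "uniform":
        ages = rng.integers(AGE_MIN, AGE_MAX + 1, size=n_subjects)
    elif age_distribution == "table1":
        sizes = _group_sizes(n_subjects)
        parts = [rng.integers(AGE_MIN + 10 * g, AGE_MIN + 10 * g + 10, size=s)
                 for g, s in enumerate(sizes)]
        ages = rng.permutation(np.concatenate(parts))
    else:
        raise ValueError(f"unknown age_distribution {age_distribution!r}")

    gi = ((ages - AGE_MIN) // 10).astype(int)
    sex = rng.integers(0, 2, size=n_subjects)
    edu_m, edu_s = np.array(_EDU_STATS).T
    tiv_m, tiv_s = np.array(_TIV_STATS).T
    education = np.clip(rng.normal(edu_m[gi], edu_s[gi]), 0.0, 25.0).round(1)
    tiv = np.clip(rng.normal(tiv_m[gi], tiv_s[gi]), 900.0, 2000.0).round(2)

    return pd.DataFrame({
        "id": [f"sub-{i + 1:04d}" for i in range(n_subjects)],
        "age": ages.astype(int),
        "sex": sex.astype(int),
        "education_years": education,
        "tiv_cm3": tiv,
        "age_group": age_group_of(ages),
    })


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str})
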