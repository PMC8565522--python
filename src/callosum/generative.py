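"""Generative model of subregional diffusion indices across the lifespan.

Each CC subregion n and diffusion index (FA, MD, RD, AD) follows a quadratic
age trajectory

    DI = C + A * age + B * age^2 + covariate effects + noise,

with default coefficients equal to the fitted lifespan trajectories of the
reference population (n = 1086, ages 21-90). Diffusivities are stored in
absolute mm^2/s: the conventional printing scales (intercept x10^-3, linear
x10^-5, quadratic x10^-7; FA linear x10^-2, quadratic x10^-4) are expanded
once, at model construction.

The residual noise SD of each row is, by default, calibrated so that the
quadratic signal explains the row's R^2 under a uniform age distribution:

    sigma^2 = Var_age[quadratic(age)] * (1 - R^2) / R^2.

Covariate effects (TIV, sex, education) default to zero and act around fixed
reference values, so nonzero settings leave the intercept interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import AGE_MAX, AGE_MIN
from .networks import DIFFUSION_INDICES, YEO7_NAMES
from .phantom import Phantom

__all__ = [
    "GenerativeModel", "noise_sd_for_r2", "simulate_index_values",
    "make_diffusion_volumes", "COEFF_SCALES", "PRINTED_COEFFICIENTS",
    "COVARIATE_REFERENCE", "N_REFERENCE",
]

N_REFERENCE = 1086  # size of the reference cohort the default rows were fitted on

# printing scales: value_absolute = value_printed * scale, per (intercept, linear, quadratic)
COEFF_SCALES: dict[str, tuple[float, float, float]] = {
    "FA": (1.0, 1e-2, 1e-4),
    "MD": (1e-3, 1e-5, 1e-7),
    "RD": (1e-3, 1e-5, 1e-7),
    "AD": (1e-3, 1e-5, 1e-7),
}

# (intercept, linear, quadratic, R2, R2_adj) at the printing scales above
PRINTED_COEFFICIENTS: dict[tuple[str, str], tuple[float, float, float, float, float]] = {
    ("FA", "VIS"): (0.737, 0.138, -0.143, 0.008, 0.006),
    ("FA", "SM"): (0.585, 0.160, -0.229, 0.059, 0.057),
    ("FA", "DA"): (0.644, 0.294, -0.337, 0.083, 0.082),
    ("FA", "VA"): (0.550, 0.291, -0.326, 0.070, 0.068),
    ("FA", "LN"): (0.468, 0.151, -0.210, 0.016, 0.014),
    ("FA", "FPN"): (0.541, 0.312, -0.344, 0.088, 0.086),
    ("FA", "DMN"): (0.581, 0.244, -0.283, 0.093, 0.091),
    ("MD", "VIS"): (0.962, -0.474, 0.531, 0.047, 0.046),
    ("MD", "SM"): (1.205, -1.060, 1.243, 0.170, 0.168),
    ("MD", "DA"): (1.062, -0.873, 0.979, 0.196, 0.194),
    ("MD", "VA"): (1.188, -0.980, 1.162, 0.212, 0.210),
    ("MD", "LN"): (1.250, -1.145, 1.318, 0.117, 0.115),
    ("MD", "FPN"): (1.196, -0.941, 1.089, 0.203, 0.201),
    ("MD", "DMN"): (1.156, -0.894, 1.017, 0.209, 0.207),
    ("RD", "VIS"): (0.480, -0.383, 0.429, 0.027, 0.025),
    ("RD", "SM"): (0.787, -0.866, 1.051, 0.141, 0.140),
    ("RD", "DA"): (0.629, -0.800, 0.911, 0.163, 0.161),
    ("RD", "VA"): (0.794, -0.891, 1.044, 0.177, 0.175),
    ("RD", "LN"): (0.921, -0.962, 1.133, 0.085, 0.084),
    ("RD", "FPN"): (0.810, -0.883, 1.014, 0.179, 0.178),
    ("RD", "DMN"): (0.754, -0.794, 0.917, 0.194, 0.193),
    ("AD", "VIS"): (1.926, -0.655, 0.734, 0.042, 0.040),
    ("AD", "SM"): (2.041, -1.447, 1.627, 0.164, 0.162),
    ("AD", "DA"): (1.927, -1.018, 1.115, 0.142, 0.141),
    ("AD", "VA"): (1.977, -1.157, 1.397, 0.198, 0.196),
    ("AD", "LN"): (1.908, -1.510, 1.690, 0.097, 0.095),
    ("AD", "FPN"): (1.967, -1.058, 1.241, 0.181, 0.179),
    ("AD", "DMN"): (1.961, -1.093, 1.217, 0.165, 0.164),
}

# covariate effects act around these references so the intercept stays interpretable
COVARIATE_REFERENCE = {"tiv_cm3": 1400.0, "sex": 0.5, "education_years": 10.0}

# plausible background (non-zone) values per index, used outside crossing zones
_BACKGROUND = {"MD": 1.0e-3, "RD": 0.7e-3, "AD": 1.8e-3}


def noise_sd_for_r2(coeffs, age_distribution, target_r2: float) -> float:
    """Residual SD sigma such that the quadratic signal has the target R^2.

    sigma^2 = Var_age[C + A*age + B*age^2] * (1 - R^2) / R^2, where the
    variance is taken under ``age_distribution``: either an explicit array of
    ages or the string ``"uniform"`` for the integer-uniform distribution on
    [21, 90].
    """
    if not 0.0 < target_r2 < 1.0:
        raise ValueError(f"target R^2 must lie in (0, 1), got {target_r2}")
    if isinstance(age_distribution, str):
        if age_distribution != "uniform":
            raise ValueError(f"unknown age distribution {age_distribution!r}")
        ages = np.arange(AGE_MIN, AGE_MAX + 1, dtype=float)
    else:
        ages = np.asarray(age_distribution, dtype=float)
    if hasattr(coeffs, "C"):
        c, a, b = float(coeffs.C), float(coeffs.A), float(coeffs.B)
    else:
        c, a, b = (float(v) for v in coeffs)
    signal = c + a * ages + b * ages**2
    return float(np.sqrt(np.var(signal) * (1.0 - target_r2) / target_r2))


@dataclass(frozen=True)
class GenerativeModel:
    """Per-(index, network) quadratic coefficients plus noise and covariates.

    ``table`` is indexed by (index, network) with absolute-unit columns
    C, A, B, r2, r2_adj, beta_tiv, beta_sex, beta_edu, noise_sd.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"C", "A", "B", "r2", "noise_sd"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"model table lacks columns {sorted(missing)}")

    @classmethod
    def default(
        cls,
        beta_tiv: float = 0.0,
        beta_sex: float = 0.0,
        beta_edu: float = 0.0,
        noise: str | float = "calibrated",
    ) -> "GenerativeModel":
        """The reference lifespan model, scales expanded to absolute units.

        ``noise="calibrated"`` sets each row's residual SD via
        :func:`noise_sd_for_r2` at the row's own R^2 under uniform ages;
        a float fixes one SD for every row; ``0.0`` gives noiseless data.
        """
        rows = []
        for (index, network), printed in PRINTED_COEFFICIENTS.items():
            sc, sa, sb = COEFF_SCALES[index]
            c, a, b = printed[0] * sc, printed[1] * sa, printed[2] * sb
            r2, r2_adj = printed[3], printed[4]
            if noise == "calibrated":
                sd = noise_sd_for_r2((c, a, b), "uniform", r2)
            else:
                sd = float(noise)
            rows.append({"index": index, "network": network, "C": c, "A": a,
                         "B": b, "r2": r2, "r2_adj": r2_adj,
                         "beta_tiv": beta_tiv, "beta_sex": beta_sex,
                         "beta_edu": beta_edu, "noise_sd": sd})
        table = pd.DataFrame(rows).set_index(["index", "network"]).sort_index()
        return cls(table)

    def row(self, index: str, network: str) -> pd.Series:
        try:
            return self.table.loc[(index, network)]
        except KeyError:
            raise KeyError(f"no generative row for index={index!r}, network={network!r}")

    def has_row(self, index: str, network: str) -> bool:
        return (index, network) in self.table.index

    def quadratic(self, index: str, network: str, ages) -> np.ndarray:
        """Noise-free trajectory values at the given ages (absolute units)."""
        r = self.row(index, network)
        a = np.asarray(ages, dtype=float)
        return r.C + r.A * a + r.B * a**2

    def covariate_shift(self, index: str, network: str, subject) -> float:
        """Linear covariate contribution for one cohort row (centered refs)."""
        r = self.row(index, network)
        return (
            r.get("beta_tiv", 0.0) * (float(subject["tiv_cm3"]) - COVARIATE_REFERENCE["tiv_cm3"])
            + r.get("beta_sex", 0.0) * (float(subject["sex"]) - COVARIATE_REFERENCE["sex"])
            + r.get("beta_edu", 0.0)
            * (float(subject["education_years"]) - COVARIATE_REFERENCE["education_years"])
        )


def simulate_index_values(
    model: GenerativeModel,
    index: str,
    network: str,
    ages,
    seed: int | np.random.SeedSequence | None = None,
    noise_sd: float | None = None,
) -> np.ndarray:
    """Subject-level DI values from one generative row: quadratic + Gaussian noise.

    This is the scalar counterpart of :func:`make_diffusion_volumes` — the
    value each subject would yield after probability-weighted extraction.
    """
    rng = np.random.default_rng(seed)
    r = model.row(index, network)
    sd = float(r.noise_sd) if noise_sd is None else float(noise_sd)
    ages = np.asarray(ages, dtype=float)
    values = model.quadratic(index, network, ages)
    if sd > 0:
        values = values + rng.normal(0.0, sd, size=ages.shape)
    return _clip_physical(index, values)


def _clip_physical(index: str, values: np.ndarray) -> np.ndarray:
    if index == "FA":
        return np.clip(values, 0.0, 1.0)
    return np.maximum(values, 1e-6)  # diffusivities must stay positive


def make_diffusion_volumes(
    phantom: Phantom,
    subject,
    model: GenerativeModel | None = None,
    seed: int | np.random.SeedSequence | None = None,
    voxel_noise_sd: float = 0.0,
    low_fa_prob: float = 0.9,
) -> dict[str, np.ndarray]:
    """Per-subject FA/MD/RD/AD volumes on the phantom grid.

    Within crossing zone n every voxel carries the generative quadratic value
    for (index, network n) at the subject's age, plus covariate effects, one
    subject-level noise draw (SD = the row's ``noise_sd``) shared by the
    zone's voxels, and optional voxel-level noise (``voxel_noise_sd``, as a
    fraction of the row SD). CC voxels outside every zone imitate partial
    volume deterministically: a fraction ``low_fa_prob`` of them (fixed
    scan-order choice, no RNG) gets FA below the 0.2 exclusion threshold, the
    rest sit just above it; diffusivities take fixed background values. This
    keeps noiseless volumes bit-identical across seeds. Voxels outside the CC
    are zero. FA is clipped to [0, 1], diffusivities to > 0.
    """
    age = int(subject["age"])
    if not AGE_MIN <= age <= AGE_MAX:
        raise ValueError(f"age {age} outside [{AGE_MIN}, {AGE_MAX}]")
    model = model or GenerativeModel.default()
    names = phantom.names
    for index in DIFFUSION_INDICES:
        for name in names:
            if not model.has_row(index, name):
                raise ValueError(f"generative model lacks row ({index}, {name})")

    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    edge = phantom.cc_mask & ~phantom.zone_union()
    n_edge = int(edge.sum())
    low = np.arange(n_edge) < int(round(low_fa_prob * n_edge))
    for index in DIFFUSION_INDICES:
        vol = phantom.grid.new_volume()
        for label in range(1, phantom.k + 1):
            zone = phantom.crossing_zone(label)
            r = model.row(index, names[label - 1])
            value = (
                model.quadratic(index, names[label - 1], age)
                + model.covariate_shift(index, names[label - 1], subject)
                + (rng.normal(0.0, r.noise_sd) if r.noise_sd > 0 else 0.0)
            )
            vol[zone] = value
            if voxel_noise_sd > 0:
                vol[zone] += rng.normal(0.0, voxel_noise_sd * r.noise_sd, size=int(zone.sum()))
        if index == "FA":
            ev = np.where(low, 0.10, 0.30)
        else:
            ev = np.full(n_edge, _BACKGROUND[index])
        vol[edge] = ev
        out[index] = _clip_physical(index, vol)
    return out
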