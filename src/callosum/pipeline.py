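"""Config-driven end-to-end runs: synth -> connectivity -> atlas -> metrics
-> trajectories -> stats, with a manifest and a human-readable report.

One global seed fans out deterministically: stage s uses
``numpy.random.SeedSequence([seed, s])`` and per-subject work within a stage
uses ``SeedSequence([seed, s, subject_index])``, so any stage can be re-run
in isolation and reproduce its outputs bit-for-bit. Stage toggles control
which outputs are written; prerequisite computations always run (they are
deterministic and cheap at the default problem size). A failing stage halts
the run with the stage named; outputs already written are retained.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import build_atlas, split_half
from .cohort import make_cohort, write_cohort
from .connectivity import count_connections, dilate_labels, normalize
from .generative import GenerativeModel, make_diffusion_volumes
from .metrics import extract_records
from .networks import DIFFUSION_INDICES, network_names
from .phantom import make_phantom
from .stats import compare_age_groups, compare_subregions
from .tracts import make_tractogram, save_tck
from .trajectories import curve_points, fit_all, fit_quadratic, table2_style

__all__ = ["RunConfig", "StageError", "run_pipeline", "make_report", "STAGES"]

STAGES = ("synth", "connect", "atlas", "metrics", "fit", "stats")
_STAGE_ID = {s: i for i, s in enumerate(STAGES)}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run (YAML round-trippable)."""

    seed: int = 0
    out_dir: str = "scratch/run"
    k: int = 7
    grid_shape: tuple[int, int, int] = (32, 44, 20)
    voxel_size: float = 2.0
    n_subjects: int = 40
    age_distribution: str = "uniform"
    streamlines_per_network: int = 48
    endpoint_jitter_mm: float = 1.0
    crossing_jitter_mm: float = 0.5
    off_target_fraction: float = 0.05
    dilation_radius_mm: float = 2.0
    noise: str | float = "calibrated"
    voxel_noise_sd: float = 0.0
    beta_tiv: float = 0.0
    beta_sex: float = 0.0
    beta_edu: float = 0.0
    low_fa_prob: float = 0.9
    fa_threshold: float = 0.2
    weight_source: str = "population"
    write_volumes: bool = False
    make_plots: bool = False
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})

    def __post_init__(self) -> None:
        if self.weight_source not in ("population", "subject"):
            raise ValueError("weight_source must be 'population' or 'subject'")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        self.stages = {s: bool(self.stages.get(s, True)) for s in STAGES}

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(d["grid_shape"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**d)

    def stage_seed(self, stage: str, *extra: int) -> np.random.SeedSequence:
        return np.random.SeedSequence([self.seed, _STAGE_ID[stage], *extra])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline; returns in-memory artifacts plus output paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    written: list[Path] = [out / "config.yaml"]
    artifacts: dict = {"out_dir": out}
    skipped = [s for s, on in config.stages.items() if not on]

    stage = "synth"
    try:
        phantom = make_phantom(config.k, config.grid_shape, config.voxel_size)
        cohort = make_cohort(config.n_subjects, config.age_distribution,
                             seed=config.stage_seed("synth"))
        model = GenerativeModel.default(config.beta_tiv, config.beta_sex,
                                        config.beta_edu, noise=config.noise)
        counts = {n: config.streamlines_per_network for n in range(1, config.k + 1)}
        tracts, volumes = [], []
        for i in range(config.n_subjects):
            tracts.append(make_tractogram(
                phantom, counts, config.endpoint_jitter_mm,
                config.off_target_fraction, config.crossing_jitter_mm,
                seed=config.stage_seed("synth", 1, i)))
            volumes.append(make_diffusion_volumes(
                phantom, cohort.iloc[i], model,
                seed=config.stage_seed("synth", 2, i),
                voxel_noise_sd=config.voxel_noise_sd,
                low_fa_prob=config.low_fa_prob))
        artifacts.update(phantom=phantom, cohort=cohort, model=model,
                         tractograms=tracts, volumes=volumes)
        if config.stages["synth"]:
            write_cohort(cohort, out / "cohort.tsv")
            written.append(out / "cohort.tsv")
            if config.write_volumes:
                vol_dir = out / "volumes"
                vol_dir.mkdir(exist_ok=True)
                grid = phantom.grid
                for i, sid in enumerate(cohort["id"]):
                    save_tck(tracts[i], vol_dir / f"{sid}.tck")
                    for index in DIFFUSION_INDICES:
                        grid.to_nifti(volumes[i][index]).to_filename(
                            str(vol_dir / f"{sid}_{index}.nii.gz"))

        stage = "connect"
        dilated = dilate_labels(phantom.network_labels, config.dilation_radius_mm,
                                phantom.grid.voxel_size)
        maps = []
        for i, sid in enumerate(cohort["id"]):
            cmap = count_connections(tracts[i], phantom.cc_mask, dilated,
                                     phantom.grid, k=config.k, subject_id=sid)
            maps.append(normalize(cmap))
        artifacts["maps"] = maps

        stage = "atlas"
        atlas = build_atlas(maps, template_cc_mask=phantom.cc_mask)
        artifacts["atlas"] = atlas
        sh = None
        if config.n_subjects >= 4:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sh = split_half(cohort, maps, seed=config.stage_seed("atlas"),
                                template_cc_mask=phantom.cc_mask)
        artifacts["split_half"] = sh
        if config.stages["atlas"]:
            adir = out / "atlas"
            adir.mkdir(exist_ok=True)
            phantom.grid.to_nifti(atlas.probs).to_filename(str(adir / "atlas_probs.nii.gz"))
            phantom.grid.to_nifti(atlas.hard_labels.astype(np.int16)).to_filename(
                str(adir / "hard_labels.nii.gz"))
            pd.DataFrame({"label": range(1, config.k + 1),
                          "network": network_names(config.k)}).to_csv(
                adir / "labels.tsv", sep="\t", index=False)
            written.append(adir / "labels.tsv")
            if sh is not None:
                (adir / "dice.json").write_text(json.dumps({
                    "dice": sh.report.as_dict(),
                    "halves": sh.half_summaries.to_dict(orient="records"),
                }, indent=2))
                written.append(adir / "dice.json")

        stage = "metrics"
        records, di_long = extract_records(
            cohort, maps, volumes, atlas, phantom.cc_mask,
            fa_threshold=config.fa_threshold, weight_source=config.weight_source)
        artifacts.update(records=records, di_long=di_long)
        if config.stages["metrics"]:
            mdir = out / "metrics"
            mdir.mkdir(exist_ok=True)
            records.to_csv(mdir / "records.tsv", sep="\t", index=False)
            di_long.to_csv(mdir / "di_long.tsv", sep="\t", index=False)
            written += [mdir / "records.tsv", mdir / "di_long.tsv"]

        stage = "fit"
        fits = fit_all(di_long, cohort)
        artifacts["fits"] = fits
        if config.stages["fit"]:
            fdir = out / "fits"
            fdir.mkdir(exist_ok=True)
            fits.to_csv(fdir / "trajectory_fits.tsv", sep="\t", index=False)
            table2_style(fits).to_csv(fdir / "fit_table.tsv", sep="\t", index=False)
            curves = pd.concat(
                [curve_points(fit_quadratic(
                    cohort.set_index("id")["age"].reindex(
                        di_long[(di_long.network == r.network)
                                & (di_long["index"] == r.index)]["subject_id"]),
                    di_long[(di_long.network == r.network)
                            & (di_long["index"] == r.index)]["value_residual"],
                    network=r.network, index=r.index))
                 for r in fits.itertuples() if str(r.status).startswith("ok")],
                ignore_index=True) if len(fits) else pd.DataFrame()
            curves.to_csv(fdir / "curves.tsv", sep="\t", index=False)
            written += [fdir / "trajectory_fits.tsv", fdir / "fit_table.tsv",
                        fdir / "curves.tsv"]

        stage = "stats"
        if config.stages["stats"]:
            sdir = out / "stats"
            sdir.mkdir(exist_ok=True)
            group_rows, sig = [], {}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for name in network_names(config.k):
                    try:
                        gc = compare_age_groups(records, name)
                    except ValueError:
                        continue
                    pw = gc.pairwise.assign(network=name, f_stat=gc.f_stat,
                                            p_omnibus=gc.p_omnibus)
                    group_rows.append(pw)
                    sig[name] = pw[pw["significant"]][
                        ["group_i", "group_j", "diff"]].to_dict(orient="records")
                sub_rows = []
                for index in DIFFUSION_INDICES:
                    sc = compare_subregions(di_long, cohort, index)
                    sub_rows.append(sc.pairwise.assign(index=index))
            if group_rows:
                pd.concat(group_rows, ignore_index=True).to_csv(
                    sdir / "group_comparisons.tsv", sep="\t", index=False)
                written.append(sdir / "group_comparisons.tsv")
            pd.concat(sub_rows, ignore_index=True).to_csv(
                sdir / "subregion_comparisons.tsv", sep="\t", index=False)
            (sdir / "significant_pairs.json").write_text(json.dumps(sig, indent=2))
            written += [sdir / "subregion_comparisons.tsv",
                        sdir / "significant_pairs.json"]
    except Exception as err:  # noqa: BLE001 — named-stage failure contract
        raise StageError(stage, err) from err

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "skipped_stages": skipped,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in written if p.exists()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = manifest
    return artifacts


def make_report(run_dir, make_plots: bool = False) -> Path:
    """Assemble a markdown summary of whatever stage outputs exist."""
    run = Path(run_dir)
    if not run.is_dir() or not any(run.iterdir()):
        raise FileNotFoundError(f"no run outputs found in {run}")
    lines = ["# Corpus callosum parcellation run report", ""]
    manifest = run / "manifest.json"
    if manifest.exists():
        m = json.loads(manifest.read_text())
        lines += [f"- version: {m['version']}  ",
                  f"- seed: {m['seed']}  ",
                  f"- skipped stages: {m['skipped_stages'] or 'none'}", ""]
    dice_json = run / "atlas" / "dice.json"
    if dice_json.exists():
        d = json.loads(dice_json.read_text())
        lines += ["## Split-half reproducibility",
                  f"Size-weighted mean Dice: {d['dice']['weighted_mean']:.4f} "
                  f"(unweighted {d['dice']['unweighted_mean']:.4f})", ""]
        for lab, val in d["dice"]["per_label"].items():
            lines.append(f"- label {lab}: {val:.4f}")
        lines.append("")
    else:
        lines += ["## Split-half reproducibility", "_not computed_", ""]
    fit_table = run / "fits" / "fit_table.tsv"
    if fit_table.exists():
        ft = pd.read_csv(fit_table, sep="\t")
        lines += ["## Quadratic aging trajectories",
                  ft.to_markdown(index=False, floatfmt=".3f"), ""]
    stats_tsv = run / "stats" / "group_comparisons.tsv"
    if stats_tsv.exists():
        gc = pd.read_csv(stats_tsv, sep="\t")
        omni = gc.groupby("network")[["f_stat", "p_omnibus"]].first()
        nsig = gc.groupby("network")["significant"].sum()
        lines += ["## Age-group comparisons of connection probability",
                  pd.concat([omni, nsig.rename("n_significant_pairs")], axis=1)
                  .to_markdown(floatfmt=".4f"), ""]
    if make_plots and fit_table.exists():
        _plot_curves(run)
        lines += ["![fitted trajectories](fitted_trajectories.png)", ""]
    path = run / "report.md"
    path.write_text("\n".join(lines))
    return path


def _plot_curves(run: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = pd.read_csv(run / "fits" / "curves.tsv", sep="\t")
    if curves.empty:
        return
    indices = curves["index"].unique()
    fig, axes = plt.subplots(1, len(indices), figsize=(4 * len(indices), 3.2),
                             squeeze=False)
    for ax, index in zip(axes[0], indices):
        sub = curves[curves["index"] == index]
        for net, grp in sub.groupby("network"):
            ax.plot(grp["age"], grp["value"], label=net, lw=1.2)
        ax.set_title(index)
        ax.set_xlabel("age (years)")
    axes[0][0].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(run / "fitted_trajectories.png", dpi=120)
    plt.close(fig)
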