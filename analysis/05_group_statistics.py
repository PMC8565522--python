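"""Group statistics on the phantom study: ANCOVA by age group, subregion
contrasts of the diffusion indices.

Reuses the tables written by 03_subregion_metrics.py if present (otherwise
recomputes them), compares subregional connection probability across the
seven decade groups with covariate adjustment and Bonferroni post hocs, and
ranks subregions by residualized diffusion indices with paired contrasts.
Writes results/group_comparisons.tsv and results/subregion_comparisons.tsv.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import (RESULTS, make_phantom, study_atlas, study_cohort,  # noqa: E402
                     study_maps, study_volumes)

from callosum.metrics import extract_records  # noqa: E402
from callosum.networks import DIFFUSION_INDICES, YEO7_NAMES  # noqa: E402
from callosum.stats import compare_age_groups, compare_subregions  # noqa: E402


def load_tables():
    rec_path = RESULTS / "records.tsv"
    di_path = RESULTS / "di_long.tsv"
    if rec_path.exists() and di_path.exists():
        return (pd.read_csv(rec_path, sep="\t"), pd.read_csv(di_path, sep="\t"),
                study_cohort())
    phantom = make_phantom(7)
    cohort = study_cohort()
    maps = study_maps(phantom, cohort)
    records, di_long = extract_records(cohort, maps, study_volumes(phantom, cohort),
                                       study_atlas(phantom, maps), phantom.cc_mask)
    return records, di_long, cohort


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    records, di_long, cohort = load_tables()

    group_rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in YEO7_NAMES:
            gc = compare_age_groups(records, name)
            group_rows.append(gc.pairwise.assign(network=name, f_stat=gc.f_stat,
                                                 p_omnibus=gc.p_omnibus))
            print(f"{name}: omnibus F={gc.f_stat:.2f} p={gc.p_omnibus:.3g}, "
                  f"{int(gc.pairwise['significant'].sum())}/21 pairs significant")
        pd.concat(group_rows, ignore_index=True).to_csv(
            RESULTS / "group_comparisons.tsv", sep="\t", index=False)

        sub_rows = []
        for index in DIFFUSION_INDICES:
            sc = compare_subregions(di_long, cohort, index)
            sub_rows.append(sc.pairwise.assign(index=index))
            print(f"{index}: subregions ranked {' > '.join(sc.ordering)}")
    pd.concat(sub_rows, ignore_index=True).to_csv(
        RESULTS / "subregion_comparisons.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
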