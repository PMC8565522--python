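"""Shared study conditions for the numbered analysis scripts.

Each script is standalone: it regenerates what it needs from the library
(deterministic under SEED) and writes only its own tables under results/.
"""

from pathlib import Path

import numpy as np

from callosum.atlas import build_atlas
from callosum.cohort import make_cohort
from callosum.connectivity import count_connections, dilate_labels, normalize
from callosum.generative import GenerativeModel, make_diffusion_volumes
from callosum.phantom import make_phantom
from callosum.tracts import make_tractogram

SEED = 7
N_SUBJECTS = 200
BUNDLE = {n: 48 for n in range(1, 8)}
RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_cohort():
    return make_cohort(N_SUBJECTS, "table1", seed=np.random.SeedSequence([SEED, 0]))


def study_maps(phantom, cohort):
    """Per-subject probability maps at the default generator settings."""
    dilated = dilate_labels(phantom.network_labels, 2.0, phantom.grid.voxel_size)
    maps = []
    for i, sid in enumerate(cohort["id"]):
        tg = make_tractogram(phantom, BUNDLE,
                             seed=np.random.SeedSequence([SEED, 1, i]))
        maps.append(normalize(count_connections(
            tg, phantom.cc_mask, dilated, phantom.grid, k=7, subject_id=sid)))
    return maps


def study_volumes(phantom, cohort, model=None):
    model = model or GenerativeModel.default()
    return [make_diffusion_volumes(phantom, row, model,
                                   seed=np.random.SeedSequence([SEED, 2, i]))
            for i, (_, row) in enumerate(cohort.iterrows())]


def study_atlas(phantom, maps):
    return build_atlas(maps, template_cc_mask=phantom.cc_mask)


__all__ = ["SEED", "N_SUBJECTS", "BUNDLE", "RESULTS", "make_phantom",
           "study_cohort", "study_maps", "study_volumes", "study_atlas"]
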