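"""Shared fixtures: synthetic cohorts and their EEMD band decompositions.

The heavy objects (a 60-subject cohort with complementary planted
effects and its per-subject decompositions) are session-scoped so the
classification-level tests share one computation.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest
from hypothesis import settings

import mbnf

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")

logging.getLogger("mbnf").setLevel(logging.ERROR)

# conditions of the fusion-benefit study: 20 ROIs, 30 subjects per
# group, a 0.4 correlation shift on ten disjoint cross-community edges
# split alternately between the two frequency bands
EFFECT_EDGES = [(i, i + 10) for i in range(10)]
EFFECT_SEED = 11
ENSEMBLE_SIZE = 16  # EEMD ensemble size used at test scale


@pytest.fixture(scope="session")
def effect_cohort():
    spec = mbnf.CohortSpec(n_per_group=30, P=20, T=137, TR=3.0,
                           effect_size=0.4, effect_band="both",
                           effect_edges=EFFECT_EDGES, seed=EFFECT_SEED)
    return mbnf.generate_cohort(spec)


@pytest.fixture(scope="session")
def effect_imfsets(effect_cohort):
    """Per-subject, per-ROI EEMD decompositions (seeds mirror
    decompose_cohort so band signals match the pipeline path)."""
    from mbnf.decomposition import EemdParams
    from mbnf.pipeline import subject_imfsets
    out = []
    for s_idx, subject in enumerate(effect_cohort.subjects):
        params = EemdParams(ensemble_size=ENSEMBLE_SIZE,
                            seed=EFFECT_SEED + 10_000 * s_idx)
        out.append(subject_imfsets(subject.values, params))
    return out


@pytest.fixture(scope="session")
def effect_bands(effect_imfsets):
    return [mbnf.split_bands(sets) for sets in effect_imfsets]


@pytest.fixture(scope="session")
def effect_labels(effect_cohort):
    return np.array([s.label for s in effect_cohort.subjects])


@pytest.fixture(scope="session")
def null_cohort():
    """No group effect, singleton communities: independent null edges."""
    spec = mbnf.null_cohort_spec(P=64, n_per_group=30, seed=5)
    return mbnf.generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
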