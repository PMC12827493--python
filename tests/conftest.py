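"""Shared fixtures.

The scaled study fixture runs the complete pipeline once per session at a
reduced scale (2 scenarios, N = 8, 50 generations, 3 replicates) chosen to
keep the suite quick while leaving the selection signal strong enough for
the qualitative contrasts to emerge; the acceptance tests share it.
"""

import pytest

import rhizosim as rz

#: Scale of the in-suite study; mirrors scripts/acceptance.py.
STUDY_SCALE = dict(
    scenarios=(0, 4),
    population_size=8,
    generations=50,
    replicates=3,
    duration=150,
    species_size=8,
    morphology_plants=8,
    experiment_replicates=6,
    experiment_neighbour_counts=(4,),
)


@pytest.fixture(scope="session")
def scaled_study() -> rz.StudyResult:
    return rz.run_study(seed=0, **STUDY_SCALE)
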