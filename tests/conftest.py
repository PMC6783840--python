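"""Shared fixtures: planted-LD founder panels and small simulated trials."""

import numpy as np
import pytest
from hypothesis import settings

from hapgs import simulate as sm

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


def planted_panel(n_founders: int, seed: int, segment_bounds=((10, 14),),
                  n_markers: int = 25, n_chromosomes: int = 1,
                  length: int = 200_000):
    """Unrelated founders with planted perfect-LD segments.

    Returns (dosage matrix, marker_map, founder spec).
    """
    ss = np.random.SeedSequence(seed)
    s1, s2, s3 = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3)]
    mmap = sm.make_marker_map(n_chromosomes, n_markers, length, s1)
    ped = sm.simulate_pedigree(1, 1, 0.0, n_founders, s2)
    founders = ped[ped.generation == 0].reset_index(drop=True)
    spec = sm.make_founder_spec(mmap, list(segment_bounds), s3)
    phased = sm.drop_genotypes(founders, mmap, spec, 0.0, s3)
    dos = phased.dosage()[:n_founders]
    return dos, mmap, spec


@pytest.fixture(scope="session")
def small_trial():
    """A compact pedigreed trial reused by slower model tests."""
    return sm.simulate_study(
        n_families=20, progeny_per_family=8, n_chromosomes=3, n_markers=240,
        n_segments=8, n_qtl=40, traits={"HT": (0.4, None), "ST": (0.2, 7)},
        seed=101,
    )
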