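"""Shared fixtures: tiny handcrafted tracks and a small synthetic dataset."""

import numpy as np
import pytest

import dyadrel as dr


def make_track(ped_id, t, x, y, height=1.70):
    return dr.PedestrianTrack(ped_id=ped_id, t=np.asarray(t, float),
                              x=np.asarray(x, float), y=np.asarray(y, float),
                              height=height)


def parallel_dyad(distance=0.6, speed=1.3, n=21, dt=0.5, relation="couples",
                  heights=(1.80, 1.65)):
    """Two straight parallel tracks: constant delta/vg, zero omega."""
    t = dt * np.arange(n)
    a = make_track("a", t, speed * t, np.zeros(n), heights[0])
    b = make_track("b", t, speed * t, np.full(n, distance), heights[1])
    return dr.DyadRecord(dyad_id="pair", track_a=a, track_b=b, relation=relation)


@pytest.fixture(scope="session")
def small_dataset():
    """40 dyads/class with precomputed observations (session-wide, seeded)."""
    rng = np.random.default_rng(1234)
    dyads = dr.sample_dataset(n_per_category=40, rng=rng)
    observations = {d.dyad_id: dr.extract_observations(d) for d in dyads}
    return dyads, observations


@pytest.fixture(scope="session")
def fitted_model(small_dataset):
    dyads, observations = small_dataset
    return dr.fit_relation_models([(d, observations[d.dyad_id]) for d in dyads])
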