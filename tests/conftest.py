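import math

import numpy as np
import pandas as pd
import pytest

import morphoflow as mf


@pytest.fixture(scope="session")
def small_sample():
    """One simulated sample with doublets and debris, plus its ground truth."""
    spec = mf.default_sample_spec(sample_id="s1", n_events=400, seed=11)
    events, truth = mf.simulate_sample(spec)
    return events, truth


@pytest.fixture(scope="session")
def small_table(small_sample):
    """Feature table of the small sample (segmentation + default panel)."""
    events, truth = small_sample
    table = mf.extract_table(events)
    return table, truth


@pytest.fixture(scope="session")
def cycling_spec():
    """Single population with a strong 4N fraction, for DNA-peak tests."""
    pop = mf.PopulationSpec("cyc", 1.0, (16.0, 1.1), (0.6, 0.03), 0.4,
                            {"FL1": (math.log(2000.0), 0.25)},
                            dna_4n_fraction=0.35)
    return [pop]


def make_gaussian_blobs(rng, centers, n_per, d=5, sd=1.0):
    pts = np.vstack([rng.normal(c, sd, (n_per, d)) for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return pts, labels
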