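import os

# single-thread mode: training and registration results are reproducible
# only with a fixed reduction order (set before numpy/SimpleITK load)
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS",
             "NUMEXPR_NUM_THREADS", "VECLIB_MAXIMUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest
import SimpleITK as sitk

sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(1)

from imtkit import phantom
from imtkit.synthio import ImageSlice


@pytest.fixture(scope="session")
def small_cohort():
    """Eight structure-task subjects at side 64, two modalities."""
    return phantom.make_cohort(seed=11, n_subjects=8, side=64)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def random_slice_pair(rng):
    def make(side=16):
        a = ImageSlice(pixels=rng.uniform(-1, 1, (side, side)), normalized=True)
        b = ImageSlice(pixels=rng.uniform(-1, 1, (side, side)), normalized=True)
        return a, b
    return make
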