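import dataclasses

import numpy as np
import pytest

from adctexture.containers import ADCMap, TumorVOI
from adctexture.phantom import PhantomSpec

VOXEL = (0.136, 0.136, 1.5)


@pytest.fixture
def small_spec():
    """~500-voxel tumor on a small grid, study voxel geometry and b-values."""
    return PhantomSpec(grid_shape=(32, 32, 8), tumor_radius=1.5, seed=7)


@pytest.fixture
def noiseless_spec(small_spec):
    return dataclasses.replace(small_spec, snr=np.inf)


def adc_map_from(values: np.ndarray, shape=None) -> tuple[ADCMap, TumorVOI]:
    """Wrap a flat array of ADC values into a 1-slice map + full VOI."""
    values = np.asarray(values, dtype=float)
    if shape is None:
        shape = (values.size, 1, 1)
    arr = values.reshape(shape)
    ones = np.ones(shape, dtype=bool)
    amap = ADCMap(adc=arr, s0=np.ones(shape), valid_mask=ones,
                  rss=np.zeros(shape), voxel_size=VOXEL)
    voi = TumorVOI(ones, VOXEL)
    return amap, voi
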