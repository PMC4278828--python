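"""Small shared builders for the test suite."""

import numpy as np

from sdmuq.climate import ClimateStack
from sdmuq.grids import Grid


def constant_climate(geom, t=10.0, p=50.0, mask=None):
    mk = lambda v: [
        Grid(geom, np.full((geom.n_rows, geom.n_cols), v), None if mask is None else mask.copy())
        for _ in range(12)
    ]
    return ClimateStack(geom, mk(t), mk(t), mk(p))
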