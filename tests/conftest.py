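import numpy as np
import pytest

from mdfconn.mdf import estimate_mdf
from mdfconn.morphogen import GrowthParams, grow_ensemble
from mdfconn.morphology import AXON, APICAL, BASAL, Morphology


@pytest.fixture(scope="session")
def default_params() -> GrowthParams:
    return GrowthParams()


@pytest.fixture(scope="session")
def ensemble100(default_params):
    """Shared 100-neuron ensemble (default growth parameters)."""
    return grow_ensemble(default_params, 100, seed=42)


@pytest.fixture(scope="session")
def mdf_pair(ensemble100, default_params):
    """Axonal/dendritic MDF pair on a grid covering the ensemble."""
    from mdfconn.morphogen import covering_extent
    r_max, z_range = covering_extent(default_params)
    kw = dict(h=2.0, r_max=r_max, z_range=z_range)
    return (estimate_mdf(ensemble100, "axonal", **kw),
            estimate_mdf(ensemble100, "dendritic", **kw))


def make_morphology(segments, kinds=None, parents=None) -> Morphology:
    """Build a Morphology from [(start, end), ...] tuples; defaults to a
    single chain of axonal segments rooted at the first one."""
    starts = np.array([s for s, _ in segments], float).reshape(-1, 3)
    ends = np.array([e for _, e in segments], float).reshape(-1, 3)
    n = len(starts)
    if kinds is None:
        kinds = np.full(n, AXON, dtype=np.int8)
    if parents is None:
        parents = np.arange(-1, n - 1, dtype=np.int64)
    return Morphology(starts, ends, np.asarray(kinds, np.int8),
                      np.asarray(parents, np.int64))
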