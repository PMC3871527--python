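import numpy as np
import pytest

from dcepk import AcquisitionSpec, make_aif
from dcepk.synthetic import GroundTruthMap, make_truth_map


@pytest.fixture(scope="session")
def spec() -> AcquisitionSpec:
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def aif(spec):
    return make_aif(spec)


@pytest.fixture(scope="session")
def truth() -> GroundTruthMap:
    return make_truth_map()


def truth_from_params(vp, ktrans, kep, t1_s=2.2, m0=1000.0, r2star=40.0):
    """Ad-hoc ground truth: one voxel per parameter triple, all order 3."""
    vp = np.atleast_1d(np.asarray(vp, dtype=float))
    n = vp.size
    return GroundTruthMap(
        shape=(n, 1, 1),
        zone=np.full(n, 3),
        order=np.full(n, 3),
        vp=vp,
        ktrans_per_min=np.broadcast_to(np.asarray(ktrans, dtype=float), (n,)).copy(),
        kep_per_min=np.broadcast_to(np.asarray(kep, dtype=float), (n,)).copy(),
        t1_s=np.full(n, t1_s),
        r2star_per_s=np.full(n, r2star),
        m0=np.full(n, m0),
        adc_mm2_s=np.full(n, 0.9e-3),
    )
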