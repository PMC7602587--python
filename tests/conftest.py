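import numpy as np
import pytest

from mucoct.geometry import ScanGeometry
from mucoct.phantom import build_profile, render_bscan
from mucoct.segmentation import segment_bscan


@pytest.fixture(scope="session")
def geometry():
    return ScanGeometry()


@pytest.fixture(scope="session")
def sublingual_scan():
    """One speckled sublingual B-scan with truth (cached for the session)."""
    profile = build_profile("sublingual")
    return render_bscan(profile, seed=42)


@pytest.fixture(scope="session")
def sublingual_segmentation(sublingual_scan):
    bscan, _ = sublingual_scan
    return segment_bscan(bscan)


@pytest.fixture(scope="session")
def noiseless_scan():
    """Noiseless, feature-free two-layer phantom (attenuation off)."""
    from mucoct.phantom import Attenuation
    profile = build_profile("sublingual", overrides={
        "speckle": False, "attenuation": Attenuation(0.0, 0.0),
        "vessel_density_target": 0.0})
    return render_bscan(profile, seed=0)


def rng(seed=0):
    return np.random.default_rng(seed)
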