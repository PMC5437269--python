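import numpy as np
import pytest

from spindlekit.structure import classify
from spindlekit.synthetic import SynthSpindleConfig, generate_reconstruction


@pytest.fixture(scope="session")
def default_spindle():
    """Full-size synthetic half spindle (8331 MTs, 227 KMTs) with truth
    labels and the classifier's labels, shared across tests."""
    recon = generate_reconstruction(SynthSpindleConfig(seed=1))
    truth = {t.id: t.mt_class for t in recon.traces}
    labels = classify(recon)
    return recon, truth, labels


@pytest.fixture(scope="session")
def small_spindle():
    """Reduced spindle for cheaper geometric tests."""
    cfg = SynthSpindleConfig(n_mts_total=900, n_kmts=150, seed=7)
    recon = generate_reconstruction(cfg)
    truth = {t.id: t.mt_class for t in recon.traces}
    return recon, truth


def random_polyline(rng, n_pts=5, box=5000.0, step=(200.0, 600.0), jitter=30.0):
    start = rng.uniform(0, box, 3)
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    pts = [start]
    for _ in range(n_pts - 1):
        pts.append(pts[-1] + d * rng.uniform(*step) + rng.normal(0, jitter, 3))
    return np.asarray(pts)
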