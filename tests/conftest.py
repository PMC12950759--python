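import numpy as np
import pytest

from momhca import SyntheticSpec, generate


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small paired dataset with 3 well-separated planted types."""
    spec = SyntheticSpec(n_cells=120, n_types=3, n_genes=200, n_peaks=400,
                         n_donors=4, markers_per_type_genes=25,
                         markers_per_type_peaks=60, type_signal_strength=1.5,
                         seed=7)
    return generate(spec)


@pytest.fixture(scope="session")
def tiny_latents():
    """Two latent matrices with 3 separable groups, matched across
    modalities (stand-ins for AE outputs)."""
    rng = np.random.default_rng(11)
    n_per, d = 30, 16
    centers = rng.normal(0, 4, size=(3, d))
    labels = np.repeat(np.arange(3), n_per)
    Zi = centers[labels] + rng.normal(0, 0.5, size=(3 * n_per, d))
    Zj = centers[labels] + rng.normal(0, 0.5, size=(3 * n_per, d))
    return Zi, Zj, labels
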