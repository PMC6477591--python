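import numpy as np
import pytest

from nephroshield.foci_quant import ThresholdConfig
from nephroshield.synthetic_data import TileSpec, generate_tile


@pytest.fixture(scope="session")
def noise_free_spec() -> TileSpec:
    """Small tile with no PSF and no background: planted and imaged pixels
    are identical, making it an exact oracle."""
    return TileSpec(
        width=256,
        height=256,
        n_nuclei=60,
        positive_fraction=0.30,
        psf_sigma=0.0,
        background_mean=0.0,
        background_sd=0.0,
    )


@pytest.fixture(scope="session")
def noisy_tile():
    """One realistic tile (PSF + Gaussian background) with its truth."""
    spec = TileSpec(width=256, height=256, n_nuclei=60, positive_fraction=0.25)
    return generate_tile(spec, seed=7)


@pytest.fixture
def loose_cfg() -> ThresholdConfig:
    """Default thresholds but no subsection gate, for single-tile tests."""
    return ThresholdConfig(min_subsection_nuclei=1)


def match_nuclei_to_truth(nuclei, truth):
    """Map each detected nucleus to the planted nucleus its pixels mostly
    overlap; returns list of (detected_record, planted_nucleus | None)."""
    pairs = []
    for rec in nuclei.records:
        mask = nuclei.labels == rec.id
        overlap = truth.labels[mask]
        overlap = overlap[overlap > 0]
        if overlap.size == 0:
            pairs.append((rec, None))
        else:
            pairs.append((rec, truth.nuclei[np.bincount(overlap).argmax() - 1]))
    return pairs
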