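import numpy as np
import pytest

from perinet.dce_data import DCESeries, make_stack


def make_series(
    grid=(24, 24, 16),
    spacing=(1.0, 1.0, 1.0),
    n_acq=6,
    lesion_centers=((12, 12, 8),),
    lesion_radii=((4, 3, 2),),
    label=0,
    patient_id="T000",
    seed=0,
):
    """Hand-built DCE series: smooth background + enhancing ellipsoids."""
    rng = np.random.default_rng(seed)
    background = 0.5 + 0.05 * rng.normal(0, 1, grid).astype(np.float32)
    mask = np.zeros(grid, dtype=bool)
    coords = np.indices(grid, dtype=float)
    for c, r in zip(lesion_centers, lesion_radii):
        d2 = sum(((coords[a] - c[a]) / r[a]) ** 2 for a in range(3))
        mask |= d2 <= 1.0
    acquisitions = [background.copy()]
    for i in range(1, n_acq):
        enh = i / (n_acq - 1)
        acquisitions.append((background + enh * mask).astype(np.float32))
    return DCESeries(
        patient_id=patient_id,
        acquisitions=acquisitions,
        spacing=spacing,
        mask=mask,
        label=label,
    )


@pytest.fixture
def unifocal_series():
    return make_series()


@pytest.fixture
def bifocal_series():
    return make_series(
        grid=(32, 32, 20),
        lesion_centers=((9, 9, 7), (23, 23, 13)),
        lesion_radii=((3, 3, 2), (4, 3, 2)),
        label=1,
        patient_id="T001",
    )


@pytest.fixture
def unifocal_stack(unifocal_series):
    return make_stack(unifocal_series)


@pytest.fixture
def bifocal_stack(bifocal_series):
    return make_stack(bifocal_series)
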