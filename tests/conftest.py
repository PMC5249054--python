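import numpy as np
import pytest

from mcmorph import load_reference_cohort


@pytest.fixture(scope="session")
def reference_records():
    return load_reference_cohort()


@pytest.fixture(scope="session")
def evaluable_records(reference_records):
    """The 27 samples retained for morphology evaluation (>1 calcification)."""
    return [r for r in reference_records if not r.morphometry.excluded]


def sphere_mask(radius_vox: float, pad: int = 4) -> np.ndarray:
    n = int(2 * radius_vox) + 2 * pad + 3
    c = (n - 1) / 2
    z, y, x = np.ogrid[:n, :n, :n]
    return (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= radius_vox**2


def cylinder_mask(radius_vox: float, length_vox: float, pad: int = 4) -> np.ndarray:
    nz = int(length_vox) + 2 * pad + 3
    nxy = int(2 * radius_vox) + 2 * pad + 3
    cz, cxy = (nz - 1) / 2, (nxy - 1) / 2
    z, y, x = np.ogrid[:nz, :nxy, :nxy]
    return (np.abs(z - cz) <= length_vox / 2) & ((y - cxy) ** 2 + (x - cxy) ** 2 <= radius_vox**2)


def plate_mask(lateral_vox: float, thickness_vox: float, pad: int = 4) -> np.ndarray:
    nz = int(thickness_vox) + 2 * pad + 3
    nxy = int(lateral_vox) + 2 * pad + 3
    cz, cxy = (nz - 1) / 2, (nxy - 1) / 2
    z, y, x = np.ogrid[:nz, :nxy, :nxy]
    return (
        (np.abs(z - cz) <= thickness_vox / 2)
        & (np.abs(y - cxy) <= lateral_vox / 2)
        & (np.abs(x - cxy) <= lateral_vox / 2)
    )
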