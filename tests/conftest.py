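"""Shared fixtures: expensive synthetic wells are session-scoped."""

import numpy as np
import pytest

from spheroseg import SyntheticSpec, analyze_well, generate_spheroid


@pytest.fixture(scope="session")
def default_spec():
    """The canonical 250-nucleus T47D-like spheroid (mild noise, no attenuation)."""
    return SyntheticSpec(seed=0)


@pytest.fixture(scope="session")
def default_well(default_spec):
    return generate_spheroid(default_spec)


@pytest.fixture(scope="session")
def default_analysis(default_well):
    well, _truth = default_well
    return analyze_well(well)


@pytest.fixture(scope="session")
def quiet_single_nucleus_spec():
    """One ellipsoid, no blur/noise/texture: geometry checks need raw voxels."""
    return SyntheticSpec(
        n_nuclei=1, spheroid_radius=20.0, margin_xy=15.0,
        gaussian_noise_sd=0.0, base_blur_sigma_xy=0.0, base_blur_sigma_z=0.0,
        nucleolus_contrast=0.0, intensity_cv=0.0, background_offset=0.0,
        nucleus_diameter_sd=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_plate_specs():
    """A fast 4-well plate: 3 spheroid wells (one labeled) + 1 empty well."""
    return {
        "B02": SyntheticSpec(n_nuclei=80, spheroid_radius=36.0,
                             labeled_fraction=1.0, seed=41),
        "B03": SyntheticSpec(n_nuclei=80, spheroid_radius=36.0,
                             labeled_fraction=0.5, seed=42),
        "B04": SyntheticSpec(n_nuclei=80, spheroid_radius=36.0,
                             labeled_fraction=0.0, seed=43,
                             render_label_channel=True),
        "B05": SyntheticSpec(n_nuclei=0, seed=44, render_label_channel=True),
    }


def assert_labels_contiguous(labels: np.ndarray) -> None:
    present = np.unique(labels)
    present = present[present > 0]
    assert list(present) == list(range(1, len(present) + 1))
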