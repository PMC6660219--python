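import numpy as np
import pytest

import conetopo as ct


@pytest.fixture(scope="session")
def reference_cohort():
    """The packaged 28-eye reference cohort table."""
    return ct.load_reference_cohort()


@pytest.fixture(scope="session")
def hex_mosaic():
    """Perfect hexagonal lattice, spacing 0.5 arcmin, centered at (500, 500) px."""
    s = 0.5
    ii, jj = np.meshgrid(np.arange(-60, 61), np.arange(-60, 61), indexing="ij")
    x = s * (ii + 0.5 * (jj % 2))
    y = s * jj * np.sqrt(3) / 2
    pts = np.column_stack([x.ravel(), y.ravel()]) * 9.48 + 500.0
    mosaic = ct.ConeMosaic(pts, pixels_per_arcmin=9.48, rmf_um_per_deg=290.0)
    return mosaic, s


@pytest.fixture(scope="session")
def constant_mosaic():
    """Generated mosaic with a flat 15,000 cones/deg^2 profile."""
    profile = ct.DensityProfile(peak_angular_density=15000.0, r0_arcmin=1e6)
    syn = ct.generate_mosaic(profile, extent_arcmin=30.0, seed=7)
    syn.mosaic.rmf_um_per_deg = 290.0
    return syn


@pytest.fixture(scope="session")
def falloff_mosaic():
    """Generated mosaic with the default radial falloff profile."""
    profile = ct.DensityProfile(peak_angular_density=15000.0, r0_arcmin=30.0, gamma=1.2)
    syn = ct.generate_mosaic(profile, extent_arcmin=90.0, seed=11)
    syn.mosaic.rmf_um_per_deg = 290.0
    return syn
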