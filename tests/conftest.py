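"""Shared fixtures: small synthetic stacks rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from mnlamina.core_io import AnalysisConfig, VoxelSpacing
from mnlamina.synthetic_data import GapSpec, SyntheticMNSpec, generate_mn_stack


@pytest.fixture(scope="session")
def spacing() -> VoxelSpacing:
    return VoxelSpacing(20.0, 20.0, 150.0)


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_spec() -> SyntheticMNSpec:
    """A compact micronucleus to keep rendering cheap in unit tests."""
    return SyntheticMNSpec(semi_axes_um=(1.0, 0.95, 0.7))


@pytest.fixture(scope="session")
def default_stack():
    """One default micronucleus, no gaps, default noise."""
    return generate_mn_stack(SyntheticMNSpec(), seed=11)


@pytest.fixture(scope="session")
def gapped_stack():
    """A micronucleus with two polar gaps of known area, default noise."""
    spec = SyntheticMNSpec(gaps=(
        GapSpec(theta=0.35, phi=0.8, area_um2=0.25, residual_fraction=0.0),
        GapSpec(theta=np.pi - 0.4, phi=3.5, area_um2=0.30, residual_fraction=0.1),
    ))
    return generate_mn_stack(spec, seed=21)


@pytest.fixture(scope="session")
def noiseless_stack():
    """Noise-free, blur-free rendering with one zero-residual gap."""
    spec = SyntheticMNSpec(
        gaps=(GapSpec(theta=0.35, phi=0.8, area_um2=0.25,
                      residual_fraction=0.0),),
        psf_sigma_nm=(0.0, 0.0),
        poisson_scale=0.0,
        gaussian_sigma=0.0,
    )
    return generate_mn_stack(spec, seed=5)
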