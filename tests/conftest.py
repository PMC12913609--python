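import numpy as np
import pytest

from nanocoal import GrowthParams, Medium, PolymerSpec


@pytest.fixture
def medium():
    """Water-like continuous phase at 300 K (reference parameter set)."""
    return Medium(viscosity=0.932e-3, temperature=300.0)


@pytest.fixture
def polymer():
    """PCL-like polymer: density 1.145 g/cm^3, M_w 14 kg/mol."""
    return PolymerSpec(density=1145.0, molar_mass=14000.0)


@pytest.fixture
def params_55(params_template):
    """Reference process at 5.5 g/L polymer."""
    return params_template.with_concentration(5.5)


@pytest.fixture
def params_template():
    """Reference process knobs: D_h0 = 41.0 nm, t = 16.0 ms."""
    return GrowthParams(
        initial_diameter=41e-9,
        growth_time=16e-3,
        mass_concentration=1.0,
    )


@pytest.fixture
def random_parameter_sets():
    """20 seeded random (medium, polymer, params) triples for oracle checks."""
    rng = np.random.default_rng(42)
    sets = []
    for _ in range(20):
        med = Medium(
            viscosity=float(rng.uniform(0.5e-3, 2e-3)),
            temperature=float(rng.uniform(280.0, 320.0)),
        )
        pol = PolymerSpec(density=float(rng.uniform(900.0, 1300.0)))
        par = GrowthParams(
            initial_diameter=float(rng.uniform(10e-9, 100e-9)),
            growth_time=float(rng.uniform(1e-3, 50e-3)),
            mass_concentration=float(rng.uniform(0.5, 50.0)),
        )
        sets.append((med, pol, par))
    return sets
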