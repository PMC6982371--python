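import numpy as np
import pytest

from lipidscatter import scattering_models as sm


@pytest.fixture
def q_grid():
    """Dense grid spanning the usual reduced-curve range."""
    return np.geomspace(1e-3, 0.5, 150)


@pytest.fixture
def css_params():
    """A generic core-shell sphere with non-trivial contrasts."""
    return sm.SphereCoreShellParams(
        core_radius=30.0, shell_thickness=20.0,
        sld_core=0.24, sld_shell=0.38, sld_solvent=0.334,
        scale=2.0, background=1e-3)


@pytest.fixture
def micelle_params():
    return sm.preset("gm1_micelle")
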