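import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def water_molecule():
    """Standard gas-phase water geometry (Å)."""
    from permeonics.qm import Molecule

    r, th = 0.9572, np.deg2rad(104.52)
    return Molecule(
        ["O", "H", "H"],
        [[0.0, 0.0, 0.0],
         [r * np.sin(th / 2), 0.0, r * np.cos(th / 2)],
         [-r * np.sin(th / 2), 0.0, r * np.cos(th / 2)]])


@pytest.fixture(scope="session")
def water_scf(water_molecule):
    """Converged SCF of one water in the built-in basis (shared, read-only)."""
    from permeonics.qm import rhf

    return rhf(water_molecule, "pdzp", conv_tol=1e-8)


@pytest.fixture(scope="session")
def sto3g_h():
    """The classic 3-Gaussian expansion of a ζ=1.24 hydrogen 1s orbital."""
    from permeonics.qm import BasisSet

    return BasisSet.from_json({
        "name": "sto3g-H",
        "elements": {"H": [{"l": 0,
                            "exp": [3.42525091, 0.62391373, 0.16885540],
                            "coef": [0.15432897, 0.53532814, 0.44463454]}]}})
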