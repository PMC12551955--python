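import numpy as np
import pytest

from vectorplan import (
    Network,
    Node,
    SpeciesParams,
    ThermalResponse,
    apply_ridl,
    equilibrium_state,
    mendelian_cube,
)


def const(v: float) -> ThermalResponse:
    return ThermalResponse("constant", (v,))


def make_toy_species(
    nu=2.0, th_E=0.3, th_L=0.2, th_P=0.3, mu_E=0.05, mu_L=0.1, mu_P=0.05, mu_A=0.12
) -> SpeciesParams:
    """Temperature-independent species; viable at the default values."""
    return SpeciesParams(
        name="toy",
        development={"egg": const(th_E), "larva": const(th_L), "pupa": const(th_P)},
        mortality={
            "egg": const(mu_E),
            "larva": const(mu_L),
            "pupa": const(mu_P),
            "adult": const(mu_A),
        },
        fecundity=const(nu),
    )


TOY_K = 300.0
TOY_TREF = 27.0


@pytest.fixture(scope="session")
def toy_species():
    return make_toy_species()


@pytest.fixture(scope="session")
def ridl_cube():
    return apply_ridl(mendelian_cube(), penetrance=1.0)


@pytest.fixture(scope="session")
def toy_network(toy_species):
    return Network(nodes=(Node(name="site", species=toy_species, K=TOY_K),))


@pytest.fixture(scope="session")
def toy_equilibrium(toy_species, ridl_cube):
    return equilibrium_state(toy_species, ridl_cube, K=TOY_K, T_ref=TOY_TREF)


@pytest.fixture(scope="session")
def const_temps_365():
    return np.full(365, TOY_TREF)
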