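import logging

import numpy as np
import pytest
from hypothesis import settings

from harkit.refine import RefinementOptions
from harkit.synthetic import (GaussianDensityProvider, ToySpec,
                              make_toy_crystal, simulate_reflections)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

logging.getLogger("harkit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def diatomic():
    """Noise-free diatomic toy crystal: (structure, model, provider, reflections)."""
    st, model = make_toy_crystal(ToySpec("diatomic_P1"))
    prov = GaussianDensityProvider(model, st)
    refl = simulate_reflections(st, prov, 0.8, 0.0, seed=11)
    return st, model, prov, refl


@pytest.fixture(scope="session")
def polar_xh():
    st, model = make_toy_crystal(ToySpec("polar_XH_P1"))
    prov = GaussianDensityProvider(model, st)
    refl = simulate_reflections(st, prov, 0.8, 0.0, seed=12)
    return st, model, prov, refl


@pytest.fixture(scope="session")
def mirror_site():
    st, model = make_toy_crystal(ToySpec("mirror_site_Pm"))
    prov = GaussianDensityProvider(model, st)
    refl = simulate_reflections(st, prov, 0.8, 0.0, seed=13)
    return st, model, prov, refl


@pytest.fixture
def default_options():
    return RefinementOptions()


def coord_error_angstrom(refined, truth):
    """Max Cartesian distance between matching sites (mod lattice)."""
    errs = []
    for a, b in zip(refined.sites, truth.sites):
        d = (a.xyz - b.xyz + 0.5) % 1.0 - 0.5
        errs.append(np.linalg.norm(truth.cell.frac_to_cart(d)))
    return max(errs)


def adp_error(refined, truth):
    errs = []
    for a, b in zip(refined.sites, truth.sites):
        if a.u_aniso is not None and b.u_aniso is not None:
            errs.append(np.max(np.abs(a.u_aniso - b.u_aniso)))
        else:
            errs.append(abs(a.u_iso - b.u_iso))
    return max(errs)
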