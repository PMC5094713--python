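import numpy as np
import pytest

import ecmkit as ek


@pytest.fixture(scope="session")
def toy_bundle():
    """The canonical X <=> A <=> B <=> Y pathway with unit constants."""
    return ek.toy_pathway()


@pytest.fixture(scope="session")
def toy_polytope(toy_bundle):
    net, par, flux, bounds, _ = toy_bundle
    return ek.build_polytope(net, par, flux, bounds)


@pytest.fixture(scope="session")
def toy_solution_emc3sp(toy_bundle, toy_polytope):
    net, par, flux, bounds, _ = toy_bundle
    spec = ek.CostFunctionSpec(variant="EMC3SP")
    return ek.ecm_solve(toy_polytope, net, par, flux, spec, seed=0)


@pytest.fixture(scope="session")
def random_chain():
    """A seeded 6-metabolite random chain model."""
    return ek.random_model(6, topology="chain", seed=7)


def random_feasible_points(poly, n, seed):
    """Rejection-sample n feasible free-coordinate points from the polytope."""
    rng = np.random.default_rng(seed)
    pts = []
    while len(pts) < n:
        xf = poly.x_min + rng.random(poly.n_free) * (poly.x_max - poly.x_min)
        if poly.contains(xf) and np.all(poly.theta(xf) > 1e-6):
            pts.append(xf)
    return pts
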