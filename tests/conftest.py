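import numpy as np
import pytest

from pollenflow.synthetic import (
    SimConfig,
    default_source_map,
    simulate_dye_deposition,
    simulate_landscape,
)
from pollenflow.transfers import build_transfer_table


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_landscape():
    """Small default landscape: 4 populations (2 Ca, 2 Si), 25 recipients each."""
    cfg = SimConfig(plants_per_population=25, seed=0)
    plants = simulate_landscape(cfg)
    dye = simulate_dye_deposition(plants, cfg)
    src = default_source_map(cfg, plants)
    return cfg, plants, dye, src


@pytest.fixture(scope="session")
def default_transfers(default_landscape):
    cfg, plants, dye, src = default_landscape
    return build_transfer_table(plants, dye, src)


def fat_tail_config(seed: int = 0, plants_per_population: int = 40) -> SimConfig:
    """Scenario with strong long-distance deposition so that interpopulation
    transfers carry dye: a very leptokurtic kernel, within the shape range
    the field data itself exhibits."""
    return SimConfig(kernel_alpha=5.0, kernel_beta=0.25, deposition_c=30.0,
                     plants_per_population=plants_per_population, seed=seed)


@pytest.fixture(scope="session")
def fat_tail_transfers():
    cfg = fat_tail_config(seed=3)
    plants = simulate_landscape(cfg)
    dye = simulate_dye_deposition(plants, cfg)
    src = default_source_map(cfg, plants)
    return build_transfer_table(plants, dye, src)


@pytest.fixture(scope="session")
def recovery_transfers():
    """Single population, 300 recipients at ~2-200 m: the kernel-recovery design."""
    cfg = SimConfig(n_populations=1, ecotypes=("Si",), centers=((0.0, 0.0),),
                    radii=(200.0,), plants_per_population=300, seed=0)
    plants = simulate_landscape(cfg)
    dye = simulate_dye_deposition(plants, cfg)
    src = default_source_map(cfg, plants)
    return cfg, build_transfer_table(plants, dye, src)


def kernel_radial_integral(alpha: float, beta: float, power: int) -> float:
    """Numerical integral of r**power * f(alpha,beta;r) * 2*pi*r over [0, inf).

    Split at kernel-scaled breakpoints so adaptive quadrature resolves the
    very fat tails (beta < 1) where most mass sits far beyond alpha.
    """
    from scipy.integrate import quad
    from pollenflow.kernel import kernel_density

    def integrand(r):
        return r ** power * kernel_density(alpha, beta, r) * 2 * np.pi * r

    breaks = [0.0] + [alpha * u ** (1.0 / beta) for u in (1.0, 5.0, 20.0, 60.0)]
    total = sum(quad(integrand, lo, hi, limit=400)[0]
                for lo, hi in zip(breaks[:-1], breaks[1:]))
    total += quad(integrand, breaks[-1], np.inf, limit=400)[0]
    return total
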