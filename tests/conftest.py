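import numpy as np
import pytest

from g6pdhkit.kinetics import (AssayMix, Cofactor, CofactorBranch,
                               EnzymeKinetics, load_kt2440)


@pytest.fixture(scope="session")
def kt2440():
    return load_kt2440()


@pytest.fixture(scope="session")
def enzyme_a(kt2440):
    return kt2440["G6PDH-A"]


@pytest.fixture(scope="session")
def enzyme_b(kt2440):
    return kt2440["G6PDH-B"]


@pytest.fixture(scope="session")
def enzyme_c(kt2440):
    return kt2440["G6PDH-C"]


def random_branch(rng: np.random.Generator, cofactor=Cofactor.NAD,
                  with_kis: bool = False) -> CofactorBranch:
    def draw():
        return float(10 ** rng.uniform(0.5, 3.5))
    return CofactorBranch(
        cofactor_id=cofactor, kcat=draw(), km_cofactor=draw(),
        ki_cofactor=draw(), km_g6p=draw(), kic_product=draw(),
        kis_cofactor=draw() if with_kis else None)


def random_enzyme(rng: np.random.Generator, with_kis: bool = False) -> EnzymeKinetics:
    return EnzymeKinetics(name="random",
                          nad=random_branch(rng, Cofactor.NAD, with_kis),
                          nadp=random_branch(rng, Cofactor.NADP))


def random_mix(rng: np.random.Generator) -> AssayMix:
    def conc():
        return float(10 ** rng.uniform(0, 3.5))
    return AssayMix(g6p=conc(), nad_ox=conc(), nadp_ox=conc(),
                    nadh=conc(), nadph=conc(), e0=float(10 ** rng.uniform(-2, 0)))
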