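import numpy as np
import pytest

from qnmladder import FoodWeb, FunctionalGroup, Pedigree, Role


def make_web(groups, diet, catch, pedigrees=None):
    n = len(groups)
    if pedigrees is None:
        ped = Pedigree(*(np.zeros(n) for _ in range(4)))
    else:
        ped = pedigrees
    return FoodWeb(groups=tuple(groups), diet=np.asarray(diet, float),
                   catch=np.asarray(catch, float), pedigree=ped)


@pytest.fixture
def toy_web():
    """Phyto/Fish/Detritus/Fleet web with hand-checkable balance numbers."""
    groups = [
        FunctionalGroup("Phyto", Role.PRODUCER, biomass=10, pb=10),
        FunctionalGroup("Fish", Role.CONSUMER, biomass=1, pb=2, qb=10),
        FunctionalGroup("Detritus", Role.DETRITUS, biomass=5),
        FunctionalGroup("Fleet", Role.FLEET),
    ]
    diet = np.zeros((4, 4))
    diet[0, 1] = 1.0  # Fish eats only Phyto
    return make_web(groups, diet, [0.0, 0.5, 0.0, 0.0])


@pytest.fixture
def chain_web():
    """Phyto → Herbivore → Predator chain plus detritus and fleet."""
    groups = [
        FunctionalGroup("Phyto", Role.PRODUCER, biomass=40, pb=10),
        FunctionalGroup("Herbivore", Role.CONSUMER, biomass=4, pb=2, qb=10),
        FunctionalGroup("Predator", Role.CONSUMER, biomass=0.4, pb=1, qb=5),
        FunctionalGroup("Detritus", Role.DETRITUS, biomass=30),
        FunctionalGroup("Fleet", Role.FLEET),
    ]
    diet = np.zeros((5, 5))
    diet[0, 1] = 1.0  # Herbivore eats Phyto
    diet[1, 2] = 1.0  # Predator eats Herbivore
    return make_web(groups, diet, [0.0, 0.0, 0.1, 0.0, 0.0])
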