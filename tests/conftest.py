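import numpy as np
import pytest

from ebvselect import FEMALE, MALE, IndividualRecord, Pedigree


def make_random_pedigree(n, seed, p_unknown=0.1, n_founders=10):
    """Random multi-generation pedigree with a fraction of unknown parents."""
    rng = np.random.default_rng(seed)
    recs = []
    males, females = [], []
    for i in range(n):
        dog = f"D{i:03d}"
        sex = MALE if i % 2 == 0 else FEMALE
        if i < n_founders:
            recs.append(IndividualRecord(dog, sex=sex, status_flags=frozenset()))
        else:
            sire = None if rng.random() < p_unknown else str(rng.choice(males))
            dam = None if rng.random() < p_unknown else str(rng.choice(females))
            recs.append(IndividualRecord(dog, sire, dam, sex))
        (males if sex == MALE else females).append(dog)
    return Pedigree(recs)


@pytest.fixture
def trio_ped():
    return Pedigree([
        IndividualRecord("S", sex=MALE),
        IndividualRecord("D", sex=FEMALE),
        IndividualRecord("X", "S", "D", MALE),
    ])


@pytest.fixture
def fullsib_ped():
    """Two founders, two full sibs, and their (inbred, F=0.25) offspring."""
    return Pedigree([
        IndividualRecord("S", sex=MALE),
        IndividualRecord("D", sex=FEMALE),
        IndividualRecord("A", "S", "D", MALE),
        IndividualRecord("B", "S", "D", FEMALE),
        IndividualRecord("X", "A", "B", MALE),
    ])


@pytest.fixture
def halfsib_ped():
    """Offspring of paternal half sibs out of unrelated founders: F = 0.125."""
    return Pedigree([
        IndividualRecord("S", sex=MALE),
        IndividualRecord("D1", sex=FEMALE),
        IndividualRecord("D2", sex=FEMALE),
        IndividualRecord("A", "S", "D1", MALE),
        IndividualRecord("B", "S", "D2", FEMALE),
        IndividualRecord("X", "A", "B", MALE),
    ])
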