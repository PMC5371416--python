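import numpy as np
import pytest

from attcfold.attc import ConstraintSet
from attcfold.folding import ReferenceModel
from attcfold.synthetic import AttCGeneratorParams, generate_attc


@pytest.fixture(scope="session")
def ref_model():
    return ReferenceModel()


@pytest.fixture()
def clean_site():
    """A mismatch-free synthetic site with known planted boxes."""
    site, truth = generate_attc(AttCGeneratorParams(), seed=42)
    return site, truth


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def random_compatible_constraint(rng, seq, model, max_pairs=2):
    """A random non-crossing constraint over complementary positions."""
    n = len(seq)
    cands = [(i, j) for i in range(n) for j in range(i + 4, n)
             if model.pairable(seq[i], seq[j])]
    if not cands:
        return None
    picks = [cands[rng.integers(len(cands))]]
    if len(cands) > 1 and max_pairs > 1 and rng.random() < 0.5:
        i2, j2 = cands[rng.integers(len(cands))]
        i1, j1 = picks[0]
        if ({i2, j2} & {i1, j1} == set()
                and not (i1 < i2 < j1 < j2) and not (i2 < i1 < j2 < j1)):
            picks.append((i2, j2))
    return ConstraintSet(frozenset(picks), "bottom")
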