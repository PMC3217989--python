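import numpy as np
import pytest

from mirduplex.hairpin import PremiRNA, NussinovBackend, ViennaBackend
from mirduplex.simulate import SynthParams, sample_dataset

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def perfect_hairpin(stem: int = 21, loop: int = 4, seed: int = 0, rid: str = "hp") -> PremiRNA:
    """Fully paired hairpin: ``stem`` pairs around an unpaired loop."""
    rng = np.random.default_rng(seed)
    arm5 = "".join(rng.choice(list("ACGU")) for _ in range(stem))
    loop_seq = "".join(rng.choice(list("ACGU")) for _ in range(loop))
    seq = arm5 + loop_seq + "".join(_COMP[c] for c in reversed(arm5))
    struct = "(" * stem + "." * loop + ")" * stem
    return PremiRNA(rid, seq, struct)


def random_nested_structure(rng: np.random.Generator, n: int) -> str:
    """A random balanced dot-bracket string of length n with >= 1 pair."""
    while True:
        chars = []
        open_stack = 0
        for i in range(n):
            remaining = n - i
            just_opened = chars and chars[-1] == "("
            if open_stack >= remaining and not just_opened:
                chars.append(")")
                open_stack -= 1
            elif open_stack > 0 and not just_opened and rng.random() < 0.35:
                # never ")" right after "(": empty hairpin loops are excluded
                chars.append(")")
                open_stack -= 1
            elif rng.random() < 0.4 and remaining > open_stack + 2:
                chars.append("(")
                open_stack += 1
            else:
                chars.append(".")
        out = "".join(chars)
        if "(" in out and open_stack == 0:
            return out


@pytest.fixture(scope="session")
def vienna():
    return ViennaBackend()


@pytest.fixture(scope="session")
def nussinov():
    return NussinovBackend()


@pytest.fixture(scope="session")
def hairpin46():
    """46-nt perfect hairpin: positions 0-20 paired to 45-25, loop 21-24."""
    return perfect_hairpin(stem=21, loop=4, seed=0, rid="hp46")


@pytest.fixture(scope="session")
def tiny_dataset():
    """Ten synthetic hairpins with labeled candidates (fixed seed)."""
    return sample_dataset(SynthParams(n_hairpins=10, seed=42))


class StubBackend:
    """Folding backend echoing a fixed structure (contract test double)."""

    def __init__(self, structure: str, mfe: float = -1.0):
        self.structure, self.mfe = structure, mfe

    def fold(self, sequence):
        return self.structure[: len(sequence)].ljust(len(sequence), "."), self.mfe

    def fold_constrained(self, sequence, unpaired):
        return self.fold(sequence)
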