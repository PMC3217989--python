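"""Synthetic pre-miRNA hairpins with planted miRNA:miRNA* duplexes.

The generator emulates the structure of a plant pre-miRNA training set so
the whole pipeline is testable without any database download: each hairpin
has a 5' arm, a terminal loop and a 3' arm that is the reverse complement
of the 5' arm degraded by per-position mismatch and bulge noise.  One L-nt
mature miRNA is planted per hairpin (occasionally its star strand is a
second annotated miRNA); within the planted duplex the per-column pairing
probability is ``q_in``, elsewhere ``q_out``, and the duplex 5' ends carry
the biogenesis stability bias (A-U pair at the miRNA 5' end, G-C at the
star 5' end).  Because most window placements are pseudo duplexes, the
pseudo:real candidate ratio lands in the tens-per-one regime of real
training data.

Structures are constructed directly from the generative pair table, which
decouples tests from any folding backend; ``fold_structures=True`` switches
to backend folding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .candidates import (
    FilterThresholds,
    enumerate_candidates,
    filter_candidates,
    label_candidates,
)
from .hairpin import UNPAIRED, PremiRNA, structure_from_pairs

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_BASES = ("A", "C", "G", "U")


@dataclass(frozen=True)
class SynthParams:
    """Generator settings; the defaults are the conditions used throughout."""

    n_hairpins: int = 100
    stem_len: tuple[int, int] = (45, 70)     # paired-column count per arm, inclusive
    loop_len: tuple[int, int] = (4, 9)
    q_in: float = 0.95                       # pairing probability inside the planted duplex
    q_out: float = 0.6                       # ... outside it
    bulge_rate: float = 0.03                 # per-column chance of a 1-2 nt bulge
    wobble_prob: float = 0.1                 # G-U instead of Watson-Crick when paired
    dangle_max: int = 4                      # unpaired nts at each hairpin end
    end_bias: bool = True                    # plant A-U / G-C pairs at the duplex 5' ends
    window_len: int = 21
    p_second_mirna: float = 0.2              # chance the star is annotated as a 2nd miRNA
    seed: int = 0

    def __post_init__(self):
        if self.q_in < self.q_out:
            raise ValueError("q_in must be >= q_out for a planted signal to exist")
        if self.stem_len[0] < self.window_len + 3:
            raise ValueError("stem too short to host a window plus the 2-nt offset")


def _pair_bases(rng, wobble_prob: float) -> tuple[str, str]:
    if rng.random() < wobble_prob:
        return ("G", "U") if rng.random() < 0.5 else ("U", "G")
    b = _BASES[rng.integers(4)]
    return b, _COMPLEMENT[b]


def sample_hairpin(rng: np.random.Generator, params: SynthParams) -> tuple[PremiRNA, list[int]]:
    """One synthetic hairpin plus the planted true miRNA start(s)."""
    L = params.window_len
    S = int(rng.integers(params.stem_len[0], params.stem_len[1] + 1))
    loop_n = int(rng.integers(params.loop_len[0], params.loop_len[1] + 1))
    arm = "5p" if rng.random() < 0.5 else "3p"
    # duplex columns [a, a+L+2): the miRNA window plus the 2-column star offset
    a = int(rng.integers(0, S - L - 1))
    protected = range(max(0, a - 1), min(S, a + L + 3))

    paired = np.zeros(S, dtype=bool)
    nt5 = [""] * S
    nt3 = [""] * S
    bulge5: dict[int, str] = {}
    bulge3: dict[int, str] = {}
    for c in range(S):
        in_duplex = a <= c < a + L + 2
        paired[c] = rng.random() < (params.q_in if in_duplex else params.q_out)
        if paired[c]:
            nt5[c], nt3[c] = _pair_bases(rng, params.wobble_prob)
        else:
            nt5[c] = _BASES[rng.integers(4)]
            nt3[c] = _BASES[rng.integers(4)]
        if c not in protected and rng.random() < params.bulge_rate:
            extra = "".join(_BASES[rng.integers(4)] for _ in range(int(rng.integers(1, 3))))
            if rng.random() < 0.5:
                bulge5[c] = extra
            else:
                bulge3[c] = extra

    # the duplex 5'-end columns are always paired, optionally with the
    # stability bias: unstable (A-U) miRNA 5' end, stable (G-C) star 5' end
    if arm == "5p":
        c_mirna5, c_star5 = a, a + L + 1
        mirna5_side, star5_side = "5", "3"
    else:
        c_mirna5, c_star5 = a + L - 1, a + 2
        mirna5_side, star5_side = "3", "5"
    for c in (c_mirna5, c_star5):
        paired[c] = True
    if params.end_bias:
        if mirna5_side == "5":
            nt5[c_mirna5], nt3[c_mirna5] = "A", "U"
        else:
            nt5[c_mirna5], nt3[c_mirna5] = "U", "A"
        if star5_side == "5":
            nt5[c_star5], nt3[c_star5] = "G", "C"
        else:
            nt5[c_star5], nt3[c_star5] = "C", "G"
    else:
        for c in (c_mirna5, c_star5):
            nt5[c], nt3[c] = _pair_bases(rng, params.wobble_prob)

    # assemble: 5' dangle, 5' arm (columns outward->loop), loop, 3' arm
    # (columns loop->outward), 3' dangle; track absolute per-column indices
    seq: list[str] = []
    d5 = int(rng.integers(0, params.dangle_max + 1))
    seq.extend(_BASES[rng.integers(4)] for _ in range(d5))
    i5 = {}
    for c in range(S):
        i5[c] = len(seq)
        seq.append(nt5[c])
        seq.extend(bulge5.get(c, ""))
    seq.extend(_BASES[rng.integers(4)] for _ in range(loop_n))
    i3 = {}
    for c in reversed(range(S)):
        i3[c] = len(seq)
        seq.append(nt3[c])
        seq.extend(bulge3.get(c, ""))
    seq.extend(_BASES[rng.integers(4)] for _ in range(int(rng.integers(0, params.dangle_max + 1))))

    pt = np.full(len(seq), UNPAIRED, dtype=int)
    for c in range(S):
        if paired[c]:
            pt[i5[c]], pt[i3[c]] = i3[c], i5[c]

    true_start = i5[a] if arm == "5p" else i3[a + L - 1]
    star_start = i3[a + L + 1] if arm == "5p" else i5[a + 2]
    trues = [true_start]
    if rng.random() < params.p_second_mirna:
        trues.append(star_start)

    pre = PremiRNA(
        id="synth",
        sequence="".join(seq),
        structure=structure_from_pairs(pt),
        pair_table=pt,
    )
    return pre, trues


@dataclass
class SynthDataset:
    """Hairpins, annotations, labeled candidates and a train/test split."""

    premirnas: list[PremiRNA]
    annotations: dict[str, list[int]]
    candidates: dict[str, list]
    train_ids: list[str]
    test_ids: list[str]

    def subset(self, ids: list[str]) -> tuple[list[PremiRNA], dict[str, list[int]]]:
        ids = set(ids)
        return (
            [p for p in self.premirnas if p.id in ids],
            {k: v for k, v in self.annotations.items() if k in ids},
        )


def sample_dataset(
    params: SynthParams = SynthParams(),
    test_fraction: float = 0.4,
    thresholds: FilterThresholds = FilterThresholds(),
    fold_structures: bool = False,
    backend=None,
) -> SynthDataset:
    """Generate hairpins, enumerate/filter/label candidates, split by hairpin."""
    rng = np.random.default_rng(params.seed)
    premirnas: list[PremiRNA] = []
    annotations: dict[str, list[int]] = {}
    candidates: dict[str, list] = {}
    for h in range(params.n_hairpins):
        pre, trues = sample_hairpin(rng, params)
        pre = replace_id(pre, f"synth-{h:04d}")
        if fold_structures:
            from .hairpin import default_backend, fold_sequence

            structure, mfe = fold_sequence(pre.sequence, backend or default_backend())
            pre = PremiRNA(id=pre.id, sequence=pre.sequence, structure=structure, mfe=mfe)
        premirnas.append(pre)
        annotations[pre.id] = trues
        cands = enumerate_candidates(pre, params.window_len)
        cands = filter_candidates(cands, pre.anatomy, thresholds)
        candidates[pre.id] = label_candidates(cands, trues, seq_len=len(pre))
    ids = [p.id for p in premirnas]
    order = rng.permutation(len(ids))
    n_test = int(round(test_fraction * len(ids)))
    test_ids = [ids[i] for i in sorted(order[:n_test])]
    train_ids = [i for i in ids if i not in set(test_ids)]
    return SynthDataset(premirnas, annotations, candidates, train_ids, test_ids)


def replace_id(pre: PremiRNA, new_id: str) -> PremiRNA:
    return PremiRNA(
        id=new_id, sequence=pre.sequence, structure=pre.structure,
        mfe=pre.mfe, pair_table=pre.pair_table,
    )


def imbalance_ratio(dataset: SynthDataset) -> float:
    """Pseudo:real candidate ratio over the whole dataset."""
    n_real = sum(1 for cs in dataset.candidates.values() for c in cs if c.label == "real")
    n_pseudo = sum(1 for cs in dataset.candidates.values() for c in cs if c.label == "pseudo")
    return n_pseudo / max(1, n_real)
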