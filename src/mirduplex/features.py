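"""Per-candidate feature extraction for miRNA:miRNA* duplexes.

Three families of features describe a candidate duplex:

* position-specific symbols — every slot of the miRNA window, the star
  window and the flanking regions is one of 10 symbols: the 8 combinations
  of base {A,C,G,U} with pairing state {M (matched), L (loose/unpaired)},
  the ``noValue`` symbol for slots beyond the sequence ends, and the gap
  symbol ``-|L`` for star slots opposite a bulge where no nucleotide exists;
* local contiguous triplet structure features — for each sliding window of
  3 nucleotides, the paired/unpaired pattern of the three positions (both
  bracket orientations collapsed to '(') keyed by the middle base, 32
  categories per strand, reported as frequencies;
* stability / distance / energy features — the pairing class of the two
  5'-end nucleotides (0 unpaired, 1 G-U wobble, 2 A-U, 3 G-C), the distance
  of the miRNA start from the terminal loop (``dis``), and three duplex
  minimum-free-energy values (``MFE_1..3``) computed on the miRNA and star
  sequences joined by a 6-symbol non-pairing linker, with 0/3/6-nt flanks.

With 21-nt windows and 12-nt flanks this yields 90 + 64 + 6 = 160 features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .candidates import DuplexCandidate
from .hairpin import UNPAIRED, HairpinAnatomy, PremiRNA

# the 10-symbol per-position alphabet: 8 base/pairing combinations,
# the noValue pair, and the novel gap symbol for bulge-opposite slots
POSITION_ALPHABET = (
    "A|M", "A|L", "C|M", "C|L", "U|M", "U|L", "G|M", "G|L", "noValue", "-|L",
)
NO_VALUE = "noValue"
GAP = "-|L"

TRIPLET_PATTERNS = ("(((", "((.", "(..", "(.(", ".((", ".(.", "..(", "...")
BASES = ("A", "C", "G", "U")

S4_NAMES = ("dis", "miRNA_5end", "miRNA*_5end", "MFE_1", "MFE_2", "MFE_3")


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction geometry: window length, flank length, MFE realization."""

    window_len: int = 21
    flank_len: int = 6            # evaluated flank sizes: 0, 2, 3, 6, 9, 12
    linker_len: int = 6
    mfe_flanks: tuple[int, ...] = (0, 3, 6)
    mfe_realization: str = "constrained"   # 'constrained' or 'linker'

    VALID_FLANKS = (0, 2, 3, 6, 9, 12)

    def __post_init__(self):
        if self.flank_len not in self.VALID_FLANKS:
            raise ValueError(f"flank_len must be one of {self.VALID_FLANKS}")


# ---------------------------------------------------------------------------
# Feature name inventory
# ---------------------------------------------------------------------------

def positional_feature_names(window_len: int = 21, flank_len: int = 12) -> list[str]:
    L, s = window_len, flank_len
    names = [f"miRNA_{i}" for i in range(1, L + 1)]
    names += [f"miRNA*_{i}" for i in range(1, L + 1)]
    for strand in ("miRNA", "miRNA*"):
        names += [f"bef_{strand}_{j}" for j in range(1, s + 1)]
        names += [f"aft_{strand}_{j}" for j in range(1, s + 1)]
    return names


def triplet_feature_names() -> list[str]:
    return [
        f"{strand}_{base}{pat}"
        for strand in ("miRNA", "miRNA*")
        for base in BASES
        for pat in TRIPLET_PATTERNS
    ]


def full_feature_names(window_len: int = 21, flank_len: int = 12) -> list[str]:
    """The complete inventory: positional + triplet + S4 (160 at L=21, s=12)."""
    return positional_feature_names(window_len, flank_len) + triplet_feature_names() + list(S4_NAMES)


def categorical_feature_names(window_len: int = 21, flank_len: int = 12) -> set[str]:
    return set(positional_feature_names(window_len, flank_len))


# ---------------------------------------------------------------------------
# Position-specific symbols
# ---------------------------------------------------------------------------

def encode_position(pre: PremiRNA, pos: int) -> str:
    """Symbol for an absolute position: (base, M/L), or noValue outside."""
    if pos < 0 or pos >= len(pre):
        return NO_VALUE
    state = "M" if pre.pair_table[pos] != UNPAIRED else "L"
    return f"{pre.sequence[pos]}|{state}"


def _star_window_symbols(pre: PremiRNA, cand: DuplexCandidate) -> list[str]:
    """Star-window symbols, laid slot-by-slot against the miRNA window.

    Slot t of the star is the alignment column of miRNA position
    ``mirna_start + t``: the partner nucleotide when that position is
    paired; for unpaired miRNA positions, the unpaired star nucleotides
    between the neighbouring partners are consumed in order and slots left
    over (the opposite strand has no nucleotide there, i.e. a miRNA-side
    bulge) receive the gap symbol.  The returned list is re-numbered so
    that index 0 is the star's own 5' end.
    """
    pt = pre.pair_table
    L = cand.window_len
    m = cand.mirna_start
    paired_slots = [t for t in range(L) if pt[m + t] != UNPAIRED]
    symbols: list[str] = [GAP] * L

    def sym(pos: int) -> str:
        return encode_position(pre, pos)

    for t in paired_slots:
        symbols[t] = sym(int(pt[m + t]))

    # gaps/unpaired star nucleotides between consecutive paired slots
    for a, b in zip(paired_slots, paired_slots[1:]):
        j_hi, j_lo = int(pt[m + a]), int(pt[m + b])
        if j_lo > j_hi:      # non-nested oddity: leave gap symbols in place
            continue
        avail = j_hi - j_lo - 1          # unpaired star nts in this column range
        for r, t in enumerate(range(a + 1, b)):
            symbols[t] = sym(j_hi - 1 - r) if r < avail else GAP

    # slots before the first / after the last paired slot continue the
    # alignment outward along the star strand
    first, last = paired_slots[0], paired_slots[-1]
    for t in range(first):
        symbols[t] = sym(int(pt[m + first]) + (first - t))
    for t in range(last + 1, L):
        symbols[t] = sym(int(pt[m + last]) - (t - last))

    # slot t follows the miRNA 5'->3' direction, which runs 3'->5' along the
    # star; re-number so miRNA*_1 is the star 5' end
    return symbols[::-1]


def positional_features(
    cand: DuplexCandidate, pre: PremiRNA, cfg: FeatureConfig
) -> dict[str, str]:
    """Named position symbols for both windows and their flanks.

    At L=21 and s=12 this yields 21+21+24+24 = 90 symbols.
    """
    L, s = cand.window_len, cfg.flank_len
    out: dict[str, str] = {}
    for t in range(L):
        out[f"miRNA_{t + 1}"] = encode_position(pre, cand.mirna_start + t)
    for t, symbol in enumerate(_star_window_symbols(pre, cand)):
        out[f"miRNA*_{t + 1}"] = symbol
    for j in range(1, s + 1):
        out[f"bef_miRNA_{j}"] = encode_position(pre, cand.mirna_start - j)
        out[f"aft_miRNA_{j}"] = encode_position(pre, cand.mirna_end - 1 + j)
    for j in range(1, s + 1):
        out[f"bef_miRNA*_{j}"] = encode_position(pre, cand.star_start - j)
        out[f"aft_miRNA*_{j}"] = encode_position(pre, cand.star_end - 1 + j)
    return out


# ---------------------------------------------------------------------------
# Distance, 5'-end stability, MFE
# ---------------------------------------------------------------------------

def dis_feature(cand: DuplexCandidate, anatomy: HairpinAnatomy) -> int:
    """Unsigned nt distance from the miRNA start to the terminal loop."""
    ls, le = anatomy.terminal_loop
    m = cand.mirna_start
    if ls <= m < le:
        return 0
    if le == ls:  # degenerate empty loop: distance to the turn point
        return abs(m - ls) if m < ls else m - ls + 1
    return ls - m if m < ls else m - (le - 1)


_PAIR_CODE = {
    frozenset(("G", "U")): 1,
    frozenset(("A", "U")): 2,
    frozenset(("G", "C")): 3,
}


def _end_code(pre: PremiRNA, pos: int) -> int:
    partner = int(pre.pair_table[pos])
    if partner == UNPAIRED:
        return 0
    return _PAIR_CODE.get(frozenset((pre.sequence[pos], pre.sequence[partner])), 0)


def stability_5prime(cand: DuplexCandidate, pre: PremiRNA) -> tuple[int, int]:
    """Pairing-stability class of the miRNA and star 5'-end nucleotides.

    0 = unpaired, 1 = G-U/U-G wobble, 2 = A-U/U-A, 3 = G-C/C-G.  A less
    stable miRNA 5' end than star 5' end marks the functional strand.
    """
    return _end_code(pre, cand.mirna_start), _end_code(pre, cand.star_start)


def mfe_features(
    cand: DuplexCandidate, pre: PremiRNA, backend, cfg: FeatureConfig = FeatureConfig()
) -> tuple[float, ...]:
    """Duplex minimum free energies MFE_1..3 (flanks 0, 3 and 6 nt).

    The miRNA and star segments (with flanks truncated at the sequence
    ends) are joined by a non-pairing 6-symbol linker.  Realization
    'constrained' folds miRNA+NNNNNN+star with the linker positions forced
    unpaired; 'linker' folds the literal miRNA+LLLLLL+star string and relies
    on the backend treating unknown letters as non-pairing.
    """
    n = len(pre)
    seq = pre.sequence
    values = []
    for f in cfg.mfe_flanks:
        a = seq[max(0, cand.mirna_start - f): min(n, cand.mirna_end + f)]
        b = seq[max(0, cand.star_start - f): min(n, cand.star_end + f)]
        lo, hi = (a, b) if cand.mirna_start <= cand.star_start else (b, a)
        if cfg.mfe_realization == "linker":
            combined = lo + "L" * cfg.linker_len + hi
            _, mfe = backend.fold(combined)
        else:
            combined = lo + "N" * cfg.linker_len + hi
            linker_pos = range(len(lo), len(lo) + cfg.linker_len)
            _, mfe = backend.fold_constrained(combined, list(linker_pos))
        values.append(float(mfe))
    return tuple(values)


# ---------------------------------------------------------------------------
# Triplet structure features
# ---------------------------------------------------------------------------

def triplet_features(seq_window: str, struct_window: str, prefix: str = "miRNA") -> dict[str, float]:
    """Frequencies of the 32 middle-base x pairing-pattern triplet categories.

    Both bracket orientations are collapsed to '(' before counting, the
    usual convention of triplet-structure classifiers; counts are
    normalized by the number of triplets (len - 2).  All 32 keys are
    always present.
    """
    if len(seq_window) < 3:
        raise ValueError("triplet features require a window of length >= 3")
    if len(seq_window) != len(struct_window):
        raise ValueError("sequence and structure windows differ in length")
    collapsed = struct_window.replace(")", "(")
    counts = {f"{prefix}_{b}{p}": 0 for b in BASES for p in TRIPLET_PATTERNS}
    n_triplets = len(seq_window) - 2
    for t in range(n_triplets):
        key = f"{prefix}_{seq_window[t + 1]}{collapsed[t:t + 3]}"
        counts[key] += 1
    return {k: v / n_triplets for k, v in counts.items()}


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------

def extract_features(
    cand: DuplexCandidate,
    pre: PremiRNA,
    cfg: FeatureConfig = FeatureConfig(),
    backend=None,
) -> dict:
    """The full named feature map for one candidate (160 at L=21, s=12).

    Triplet features are computed on the candidate windows' sub-structure
    taken from the full-hairpin fold, not a re-fold of the window.
    """
    out: dict = {}
    out.update(positional_features(cand, pre, cfg))
    out.update(
        triplet_features(
            pre.sequence[cand.mirna_start: cand.mirna_end],
            pre.structure[cand.mirna_start: cand.mirna_end],
            prefix="miRNA",
        )
    )
    out.update(
        triplet_features(
            pre.sequence[cand.star_start: cand.star_end],
            pre.structure[cand.star_start: cand.star_end],
            prefix="miRNA*",
        )
    )
    out["dis"] = dis_feature(cand, pre.anatomy)
    out["miRNA_5end"], out["miRNA*_5end"] = stability_5prime(cand, pre)
    if backend is None:
        from .hairpin import default_backend

        backend = default_backend()
    out["MFE_1"], out["MFE_2"], out["MFE_3"] = mfe_features(cand, pre, backend, cfg)
    return out


def extract_table(
    premirnas: list[PremiRNA],
    candidates_by_id: dict[str, list[DuplexCandidate]],
    cfg: FeatureConfig = FeatureConfig(),
    backend=None,
) -> pd.DataFrame:
    """Feature table: one row per candidate, id/start/arm/label columns first."""
    if backend is None:
        from .hairpin import default_backend

        backend = default_backend()
    pre_by_id = {p.id: p for p in premirnas}
    rows = []
    for rid, cands in candidates_by_id.items():
        pre = pre_by_id[rid]
        for c in cands:
            row = {
                "premirna_id": rid,
                "mirna_start": c.mirna_start,
                "arm": c.arm,
                "label": c.label,
            }
            row.update(extract_features(c, pre, cfg, backend))
            rows.append(row)
    columns = ["premirna_id", "mirna_start", "arm", "label"] + full_feature_names(
        cfg.window_len, cfg.flank_len
    )
    return pd.DataFrame(rows, columns=columns)


def write_feature_table(table: pd.DataFrame, path_or_buf) -> None:
    out = table.copy()
    out["mirna_start_1based"] = out.pop("mirna_start") + 1
    cols = ["premirna_id", "mirna_start_1based", "arm", "label"] + [
        c for c in out.columns if c not in ("premirna_id", "mirna_start_1based", "arm", "label")
    ]
    out[cols].to_csv(path_or_buf, sep="\t", index=False)
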