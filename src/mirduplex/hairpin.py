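"""Pre-miRNA hairpin records: FASTA/Vienna I/O, folding backends, pair tables, anatomy.

A pre-miRNA is a single-stranded RNA that folds back on itself into a
stem-loop (hairpin).  Everything downstream (candidate enumeration, feature
extraction) works off the dot-bracket secondary structure of the hairpin,
represented here as a symmetric pair table plus a structural "anatomy":
the terminal loop, the two arms, bulges, internal loops and unmatched ends.

Coordinates are 0-based, half-open throughout the library; user-facing
tables convert to 1-based inclusive on write.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

UNPAIRED = -1
_RNA_ALPHABET = frozenset("ACGU")


class HairpinError(ValueError):
    """Base class for structural errors on hairpin records."""


class StructureParseError(HairpinError):
    """Dot-bracket string is unbalanced or malformed."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class NoHairpinError(HairpinError):
    """Structure contains no base pair, so no hairpin exists."""


class FoldingBackendUnavailable(RuntimeError):
    """The requested folding backend cannot be used.

    Raised explicitly (never a silent fallback): the folding contract is
    ``fold(seq) -> (dot-bracket, mfe)`` and
    ``fold_constrained(seq, unpaired) -> (dot-bracket, mfe)``.
    """


# ---------------------------------------------------------------------------
# FASTA / Vienna parsing
# ---------------------------------------------------------------------------

def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U."""
    return seq.upper().replace("T", "U")


def parse_fasta(stream) -> list[tuple[str, str]]:
    """Read FASTA records as (id, RNA sequence) pairs.

    Sequences are uppercased and T is normalized to U.  Records that are
    empty or contain characters outside {A,C,G,U} (e.g. ambiguity codes)
    are skipped with a logged warning; record order is preserved.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: list[tuple[str, str]] = []
    for rec in SeqIO.parse(stream, "fasta"):
        seq = normalize_rna(str(rec.seq))
        if not seq:
            logger.warning("skipping empty FASTA record %r", rec.id)
            continue
        if not set(seq) <= _RNA_ALPHABET:
            bad = sorted(set(seq) - _RNA_ALPHABET)
            logger.warning("skipping record %r with non-ACGU characters %s", rec.id, bad)
            continue
        out.append((rec.id, seq))
    return out


def write_fasta(records: Iterable[tuple[str, str]], stream) -> None:
    for rid, seq in records:
        stream.write(f">{rid}\n{seq}\n")


def parse_vienna(stream) -> list["PremiRNA"]:
    """Read records in Vienna format: ``>id`` / sequence / ``structure (mfe)``."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = [ln.rstrip("\n") for ln in stream if ln.strip()]
    out = []
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise StructureParseError(f"expected header at line {i + 1}")
        rid = lines[i][1:].split()[0]
        seq = normalize_rna(lines[i + 1].strip())
        struct_line = lines[i + 2].strip()
        mfe = None
        if "(" in struct_line and struct_line.rstrip().endswith(")") and " " in struct_line:
            struct, _, tail = struct_line.rpartition(" ")
            struct = struct.strip()
            mfe = float(tail.strip("() "))
        else:
            struct = struct_line
        out.append(PremiRNA(id=rid, sequence=seq, structure=struct, mfe=mfe))
        i += 3
    return out


def write_vienna(records: Iterable["PremiRNA"], stream) -> None:
    for p in records:
        stream.write(f">{p.id}\n{p.sequence}\n{p.structure}")
        if p.mfe is not None:
            stream.write(f" ({p.mfe:.2f})")
        stream.write("\n")


# ---------------------------------------------------------------------------
# Folding backends
# ---------------------------------------------------------------------------

class ViennaBackend:
    """Thermodynamic MFE folding via the RNAlib python bindings."""

    def __init__(self):
        try:
            import RNA  # noqa: F401
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise FoldingBackendUnavailable(
                "ViennaRNA python bindings (module 'RNA') are required by the "
                "folding contract fold(seq) -> (structure, mfe); install "
                "ViennaRNA or inject another backend"
            ) from exc
        self._RNA = __import__("RNA")

    def fold(self, sequence: str) -> tuple[str, float]:
        structure, mfe = self._RNA.fold(sequence)
        return structure, float(mfe)

    def fold_constrained(self, sequence: str, unpaired: Sequence[int]) -> tuple[str, float]:
        """MFE fold with the given 0-based positions forced unpaired."""
        fc = self._RNA.fold_compound(sequence)
        for pos in unpaired:
            fc.hc_add_up(pos + 1)  # RNAlib is 1-based
        structure, mfe = fc.mfe()
        return structure, float(mfe)


class NussinovBackend:
    """Base-pair maximization folding (Nussinov DP).

    Deterministic, dependency-free alternative satisfying the folding
    contract; the pseudo-energy is -1 kcal/mol per pair.  Minimum loop
    size 3, Watson-Crick plus G-U pairs.
    """

    _CAN_PAIR = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")})
    MIN_LOOP = 3

    def _pairable(self, a: str, b: str) -> bool:
        return (a, b) in self._CAN_PAIR

    def fold(self, sequence: str) -> tuple[str, float]:
        return self._fold(sequence, frozenset())

    def fold_constrained(self, sequence: str, unpaired: Sequence[int]) -> tuple[str, float]:
        return self._fold(sequence, frozenset(unpaired))

    def _fold(self, seq: str, forbidden: frozenset) -> tuple[str, float]:
        n = len(seq)
        dp = np.zeros((n + 1, n + 1), dtype=int)
        for span in range(self.MIN_LOOP + 1, n):
            for i in range(0, n - span):
                j = i + span
                best = dp[i][j - 1]
                for t in range(i, j - self.MIN_LOOP):
                    if t in forbidden or j in forbidden:
                        continue
                    if self._pairable(seq[t], seq[j]):
                        cand = dp[i][t - 1] + 1 + dp[t + 1][j - 1] if t > i else 1 + dp[t + 1][j - 1]
                        best = max(best, cand)
                dp[i][j] = best
        structure = ["."] * n

        def traceback(i: int, j: int) -> None:
            while i < j:
                if dp[i][j] == dp[i][j - 1]:
                    j -= 1
                    continue
                for t in range(i, j - self.MIN_LOOP):
                    if t in forbidden or j in forbidden or not self._pairable(seq[t], seq[j]):
                        continue
                    left = dp[i][t - 1] if t > i else 0
                    if left + 1 + dp[t + 1][j - 1] == dp[i][j]:
                        structure[t], structure[j] = "(", ")"
                        traceback(i, t - 1)
                        i, j = t + 1, j - 1
                        break
                else:  # pragma: no cover - defensive
                    break

        if n:
            traceback(0, n - 1)
        n_pairs = structure.count("(")
        return "".join(structure), -float(n_pairs)


def default_backend():
    return ViennaBackend()


def fold_sequence(sequence: str, backend=None) -> tuple[str, float]:
    """Fold an RNA sequence with the given backend (default: ViennaRNA MFE)."""
    if not sequence:
        raise ValueError("cannot fold an empty sequence")
    if backend is None:
        backend = default_backend()
    structure, mfe = backend.fold(sequence)
    if len(structure) != len(sequence):
        raise HairpinError("backend returned structure of wrong length")
    return structure, mfe


# ---------------------------------------------------------------------------
# Pair table and anatomy
# ---------------------------------------------------------------------------

def build_pair_table(structure: str) -> np.ndarray:
    """Map each position to its partner index, or UNPAIRED (-1) for dots.

    Raises StructureParseError (with the offending position) on unbalanced
    brackets or foreign characters.
    """
    pt = np.full(len(structure), UNPAIRED, dtype=int)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureParseError(f"unmatched ')' at index {i}", position=i)
            j = stack.pop()
            pt[j], pt[i] = i, j
        elif ch != ".":
            raise StructureParseError(f"invalid character {ch!r} at index {i}", position=i)
    if stack:
        raise StructureParseError(f"unmatched '(' at index {stack[0]}", position=stack[0])
    return pt


def structure_from_pairs(pair_table: Sequence[int]) -> str:
    """Dot-bracket string from a symmetric pair table (nested pairs only)."""
    chars = []
    for i, j in enumerate(pair_table):
        if j == UNPAIRED:
            chars.append(".")
        elif j > i:
            chars.append("(")
        else:
            chars.append(")")
    return "".join(chars)


@dataclass(frozen=True)
class HairpinAnatomy:
    """Structural regions of a hairpin, all as 0-based half-open spans."""

    terminal_loop: tuple[int, int]
    arm5: tuple[int, int]
    arm3: tuple[int, int]
    bulges: tuple[tuple[int, int], ...]
    internal_loops: tuple[tuple[int, int], ...]
    unmatched_ends: tuple[tuple[int, int], ...]


def _unpaired_runs(pt: np.ndarray) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, p in enumerate(pt):
        if p == UNPAIRED and start is None:
            start = i
        elif p != UNPAIRED and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(pt)))
    return runs


def annotate_anatomy(pre: "PremiRNA") -> HairpinAnatomy:
    """Classify unpaired regions of the hairpin.

    The terminal loop is the hairpin loop (unpaired run closed by its
    flanking pair) enclosed by the largest number of pairs; branched
    structures with several hairpin loops are kept but logged.  Each other
    internal unpaired run is a bulge when its two flanking pairs are
    adjacent on the opposite strand, otherwise part of an internal loop.
    """
    pt = pre.pair_table
    n = len(pt)
    if not (pt != UNPAIRED).any():
        raise NoHairpinError(f"{pre.id}: structure has no base pair")

    runs = _unpaired_runs(pt)
    # hairpin loops: runs immediately enclosed by a single pair
    hairpin_loops = []
    # empty loops (adjacent "()" pairs) are also hairpin turns
    for a in range(n - 1):
        if pt[a] == a + 1:
            hairpin_loops.append((a + 1, a + 1))
    for a, b in runs:
        if a > 0 and b < n and pt[a - 1] == b:
            hairpin_loops.append((a, b))
    if not hairpin_loops:
        raise NoHairpinError(f"{pre.id}: no hairpin loop found")

    depth = np.cumsum([1 if c == "(" else (-1 if c == ")" else 0) for c in pre.structure])

    def loop_depth(span):
        a, _ = span
        return depth[a - 1] if a > 0 else 0

    if len(hairpin_loops) > 1:
        logger.warning("%s: branched structure with %d hairpin loops; using the most "
                       "deeply enclosed one", pre.id, len(hairpin_loops))
    terminal_loop = max(hairpin_loops, key=lambda s: (loop_depth(s), -s[0]))

    bulges: list[tuple[int, int]] = []
    internal: list[tuple[int, int]] = []
    unmatched: list[tuple[int, int]] = []
    for a, b in runs:
        if (a, b) == terminal_loop:
            continue
        if a == 0 or b == n:
            unmatched.append((a, b))
            continue
        if abs(int(pt[a - 1]) - int(pt[b])) == 1:
            bulges.append((a, b))
        else:
            internal.append((a, b))

    return HairpinAnatomy(
        terminal_loop=terminal_loop,
        arm5=(0, terminal_loop[0]),
        arm3=(terminal_loop[1], n),
        bulges=tuple(bulges),
        internal_loops=tuple(internal),
        unmatched_ends=tuple(unmatched),
    )


# ---------------------------------------------------------------------------
# The hairpin record
# ---------------------------------------------------------------------------

@dataclass
class PremiRNA:
    """One pre-miRNA hairpin: sequence, dot-bracket structure, pair table."""

    id: str
    sequence: str
    structure: str
    mfe: float | None = None
    pair_table: np.ndarray = field(default=None, repr=False)
    _anatomy: HairpinAnatomy | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(self.structure) != len(self.sequence):
            raise HairpinError(
                f"{self.id}: structure length {len(self.structure)} != "
                f"sequence length {len(self.sequence)}"
            )
        if self.pair_table is None:
            self.pair_table = build_pair_table(self.structure)

    def __len__(self) -> int:
        return len(self.sequence)

    def __eq__(self, other):
        return (
            isinstance(other, PremiRNA)
            and self.id == other.id
            and self.sequence == other.sequence
            and self.structure == other.structure
            and (self.mfe is None) == (other.mfe is None)
            and (self.mfe is None or abs(self.mfe - other.mfe) < 0.005)
        )

    @property
    def anatomy(self) -> HairpinAnatomy:
        if self._anatomy is None:
            self._anatomy = annotate_anatomy(self)
        return self._anatomy

    @classmethod
    def from_sequence(cls, rid: str, sequence: str, backend=None) -> "PremiRNA":
        structure, mfe = fold_sequence(sequence, backend)
        return cls(id=rid, sequence=sequence, structure=structure, mfe=mfe)
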