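"""miRNA:miRNA* duplex candidate enumeration, filtering and labelling.

Two coupled windows slide with step 1 over a hairpin: window 1 is the
mature-miRNA candidate, window 2 the star candidate on the opposite arm.
The star has the same length as the miRNA and its 3' end sits 2 nt from the
pairing partner of the miRNA 5' end, displaced toward the terminal loop on
the opposite strand (the classic 2-nt 3' overhang left by Dicer/DCL1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .hairpin import UNPAIRED, HairpinAnatomy, PremiRNA

logger = logging.getLogger(__name__)


class StarUndefinedError(ValueError):
    """No valid star placement exists for this miRNA window."""


class AnnotationError(ValueError):
    """A true miRNA start is inconsistent with its pre-miRNA."""


@dataclass(frozen=True)
class FilterThresholds:
    """Cut-offs for discarding candidates that overlap large unpaired regions.

    ``math.inf`` for any field disables that rule.
    """

    loop_overlap_max: float = 6    # max nt of window overlap with the terminal loop
    big_bulge_min: float = 8       # bulges/internal loops at least this big are "big"
    big_unmatched_min: float = 8   # terminal unmatched regions at least this big

    @classmethod
    def permissive(cls) -> "FilterThresholds":
        return cls(math.inf, math.inf, math.inf)


@dataclass(frozen=True)
class DuplexCandidate:
    """A windowed miRNA:miRNA* placement (all coordinates 0-based half-open)."""

    premirna_id: str
    mirna_start: int
    window_len: int
    star_start: int
    star_end: int
    arm: str                      # '5p' or '3p': arm carrying the miRNA window
    label: str = "unknown"        # 'real', 'pseudo' or 'unknown'

    @property
    def mirna_end(self) -> int:
        return self.mirna_start + self.window_len

    @property
    def mirna_span(self) -> tuple[int, int]:
        return (self.mirna_start, self.mirna_end)

    @property
    def star_span(self) -> tuple[int, int]:
        return (self.star_start, self.star_end)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def locate_star(pre: PremiRNA, mirna_start: int, window_len: int) -> tuple[int, int]:
    """Place the star window for a miRNA window starting at ``mirna_start``.

    The anchor is the miRNA 5'-end nucleotide; when it is unpaired, the
    anchor slides 3'-ward to the first paired position inside the window and
    the star end is corrected by the slide distance.  The star 3' end lies
    2 nt from the (estimated) partner of the miRNA 5' end, toward the
    terminal loop on the opposite strand.

    Raises StarUndefinedError when no paired anchor exists in the window or
    the star window falls outside the sequence.
    """
    n = len(pre)
    L = window_len
    if mirna_start < 0 or mirna_start + L > n:
        raise StarUndefinedError(f"miRNA window [{mirna_start},{mirna_start + L}) outside sequence")
    pt = pre.pair_table
    anchor = next((i for i in range(mirna_start, mirna_start + L) if pt[i] != UNPAIRED), None)
    if anchor is None:
        raise StarUndefinedError("no paired anchor position within the miRNA window")
    slide = anchor - mirna_start
    partner = int(pt[anchor])
    # estimated partner of the true 5' end: sliding the anchor 3'-ward moves
    # its partner 5'-ward on the opposite strand, so compensate by +slide
    est_partner = partner + slide
    if partner > anchor:
        # miRNA on the 5' side of its pair; star on the 3' arm, where
        # "toward the loop" means decreasing coordinates
        star_3p_end = est_partner - 2
    else:
        star_3p_end = est_partner + 2
    star_start, star_end = star_3p_end - L + 1, star_3p_end + 1
    if star_start < 0 or star_end > n:
        raise StarUndefinedError(
            f"star window [{star_start},{star_end}) outside sequence of length {n}"
        )
    return star_start, star_end


def _arm_of(pre: PremiRNA, position: int) -> str:
    loop_start = pre.anatomy.terminal_loop[0]
    return "5p" if position < loop_start else "3p"


def enumerate_candidates(pre: PremiRNA, window_len: int) -> list[DuplexCandidate]:
    """All admissible miRNA:miRNA* placements, step 1, both arms.

    Starts whose star is undefined are skipped (and counted in the log).
    """
    n = len(pre)
    out: list[DuplexCandidate] = []
    dropped = 0
    for m in range(0, n - window_len + 1):
        try:
            ss, se = locate_star(pre, m, window_len)
        except StarUndefinedError:
            dropped += 1
            continue
        out.append(
            DuplexCandidate(
                premirna_id=pre.id,
                mirna_start=m,
                window_len=window_len,
                star_start=ss,
                star_end=se,
                arm=_arm_of(pre, m),
            )
        )
    if dropped:
        logger.debug("%s: %d window starts had no definable star", pre.id, dropped)
    return out


def filter_candidates(
    cands: list[DuplexCandidate],
    anatomy: HairpinAnatomy,
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[DuplexCandidate]:
    """Drop candidates overlapping the big loop, big bulges or unmatched ends.

    A candidate is removed when its miRNA or star window (i) overlaps the
    terminal loop by more than ``loop_overlap_max`` nt, (ii) touches a bulge
    or internal loop of size >= ``big_bulge_min`` nt, or (iii) touches a
    terminal unmatched region of size >= ``big_unmatched_min`` nt.
    """
    big_interior = [
        s for s in (*anatomy.bulges, *anatomy.internal_loops)
        if s[1] - s[0] >= thresholds.big_bulge_min
    ]
    big_ends = [
        s for s in anatomy.unmatched_ends if s[1] - s[0] >= thresholds.big_unmatched_min
    ]
    kept: list[DuplexCandidate] = []
    n_loop = n_bulge = n_end = 0
    for c in cands:
        windows = (c.mirna_span, c.star_span)
        if any(_overlap(w, anatomy.terminal_loop) > thresholds.loop_overlap_max for w in windows):
            n_loop += 1
            continue
        if any(_overlap(w, s) > 0 for w in windows for s in big_interior):
            n_bulge += 1
            continue
        if any(_overlap(w, s) > 0 for w in windows for s in big_ends):
            n_end += 1
            continue
        kept.append(c)
    if n_loop or n_bulge or n_end:
        logger.debug(
            "filtered %d candidates (loop=%d, bulge=%d, unmatched=%d), kept %d",
            n_loop + n_bulge + n_end, n_loop, n_bulge, n_end, len(kept),
        )
    return kept


def label_candidates(
    cands: list[DuplexCandidate],
    true_starts: list[int],
    seq_len: int | None = None,
) -> list[DuplexCandidate]:
    """Label each candidate real/pseudo by whether its start is a true start."""
    if seq_len is not None:
        for t in true_starts:
            if not (0 <= t < seq_len):
                raise AnnotationError(f"true start {t} outside sequence of length {seq_len}")
    truth = set(true_starts)
    return [replace(c, label="real" if c.mirna_start in truth else "pseudo") for c in cands]


# ---------------------------------------------------------------------------
# Annotation table and candidate dump I/O (TSV; 1-based inclusive on disk)
# ---------------------------------------------------------------------------

def read_annotations(path_or_buf) -> dict[str, list[int]]:
    """Read TSV (premirna_id, mirna_start_1based, mirna_name) -> 0-based starts."""
    df = pd.read_csv(path_or_buf, sep="\t")
    required = {"premirna_id", "mirna_start_1based"}
    if not required <= set(df.columns):
        raise AnnotationError(f"annotation table must have columns {sorted(required)}")
    out: dict[str, list[int]] = {}
    for rid, start in zip(df["premirna_id"], df["mirna_start_1based"]):
        out.setdefault(str(rid), []).append(int(start) - 1)
    return out


def write_annotations(annotations: dict[str, list[int]], path_or_buf) -> None:
    rows = [
        {"premirna_id": rid, "mirna_start_1based": s + 1, "mirna_name": f"{rid}-mir-{i + 1}"}
        for rid, starts in annotations.items()
        for i, s in enumerate(starts)
    ]
    pd.DataFrame(rows, columns=["premirna_id", "mirna_start_1based", "mirna_name"]).to_csv(
        path_or_buf, sep="\t", index=False
    )


def candidates_to_frame(cands: list[DuplexCandidate]) -> pd.DataFrame:
    """Candidate dump with 0-based to 1-based inclusive coordinate conversion."""
    return pd.DataFrame(
        {
            "premirna_id": [c.premirna_id for c in cands],
            "mirna_start_1based": [c.mirna_start + 1 for c in cands],
            "mirna_end_1based": [c.mirna_end for c in cands],
            "star_start_1based": [c.star_start + 1 for c in cands],
            "star_end_1based": [c.star_end for c in cands],
            "arm": [c.arm for c in cands],
            "label": [c.label for c in cands],
        }
    )
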