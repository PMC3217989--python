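"""Position-deviation metrics, distance distributions, cross-validation.

A prediction is scored by where the top-ranked candidate starts relative to
the annotated mature miRNA: the signed deviation x_i = p_i - a_i per
hairpin, summarized as the mean absolute deviation E (nt), the percentage P
of hairpins whose top candidate lies on the functional strand (the arm
carrying the mature miRNA), and the cumulative distribution of |x_i| within
0, +/-1, +/-2, +/-4, +/-6 and +/-8 nt.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_BINS = (0, 1, 2, 4, 6, 8)


def position_deviation(predicted: int, actual: int) -> int:
    """Signed deviation p - a; negative when the prediction is upstream."""
    return int(predicted) - int(actual)


def average_deviation(deviations) -> float:
    """Mean absolute deviation E (nt) over the evaluated hairpins."""
    deviations = np.asarray(list(deviations), dtype=float)
    if deviations.size == 0:
        raise ValueError("no deviations to average")
    return float(np.abs(deviations).mean())


def strand_accuracy(flags) -> float:
    """P = 100 * (correct functional-strand calls) / N, in percent."""
    flags = np.asarray(list(flags), dtype=float)
    if flags.size == 0:
        raise ValueError("no strand flags")
    if not np.isin(flags, (0, 1)).all():
        raise ValueError("strand flags must be 0 or 1")
    return float(100.0 * flags.sum() / flags.size)


def distance_distribution(deviations, bins=DEFAULT_BINS) -> dict[int, float]:
    """Cumulative % of hairpins with |x_i| <= d for each bin d."""
    dev = np.abs(np.asarray(list(deviations), dtype=float))
    if dev.size == 0:
        raise ValueError("no deviations")
    return {int(d): float(100.0 * (dev <= d).sum() / dev.size) for d in bins}


@dataclass
class EvalReport:
    """Aggregate prediction-accuracy report over N pre-miRNAs."""

    n: int
    e_nt: float
    p_percent: float
    bins: dict[int, float]
    deviations: list[int] = field(default_factory=list)
    strand_flags: list[int] = field(default_factory=list)

    @classmethod
    def from_deviations(cls, deviations, strand_flags, bins=DEFAULT_BINS) -> "EvalReport":
        deviations = list(deviations)
        return cls(
            n=len(deviations),
            e_nt=average_deviation(deviations),
            p_percent=strand_accuracy(strand_flags),
            bins=distance_distribution(deviations, bins),
            deviations=[int(d) for d in deviations],
            strand_flags=[int(f) for f in strand_flags],
        )

    def to_frame(self) -> pd.DataFrame:
        row = {f"±{d} nt" if d else "0 nt": v for d, v in self.bins.items()}
        row.update({"E (nt)": self.e_nt, "P (%)": self.p_percent, "N": self.n})
        return pd.DataFrame([row])

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "E_nt": self.e_nt,
                "P_percent": self.p_percent,
                "bins": self.bins,
            }
        )


def score_prediction(
    result, true_starts: list[int], true_arms: list[str]
) -> tuple[int, int]:
    """(signed deviation, functional-strand flag) of a hairpin's top-1.

    When a hairpin carries several mature miRNAs, the deviation is taken
    against the nearest true start on the predicted arm; if no true miRNA
    lies on that arm, the nearest true start overall is used and the strand
    flag is 0.
    """
    top = result.top1
    if top is None:
        raise ValueError(f"{result.premirna_id}: no prediction to score")
    p = top.mirna_start
    same_arm = [a for a, arm in zip(true_starts, true_arms) if arm == top.arm]
    if same_arm:
        a = min(same_arm, key=lambda a: abs(p - a))
        return position_deviation(p, a), 1
    a = min(true_starts, key=lambda a: abs(p - a))
    return position_deviation(p, a), 0


def topk_min_deviation(result, actual_starts: list[int], k: int = 10) -> int:
    """Minimum |p - a| over the top-k candidates and all true starts."""
    if not result.ranked:
        raise ValueError("empty prediction result")
    return min(
        abs(cand.mirna_start - a) for cand, _ in result.topk(k) for a in actual_starts
    )


def ten_fold_cv(
    premirnas: list,
    annotations: dict[str, list[int]],
    train_fn,
    predict_fn,
    n_folds: int = 10,
    n_repeats: int = 1,
    seed: int = 0,
) -> EvalReport:
    """Group-wise k-fold cross-validation of the full pipeline.

    Hairpins (not candidates) are partitioned into folds so that all
    candidates of a hairpin stay together.  ``train_fn(train_premirnas,
    annotations)`` returns a model; ``predict_fn(premirna, model)`` returns
    a PredictionResult.  Deviations are aggregated over all folds and
    repetitions.
    """
    if len(premirnas) < n_folds:
        raise ValueError(f"{n_folds}-fold CV requires >= {n_folds} hairpins")
    rng = np.random.default_rng(seed)
    deviations: list[int] = []
    flags: list[int] = []
    for _ in range(n_repeats):
        order = rng.permutation(len(premirnas))
        folds = [order[i::n_folds] for i in range(n_folds)]
        for fold in folds:
            held = set(int(i) for i in fold)
            train_set = [p for i, p in enumerate(premirnas) if i not in held]
            model = train_fn(train_set, annotations)
            for i in held:
                pre = premirnas[i]
                result = predict_fn(pre, model)
                if not result.ranked:
                    continue
                trues = annotations[pre.id]
                arms = [_arm_of(pre, t) for t in trues]
                d, f = score_prediction(result, trues, arms)
                deviations.append(d)
                flags.append(f)
    return EvalReport.from_deviations(deviations, flags)


def _arm_of(pre, position: int) -> str:
    return "5p" if position < pre.anatomy.terminal_loop[0] else "3p"
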