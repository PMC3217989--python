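"""Two-stage representative negative-sample selection under ~1:89 imbalance.

Nearly every window placement in a hairpin is a pseudo duplex, so negatives
outnumber positives by roughly two orders of magnitude.  Training on all of
them overfits; training on a random subset wastes the informative ones.

Stage 1 condenses each hairpin's negative group by k-NN density: the
density of a sample is the number of neighbours inside the hypersphere
reaching its k-th nearest neighbour, divided by the sphere's volume and the
total negative count.  Densities are computed once per group; the densest
remaining sample is selected and every sample within its k-NN radius is
deleted, until the group is exhausted.  Dense regions therefore contribute
more representatives, and every deleted sample lies within the radius of
some selected one (the coverage invariant).

Stage 2 iteratively mines the negatives that fool the current model: after
training on the selected set, the negative with the greatest prediction
deviation sigma(x) = score(x) - max_y score(p_y) is added per hairpin, until
the top-scored candidate of every hairpin is its real duplex (or its
negatives are exhausted).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import gammaln

logger = logging.getLogger(__name__)


class SampleSelectionError(RuntimeError):
    pass


@dataclass
class SampleGroup:
    """All encoded candidates of one pre-miRNA: negatives plus 1-4 positives."""

    premirna_id: str
    neg_X: np.ndarray              # (n_neg, m)
    neg_ids: list                  # candidate identifiers (e.g. start positions)
    pos_X: np.ndarray              # (n_pos, m)
    pos_ids: list

    def __post_init__(self):
        if len(self.pos_ids) > 4:
            raise SampleSelectionError(
                f"{self.premirna_id}: more than 4 positives in a group"
            )


# ---------------------------------------------------------------------------
# Distances and k-NN density (stage 1)
# ---------------------------------------------------------------------------

def sample_distance(v_x: np.ndarray, v_i: np.ndarray) -> float:
    """Euclidean distance sqrt((v_x - v_i)^T (v_x - v_i))."""
    v_x, v_i = np.asarray(v_x, dtype=float), np.asarray(v_i, dtype=float)
    if v_x.shape != v_i.shape:
        raise ValueError(f"dimension mismatch: {v_x.shape} vs {v_i.shape}")
    d = v_x - v_i
    return float(np.sqrt(d @ d))


def _group_distances(X: np.ndarray) -> np.ndarray:
    return cdist(X, X)


def knn_radius(X: np.ndarray, i: int, k: int, dist: np.ndarray | None = None) -> float:
    """Distance from sample i to its k-th nearest other sample in the group."""
    n = len(X)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the group size {n}")
    if dist is None:
        dist = cdist(X[i: i + 1], X)[0]
    else:
        dist = dist[i]
    others = np.sort(np.delete(dist, i), kind="stable")
    return float(others[k - 1])


def _log_hypersphere_volume(m: int, r: float) -> float:
    """log volume of the m-dimensional ball of radius r (log-space for m ~ 10^3)."""
    if r <= 0:
        return -np.inf
    return (m / 2) * np.log(np.pi) - gammaln(m / 2 + 1) + m * np.log(r)


def knn_log_density(
    X: np.ndarray, i: int, k: int, total_negatives: int, dist: np.ndarray | None = None
) -> float:
    """log of f(v_i, r) = g / (L * V(m, r)); +inf when r = 0 (duplicates).

    g is the number of other group members within the k-NN radius r, L the
    total negative count, V the m-dimensional hypersphere volume.  Within a
    group (fixed k, L, m) the ordering by f equals ordering by descending g
    then ascending r.
    """
    r = knn_radius(X, i, k, dist)
    if r == 0:
        return np.inf
    d = cdist(X[i: i + 1], X)[0] if dist is None else dist[i]
    g = int((np.delete(d, i) <= r).sum())
    return np.log(g) - np.log(total_negatives) - _log_hypersphere_volume(X.shape[1], r)


def knn_density(X: np.ndarray, i: int, k: int, total_negatives: int) -> float:
    """Linear-scale density f(v_i, r); may over/underflow at high dimension."""
    return float(np.exp(knn_log_density(X, i, k, total_negatives)))


def stage1_select(
    groups: list[SampleGroup], k: int = 11
) -> dict[str, list[int]]:
    """Density-based condensation of each group's negatives.

    Returns, per group, the indices (into ``neg_X``) of the selected
    representatives.  Groups with at most k negatives are kept whole
    (degenerate rule).  Densities are computed once per group; ties are
    broken by index order (i.e. smaller candidate start first).
    """
    total = sum(len(g.neg_ids) for g in groups)
    selected: dict[str, list[int]] = {}
    for g in groups:
        n = len(g.neg_ids)
        if n == 0:
            selected[g.premirna_id] = []
            continue
        if n <= k:
            logger.debug("%s: group of %d <= k=%d, keeping all", g.premirna_id, n, k)
            selected[g.premirna_id] = list(range(n))
            continue
        dist = _group_distances(g.neg_X)
        radius = np.empty(n)
        logf = np.empty(n)
        for i in range(n):
            radius[i] = knn_radius(g.neg_X, i, k, dist)
            logf[i] = knn_log_density(g.neg_X, i, k, total, dist)
        remaining = np.ones(n, dtype=bool)
        chosen: list[int] = []
        while remaining.any():
            idx = np.flatnonzero(remaining)
            j = idx[int(np.argmax(logf[idx]))]   # argmax takes the first on ties
            chosen.append(int(j))
            remaining &= dist[j] > radius[j]
            remaining[j] = False
        selected[g.premirna_id] = chosen
    return selected


# ---------------------------------------------------------------------------
# Prediction-deviation mining (stage 2)
# ---------------------------------------------------------------------------

def prediction_deviation(score_neg: float, positive_scores) -> float:
    """sigma(x) = score(x) - max_y score(p_y); > 0 iff x outranks every positive."""
    positive_scores = np.asarray(positive_scores, dtype=float)
    if positive_scores.size == 0:
        raise ValueError("prediction deviation requires at least one positive score")
    return float(score_neg - positive_scores.max())


@dataclass
class SelectionState:
    """Bookkeeping for the stage-2 iteration."""

    selected_neg: dict[str, set]          # group id -> set of selected negative indices
    terminated: dict[str, bool]
    iterations: int = 0
    audit: list[dict] = field(default_factory=list)


def stage2_select(
    groups: list[SampleGroup],
    stage1_selected: dict[str, list[int]],
    trainer,
    max_iter: int = 50,
):
    """Iterative hard-negative mining against a retrained model.

    ``trainer(X, z)`` must return an object with ``decision_function(X)``.
    Per sweep, the model is trained on the current set U (all positives +
    selected negatives), every candidate is scored, and each non-terminated
    group contributes its highest-deviation unselected negative (only when
    sigma > 0).  A group terminates when its top-scored candidate is the
    real duplex or all its negatives are selected.

    Returns ``(state, model)`` where ``state.selected_neg`` defines the
    final training set U and ``model`` is the last trained model.
    """
    state = SelectionState(
        selected_neg={g.premirna_id: set(stage1_selected.get(g.premirna_id, [])) for g in groups},
        terminated={
            g.premirna_id: len(g.neg_ids) == 0 or len(g.pos_ids) == 0 for g in groups
        },
    )
    model = None
    for iteration in range(max_iter):
        X_train, z_train = _training_arrays(groups, state.selected_neg)
        try:
            model = trainer(X_train, z_train)
        except Exception as exc:
            raise SampleSelectionError(
                f"trainer failed at iteration {iteration} "
                f"(U size {len(z_train)}): {exc}"
            ) from exc
        state.iterations = iteration + 1
        any_addition = False
        for g in groups:
            if state.terminated[g.premirna_id]:
                continue
            pos_scores = model.decision_function(g.pos_X)
            neg_scores = model.decision_function(g.neg_X)
            top_is_real = pos_scores.max() >= neg_scores.max()
            if top_is_real:
                state.terminated[g.premirna_id] = True
                continue
            sel = state.selected_neg[g.premirna_id]
            if len(sel) == len(g.neg_ids):
                state.terminated[g.premirna_id] = True
                continue
            sigma = neg_scores - pos_scores.max()
            order = np.argsort(-sigma, kind="stable")
            added = False
            for j in order:
                if sigma[j] <= 0:
                    break
                if int(j) not in sel:
                    sel.add(int(j))
                    state.audit.append(
                        {
                            "iteration": iteration,
                            "group": g.premirna_id,
                            "candidate_id": g.neg_ids[int(j)],
                            "sigma": float(sigma[j]),
                        }
                    )
                    added = any_addition = True
                    break
            if not added and len(sel) == len(g.neg_ids):
                state.terminated[g.premirna_id] = True
        if all(state.terminated.values()):
            break
        if not any_addition:
            # no group could add a sample; a further sweep cannot change U
            break
    return state, model


def _training_arrays(groups: list[SampleGroup], selected_neg: dict[str, set]):
    xs, zs = [], []
    for g in groups:
        if len(g.pos_ids):
            xs.append(g.pos_X)
            zs.append(np.ones(len(g.pos_ids)))
        sel = sorted(selected_neg[g.premirna_id])
        if sel:
            xs.append(g.neg_X[sel])
            zs.append(-np.ones(len(sel)))
    return np.vstack(xs), np.concatenate(zs)


def training_set(groups: list[SampleGroup], state: SelectionState):
    """Final training arrays (X, z) defined by a selection state."""
    return _training_arrays(groups, state.selected_neg)


def write_audit_log(state: SelectionState, path) -> None:
    with open(path, "w") as fh:
        for entry in state.audit:
            fh.write(json.dumps(entry) + "\n")
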