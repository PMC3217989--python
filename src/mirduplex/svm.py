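"""RBF-kernel SVM training, decision-value scoring, grid search, ranking.

The classifier is a standard soft-margin SVM with an RBF kernel
K(u, v) = exp(-gamma ||u - v||^2); the raw decision value
f(x) = sum_i alpha_i z_i K(x_i, x) + b is used directly as the prediction
score of a candidate, and candidates of a hairpin are ranked by it.

Training delegates to scikit-learn's libsvm solver; scoring is recomputed
from the extracted support vectors and coefficients with plain numpy so
that a saved and reloaded model reproduces scores bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel as _sk_rbf
from sklearn.svm import SVC

from .feature_select import FeatureSubset

DEFAULT_C_GRID = tuple(float(2.0 ** e) for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(float(2.0 ** e) for e in range(-15, 4, 2))


def rbf_kernel(u: np.ndarray, v: np.ndarray, gamma: float) -> float:
    """exp(-gamma ||u - v||^2); K(u, u) = 1, symmetric, in (0, 1]."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    u, v = np.asarray(u, dtype=float), np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("dimension mismatch")
    d = u - v
    return float(np.exp(-gamma * (d @ d)))


def kernel_matrix(X: np.ndarray, Y: np.ndarray, gamma: float) -> np.ndarray:
    return _sk_rbf(X, Y, gamma=gamma)


@dataclass
class TrainedModel:
    """Support vectors, dual coefficients alpha_i z_i, bias and kernel params."""

    support_vectors: np.ndarray
    dual_coef: np.ndarray          # alpha_i z_i, |alpha_i| <= C
    bias: float
    gamma: float
    C: float
    subset: FeatureSubset | None = None
    metadata: dict = field(default_factory=dict)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        K = kernel_matrix(X, self.support_vectors, self.gamma)
        return K @ self.dual_coef + self.bias

    # -- persistence: JSON header + support-vector matrix ------------------
    def save(self, path) -> None:
        payload = {
            "gamma": self.gamma,
            "C": self.C,
            "bias": self.bias,
            "dual_coef": self.dual_coef.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "metadata": self.metadata,
            "subset": json.loads(self.subset.to_json()) if self.subset else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            payload = json.load(fh)
        subset = None
        if payload["subset"] is not None:
            subset = FeatureSubset.from_json(json.dumps(payload["subset"]))
        return cls(
            support_vectors=np.array(payload["support_vectors"], dtype=float),
            dual_coef=np.array(payload["dual_coef"], dtype=float),
            bias=float(payload["bias"]),
            gamma=float(payload["gamma"]),
            C=float(payload["C"]),
            subset=subset,
            metadata=payload["metadata"],
        )


def train(
    X: np.ndarray,
    z: np.ndarray,
    C: float = 1.0,
    gamma: float = "scale",
    subset: FeatureSubset | None = None,
    metadata: dict | None = None,
    tol: float = 1e-3,
) -> TrainedModel:
    """Fit the soft-margin RBF SVM; z must contain both classes (+1/-1)."""
    z = np.asarray(z)
    if len(np.unique(z)) < 2:
        raise ValueError("training requires at least one sample of each class")
    svc = SVC(C=C, kernel="rbf", gamma=gamma, tol=tol)
    svc.fit(np.asarray(X, dtype=float), z)
    # sklearn orders classes ascending: dual_coef_ weights the second class
    # (+1) positively, matching sum alpha_i z_i K(x_i, x) + b directly
    return TrainedModel(
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        gamma=float(svc._gamma),
        C=float(C),
        subset=subset,
        metadata=metadata or {},
    )


# ---------------------------------------------------------------------------
# Grid search (group-aware CV on top-1 position accuracy)
# ---------------------------------------------------------------------------

def _group_folds(group_ids: list, n_folds: int, seed: int) -> list[set]:
    uniq = sorted(set(group_ids), key=str)
    if n_folds > len(uniq):
        raise ValueError(f"{n_folds} folds requested but only {len(uniq)} groups")
    rng = np.random.default_rng(seed)
    rng.shuffle(uniq)
    return [set(uniq[i::n_folds]) for i in range(n_folds)]


def grid_search(
    X: np.ndarray,
    z: np.ndarray,
    group_ids: list,
    starts: np.ndarray,
    C_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    n_folds: int = 3,
    seed: int = 0,
) -> tuple[float, float]:
    """Exhaustive (C, gamma) search by cross-validated top-1 position accuracy.

    Folds keep all candidates of a pre-miRNA together.  The metric is the
    fraction of held-out hairpins whose top-scored candidate is a real
    duplex (ranking ties broken by smaller start).  Grid ties go to the
    smaller C, then the smaller gamma.
    """
    if not len(C_grid) or not len(gamma_grid):
        raise ValueError("grids must be nonempty")
    X = np.asarray(X, dtype=float)
    z = np.asarray(z)
    starts = np.asarray(starts)
    gids = np.asarray(group_ids, dtype=object)
    folds = _group_folds(group_ids, n_folds, seed)

    best = None
    for C in sorted(set(float(c) for c in C_grid)):
        for gamma in sorted(set(float(g) for g in gamma_grid)):
            hits = total = 0
            for held in folds:
                test_mask = np.array([g in held for g in gids])
                if test_mask.all() or not test_mask.any():
                    continue
                try:
                    model = train(X[~test_mask], z[~test_mask], C=C, gamma=gamma)
                except ValueError:
                    continue
                scores = model.decision_function(X[test_mask])
                t_gids, t_starts, t_z = gids[test_mask], starts[test_mask], z[test_mask]
                for gid in set(t_gids):
                    gm = t_gids == gid
                    if not (t_z[gm] == 1).any():
                        continue
                    order = np.lexsort((t_starts[gm], -scores[gm]))
                    hits += int(t_z[gm][order[0]] == 1)
                    total += 1
            acc = hits / total if total else 0.0
            key = (acc, -C, -gamma)
            if best is None or key > best[0]:
                best = (key, (C, gamma))
    return best[1]


# ---------------------------------------------------------------------------
# Per-hairpin candidate ranking
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    """Ranked candidates of one hairpin with scores (non-increasing)."""

    premirna_id: str
    ranked: list          # list of (DuplexCandidate, score), score descending
    reason: str | None = None   # set when no candidate survived

    @property
    def top1(self):
        return self.ranked[0][0] if self.ranked else None

    def per_arm_best(self) -> dict:
        out = {}
        for cand, score in self.ranked:
            if cand.arm not in out:
                out[cand.arm] = (cand, score)
        return out

    def topk(self, k: int = 10) -> list:
        return self.ranked[:k]


def rank_candidates(premirna_id: str, cands: list, scores: np.ndarray) -> PredictionResult:
    """Sort candidates by score descending, ties broken by smaller start."""
    order = sorted(range(len(cands)), key=lambda i: (-scores[i], cands[i].mirna_start))
    return PredictionResult(
        premirna_id=premirna_id,
        ranked=[(cands[i], float(scores[i])) for i in order],
    )


def predict_premirna(pre, model: TrainedModel, cfg=None, backend=None, thresholds=None):
    """Enumerate, filter, featurize, encode and score all candidates of a hairpin."""
    from .candidates import FilterThresholds, enumerate_candidates, filter_candidates
    from .feature_select import encode_numeric
    from .features import FeatureConfig, extract_features
    from .hairpin import default_backend

    cfg = cfg or FeatureConfig()
    backend = backend or default_backend()
    thresholds = thresholds or FilterThresholds()
    cands = enumerate_candidates(pre, cfg.window_len)
    cands = filter_candidates(cands, pre.anatomy, thresholds)
    if not cands:
        return PredictionResult(premirna_id=pre.id, ranked=[], reason="no surviving candidate")
    X = np.vstack([
        encode_numeric(extract_features(c, pre, cfg, backend), model.subset) for c in cands
    ])
    return rank_candidates(pre.id, cands, model.decision_function(X))
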