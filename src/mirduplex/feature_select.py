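"""Information-gain feature ranking, subset composition, numeric encoding.

The discriminative value of each feature is measured as the information
gain IG(c, x) = H(c) - H(c | x) in bits, where c is the real/pseudo class.
Continuous features (dis, MFE_1..3, triplet frequencies) are discretized
with equal-frequency binning for the IG computation only.

Subset composition mirrors the published model family: all positional
features at the configured flank size, all six stability/distance/energy
features, and the triplet features passing a per-arm information-gain
threshold (lambda_1 on hairpins whose miRNA lies on the 5' arm, lambda_2 on
3'-arm hairpins, union of survivors).  The default plant policy yields an
86-name subset: 66 positional (6-nt flanks) + 14 triplet survivors + 6.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .features import (
    POSITION_ALPHABET,
    S4_NAMES,
    positional_feature_names,
    triplet_feature_names,
)

META_COLUMNS = ("premirna_id", "mirna_start", "arm", "label")


# ---------------------------------------------------------------------------
# Entropy and information gain
# ---------------------------------------------------------------------------

def shannon_entropy(values) -> float:
    """Shannon entropy in bits of a discrete column; 0 for a constant column."""
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("entropy of an empty column is undefined")
    _, counts = np.unique(values, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def discretize(values, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency binning for continuous columns; discrete columns pass through.

    A column is treated as continuous when it is float-typed with more
    distinct values than bins.
    """
    arr = np.asarray(values)
    if arr.dtype.kind not in "fc":
        return arr
    uniq = np.unique(arr)
    if uniq.size <= n_bins:
        return arr
    edges = np.quantile(arr, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, arr, side="right")


def information_gain(feature_col, class_col, n_bins: int = 10) -> float:
    """IG(c, x) = H(c) - H(c | x), in bits (always >= 0 up to rounding)."""
    x = discretize(feature_col, n_bins)
    c = np.asarray(class_col)
    if len(x) != len(c):
        raise ValueError("feature and class columns differ in length")
    h_c = shannon_entropy(c)
    h_c_given_x = 0.0
    n = len(c)
    for value in np.unique(x):
        mask = x == value
        h_c_given_x += mask.sum() / n * shannon_entropy(c[mask])
    return max(0.0, h_c - h_c_given_x)


# ---------------------------------------------------------------------------
# Subset composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubsetPolicy:
    """Which feature families enter the model and how triplets are chosen.

    ``triplet_mode``: 'none' (no triplet features), 'all' (all 64), or
    'lambda_top' (per-arm IG thresholds lambda_1/lambda_2, survivors ranked
    by pooled IG and padded/truncated to ``n_triplet`` names).
    """

    include_mirna_pos: bool = True
    include_star_pos: bool = True
    flank_len: int = 6
    include_s4: bool = True
    triplet_mode: str = "lambda_top"
    lambda_1: float = 0.0239
    lambda_2: float = 0.0289
    n_triplet: int = 14
    provenance: str = "custom"

    @classmethod
    def plant_default(cls) -> "SubsetPolicy":
        """The shipped 86-feature plant policy (66 positional + 14 triplet + 6)."""
        return cls(provenance="default-plant-86")

    @classmethod
    def calibration(cls, size: int) -> "SubsetPolicy":
        """The 27/48/72/136-feature calibration policies."""
        table = {
            27: cls(include_star_pos=False, flank_len=0, triplet_mode="none", provenance="cal-27"),
            48: cls(flank_len=0, triplet_mode="none", provenance="cal-48"),
            72: cls(flank_len=6, triplet_mode="none", provenance="cal-72"),
            136: cls(flank_len=6, triplet_mode="all", provenance="cal-136"),
        }
        return table[size]


@dataclass
class FeatureSubset:
    """An ordered selection of feature names with IG scores and scaling."""

    names: list[str]
    ig: dict[str, float] = field(default_factory=dict)
    ig_5p: dict[str, float] = field(default_factory=dict)
    ig_3p: dict[str, float] = field(default_factory=dict)
    lambda_1: float | None = None
    lambda_2: float | None = None
    provenance: str = "custom"
    categorical: list[str] = field(default_factory=list)
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def dimension(self) -> int:
        n_cat = len(set(self.names) & set(self.categorical))
        return n_cat * len(POSITION_ALPHABET) + (len(self.names) - n_cat)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FeatureSubset":
        d = json.loads(text)
        d["scaling"] = {k: tuple(v) for k, v in d["scaling"].items()}
        return cls(**d)


def _class_column(table: pd.DataFrame) -> np.ndarray:
    return np.where(table["label"].to_numpy() == "real", 1, -1)


def functional_arm_by_group(table: pd.DataFrame) -> dict[str, str]:
    """Arm carrying the (first) real duplex of each pre-miRNA group."""
    out: dict[str, str] = {}
    for rid, sub in table.groupby("premirna_id", sort=False):
        real = sub[sub["label"] == "real"]
        out[rid] = real["arm"].iloc[0] if len(real) else "5p"
    return out


def ig_table(table: pd.DataFrame, feature_names: list[str], n_bins: int = 10) -> pd.DataFrame:
    """Per-feature IG on the pooled data and on the 5'/3'-arm partitions."""
    c = _class_column(table)
    arm_of = functional_arm_by_group(table)
    arm = table["premirna_id"].map(arm_of).to_numpy()
    rows = []
    for name in feature_names:
        col = table[name].to_numpy()
        rows.append(
            {
                "feature": name,
                "IG_all": information_gain(col, c, n_bins),
                "IG_5parm": information_gain(col[arm == "5p"], c[arm == "5p"], n_bins)
                if (arm == "5p").any() else 0.0,
                "IG_3parm": information_gain(col[arm == "3p"], c[arm == "3p"], n_bins)
                if (arm == "3p").any() else 0.0,
            }
        )
    return pd.DataFrame(rows)


def compose_subset(
    table: pd.DataFrame,
    policy: SubsetPolicy = SubsetPolicy.plant_default(),
    window_len: int = 21,
) -> FeatureSubset:
    """Select the modelled feature names from a full-inventory feature table."""
    names: list[str] = []
    if policy.include_mirna_pos:
        names += [f"miRNA_{i}" for i in range(1, window_len + 1)]
    if policy.include_star_pos:
        names += [f"miRNA*_{i}" for i in range(1, window_len + 1)]
    strands = ["miRNA"] + (["miRNA*"] if policy.include_star_pos else [])
    for strand in strands:
        for j in range(1, policy.flank_len + 1):
            names += [f"bef_{strand}_{j}", f"aft_{strand}_{j}"]

    triplet_names = triplet_feature_names()
    ig = ig_5p = ig_3p = {}
    if policy.triplet_mode == "all":
        names += triplet_names
    elif policy.triplet_mode == "lambda_top":
        igt = ig_table(table, triplet_names)
        ig = dict(zip(igt["feature"], igt["IG_all"]))
        ig_5p = dict(zip(igt["feature"], igt["IG_5parm"]))
        ig_3p = dict(zip(igt["feature"], igt["IG_3parm"]))
        survivors = [
            f for f in triplet_names
            if ig_5p[f] > policy.lambda_1 or ig_3p[f] > policy.lambda_2
        ]
        ranked = sorted(survivors, key=lambda f: (-ig[f], f))
        if len(ranked) < policy.n_triplet:
            rest = sorted(
                (f for f in triplet_names if f not in survivors),
                key=lambda f: (-ig[f], f),
            )
            ranked += rest[: policy.n_triplet - len(ranked)]
        names += sorted(ranked[: policy.n_triplet], key=triplet_names.index)
    elif policy.triplet_mode != "none":
        raise ValueError(f"unknown triplet_mode {policy.triplet_mode!r}")

    if policy.include_s4:
        names += list(S4_NAMES)

    missing = [n for n in names if n not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks required columns: {missing[:5]} ...")

    categorical = [n for n in names if n in categorical_names(window_len)]
    return FeatureSubset(
        names=names,
        ig=ig,
        ig_5p=ig_5p,
        ig_3p=ig_3p,
        lambda_1=policy.lambda_1 if policy.triplet_mode == "lambda_top" else None,
        lambda_2=policy.lambda_2 if policy.triplet_mode == "lambda_top" else None,
        provenance=policy.provenance,
        categorical=categorical,
    )


def categorical_names(window_len: int = 21) -> set[str]:
    return set(positional_feature_names(window_len, 12))


# ---------------------------------------------------------------------------
# Numeric encoding
# ---------------------------------------------------------------------------

_SYMBOL_INDEX = {s: i for i, s in enumerate(POSITION_ALPHABET)}


def fit_scaling(table: pd.DataFrame, subset: FeatureSubset) -> FeatureSubset:
    """Store training-set min/max for the numeric features (scaled to [-1, 1])."""
    cat = set(subset.categorical)
    for name in subset.names:
        if name in cat:
            continue
        col = table[name].to_numpy(dtype=float)
        subset.scaling[name] = (float(col.min()), float(col.max()))
    return subset


def encode_numeric(features, subset: FeatureSubset) -> np.ndarray:
    """Encode one feature map (or a table) into the SVM input vector(s).

    Categorical position symbols become one-hot over the 10-symbol
    alphabet; numeric features are linearly scaled to [-1, 1] using the
    stored training min/max.  Deterministic; the dimension is fixed by the
    subset (e.g. 66*10 + 14 + 6 = 680 for the default plant subset).
    """
    if isinstance(features, pd.DataFrame):
        return np.vstack([
            encode_numeric(row, subset) for row in features.to_dict("records")
        ])
    cat = set(subset.categorical)
    parts: list[np.ndarray] = []
    for name in subset.names:
        if name not in features:
            raise KeyError(f"feature vector lacks {name!r}")
        value = features[name]
        if name in cat:
            onehot = np.zeros(len(POSITION_ALPHABET))
            try:
                onehot[_SYMBOL_INDEX[value]] = 1.0
            except KeyError:
                raise ValueError(f"unseen position symbol {value!r} for {name!r}") from None
            parts.append(onehot)
        else:
            lo, hi = subset.scaling.get(name, (0.0, 0.0))
            x = float(value)
            scaled = 0.0 if hi == lo else 2.0 * (x - lo) / (hi - lo) - 1.0
            parts.append(np.array([scaled]))
    return np.concatenate(parts)


def write_ig_report(igt: pd.DataFrame, selected: list[str], path_or_buf) -> None:
    out = igt.copy()
    out["selected"] = out["feature"].isin(set(selected))
    out.to_csv(path_or_buf, sep="\t", index=False)
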