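"""Somatic scoring with a glass-box cyclic additive boosting classifier.

Candidates are described by window-level (percent high-quality reads per
sample), variant-level (type, length, depth, absolute tumor/normal VAF
difference) and allele-level (allele counts, strand bias, base quality,
mapping quality) features.  Training under-samples the overwhelming
non-somatic majority class, then fits one binned shape function per feature
by cyclic gradient boosting with depth-1 splits, so every probability
decomposes exactly into an intercept plus per-feature contributions.
Default PASS thresholds: probability >= 0.90 for substitutions and >= 0.95
for insertions/deletions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .realign_genotype import AlleleSupport

__all__ = [
    "FEATURE_NAMES",
    "DEFAULT_THRESHOLDS",
    "EbmModel",
    "extract_features",
    "undersample",
    "train",
    "score",
    "explain",
    "apply_threshold",
]

FEATURE_NAMES = [
    "pct_hq_reads_tumor",
    "pct_hq_reads_normal",
    "vtype_code",
    "length",
    "depth_tumor",
    "depth_normal",
    "abs_vaf_diff",
    "alt_count_tumor",
    "alt_count_normal",
    "ref_count_tumor",
    "ref_count_normal",
    "strand_bias_tumor",
    "strand_bias_normal",
    "mean_alt_baseq_tumor",
    "mean_alt_mapq_tumor",
    "mean_alt_baseq_normal",
    "mean_alt_mapq_normal",
]

VTYPE_CODES = {"SNV": 0, "INS": 1, "DEL": 2, "MNV": 3}

DEFAULT_THRESHOLDS = {"SNV": 0.90, "MNV": 0.90, "INS": 0.95, "DEL": 0.95}


def _strand_bias(fwd: int, rev: int) -> float:
    total = fwd + rev
    return min(fwd, rev) / total if total else 0.0


def _mean(values) -> float:
    return float(np.mean(values)) if len(values) else 0.0


def extract_features(variant, support: AlleleSupport, window_stats: dict) -> np.ndarray:
    """Deterministic feature vector in FEATURE_NAMES order.

    ``window_stats`` carries pct_hq_reads_tumor/_normal for the window the
    variant came from.  Zero-denominator VAFs are 0 by convention; strand
    bias is min(fwd, rev)/(fwd+rev) on alt reads (0.5 = balanced, 0 = none).
    """
    t, n = support.tumor, support.normal
    return np.array(
        [
            window_stats.get("pct_hq_reads_tumor", 0.0),
            window_stats.get("pct_hq_reads_normal", 0.0),
            VTYPE_CODES[variant.vtype],
            variant.length,
            t.depth,
            n.depth,
            abs(t.vaf - n.vaf),
            t.alt_count,
            n.alt_count,
            t.ref_count,
            n.ref_count,
            _strand_bias(t.alt_fwd, t.alt_rev),
            _strand_bias(n.alt_fwd, n.alt_rev),
            _mean(t.alt_base_quals),
            _mean(t.alt_map_quals),
            _mean(n.alt_base_quals),
            _mean(n.alt_map_quals),
        ],
        dtype=float,
    )


def undersample(labels: np.ndarray, neg_per_pos: int = 30, seed: int = 0) -> np.ndarray:
    """Indices keeping all positives and at most neg_per_pos negatives each.

    Negatives are drawn uniformly without replacement; deterministic per
    seed.  Returned indices are sorted.
    """
    if neg_per_pos < 1:
        raise ValueError("neg_per_pos must be >= 1")
    labels = np.asarray(labels).astype(bool)
    pos = np.nonzero(labels)[0]
    neg = np.nonzero(~labels)[0]
    if len(pos) == 0:
        raise ValueError("no positive examples to anchor under-sampling")
    target = min(len(neg), neg_per_pos * len(pos))
    rng = np.random.default_rng(seed)
    keep_neg = rng.choice(neg, size=target, replace=False)
    return np.sort(np.concatenate([pos, keep_neg]))


# ---------------------------------------------------------------------------
# model


@dataclass
class EbmModel:
    """Additive logistic model: score = sigmoid(intercept + sum shape_f(x_f))."""

    intercept: float
    feature_names: list[str]
    bin_edges: list[np.ndarray]  # per feature, interior edges
    shapes: list[np.ndarray]  # per feature, len(edges)+1 additive values
    thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    metadata: dict = field(default_factory=dict)

    def bin_index(self, f: int, value: float) -> int:
        return int(np.searchsorted(self.bin_edges[f], value, side="right"))

    def to_dict(self) -> dict:
        return {
            "intercept": float(self.intercept),
            "feature_names": list(self.feature_names),
            "bin_edges": [e.tolist() for e in self.bin_edges],
            "shapes": [s.tolist() for s in self.shapes],
            "thresholds": {k: float(v) for k, v in self.thresholds.items()},
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EbmModel":
        return cls(
            intercept=float(d["intercept"]),
            feature_names=list(d["feature_names"]),
            bin_edges=[np.asarray(e, dtype=float) for e in d["bin_edges"]],
            shapes=[np.asarray(s, dtype=float) for s in d["shapes"]],
            thresholds=dict(d.get("thresholds", DEFAULT_THRESHOLDS)),
            metadata=dict(d.get("metadata", {})),
        )


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _log_loss(y, p):
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _quantile_edges(x: np.ndarray, max_bins: int) -> np.ndarray:
    qs = np.linspace(0, 1, max_bins + 1)[1:-1]
    edges = np.unique(np.quantile(x, qs))
    # interior edges only: a constant feature gets no bins and stays flat
    edges = edges[(edges > x.min()) & (edges < x.max())]
    return edges.astype(float)


def train(
    features: np.ndarray,
    labels: np.ndarray,
    rounds: int = 500,
    learning_rate: float = 0.1,
    max_bins: int = 64,
    seed: int = 0,
    feature_names: list[str] | None = None,
    thresholds: dict[str, float] | None = None,
    loss_history: list | None = None,
) -> EbmModel:
    """Cyclic additive boosting on quantile-binned features.

    Each round visits the features in fixed order and fits a single
    depth-1 split (Newton leaf values on the logistic-loss gradient),
    adding the learning-rate-scaled update into that feature's shape.  An
    update that would increase the training loss is skipped, so the loss
    history is non-increasing.  Shapes are centered to mean zero over the
    training data, with the offsets folded into the intercept.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features/labels shape mismatch")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels are degenerate (single class)")
    n, nf = X.shape
    if feature_names is None:
        feature_names = FEATURE_NAMES if nf == len(FEATURE_NAMES) else [f"f{i}" for i in range(nf)]

    edges = [_quantile_edges(X[:, f], max_bins) for f in range(nf)]
    bins = [np.searchsorted(edges[f], X[:, f], side="right") for f in range(nf)]
    n_bins = [len(edges[f]) + 1 for f in range(nf)]
    shapes = [np.zeros(nb) for nb in n_bins]

    base = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    intercept = float(np.log(base / (1 - base)))
    margin = np.full(n, intercept)
    loss = _log_loss(y, _sigmoid(margin))
    if loss_history is not None:
        loss_history.append(loss)

    lam = 1e-3
    for _ in range(rounds):
        for f in range(nf):
            nb = n_bins[f]
            if nb < 2:
                continue
            p = _sigmoid(margin)
            grad = y - p
            hess = p * (1 - p)
            g = np.bincount(bins[f], weights=grad, minlength=nb)
            h = np.bincount(bins[f], weights=hess, minlength=nb)
            gc = np.cumsum(g)
            hc = np.cumsum(h)
            gl, hl = gc[:-1], hc[:-1]
            gr, hr = gc[-1] - gl, hc[-1] - hl
            gain = gl**2 / (hl + lam) + gr**2 / (hr + lam)
            s = int(np.argmax(gain))
            update = np.empty(nb)
            update[: s + 1] = gl[s] / (hl[s] + lam)
            update[s + 1 :] = gr[s] / (hr[s] + lam)
            update *= learning_rate
            new_margin = margin + update[bins[f]]
            new_loss = _log_loss(y, _sigmoid(new_margin))
            if new_loss <= loss:
                shapes[f] += update
                margin = new_margin
                loss = new_loss
        if loss_history is not None:
            loss_history.append(loss)

    # center shapes over the training distribution
    for f in range(nf):
        counts = np.bincount(bins[f], minlength=n_bins[f])
        mean = float(np.average(shapes[f], weights=np.maximum(counts, 0) + 1e-12))
        shapes[f] -= mean
        intercept += mean

    return EbmModel(
        intercept=intercept,
        feature_names=list(feature_names),
        bin_edges=edges,
        shapes=shapes,
        thresholds=dict(thresholds or DEFAULT_THRESHOLDS),
        metadata={"rounds": rounds, "learning_rate": learning_rate,
                  "max_bins": max_bins, "seed": seed, "n_train": int(n)},
    )


def _contributions(model: EbmModel, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[0] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features, got {x.shape[0]}"
        )
    return np.array(
        [model.shapes[f][model.bin_index(f, x[f])] for f in range(len(model.feature_names))]
    )


def score(model: EbmModel, feature_vector: np.ndarray) -> float:
    """Somatic probability in [0, 1]."""
    z = model.intercept + _contributions(model, feature_vector).sum()
    return float(_sigmoid(z))


def explain(model: EbmModel, feature_vector: np.ndarray) -> dict:
    """Exact additive explanation: intercept + sum(contributions) = logit(p)."""
    contrib = _contributions(model, feature_vector)
    return {
        "intercept": model.intercept,
        "contributions": dict(zip(model.feature_names, contrib.tolist())),
        "logit": float(model.intercept + contrib.sum()),
        "probability": float(_sigmoid(model.intercept + contrib.sum())),
    }


def apply_threshold(probability: float, vtype: str, thresholds: dict[str, float] | None = None) -> str:
    """PASS/LowScore by the type-specific probability cutoff (inclusive)."""
    if not 0.0 <= probability <= 1.0:
        raise ValueError("probability outside [0, 1]")
    cut = (thresholds or DEFAULT_THRESHOLDS)[vtype]
    return "PASS" if probability >= cut else "LowScore"
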