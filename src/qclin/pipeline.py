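"""Dataset handling, preprocessing, cross-validated evaluation, synthesis.

The evaluation protocol: repeated stratified 80/20 train-validation splits
(ten by default).  Within each fold, correlation-based redundancy reduction
and univariate feature ranking are fitted on the training rows only, the
chosen classifier is trained, and the validation AUC is computed from
continuous decision scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classifiers import (
    Backend,
    LabeledDataset,
    QKSVMReference,
    qdc_scores,
    sqksvm_alpha,
    sqksvm_decision,
)
from .encoding import get_encoder
from .inner_product import DEFAULT_SHOTS, KernelMatrix

__all__ = [
    "CVConfig",
    "EvaluationReport",
    "load_csv",
    "reduce_redundancy",
    "rank_and_select",
    "point_biserial_scores",
    "auc",
    "imbalance_ratio",
    "gcq_score",
    "generate_two_class",
    "cross_validate",
    "linear_kernel_matrix",
]

CLASSIFIERS = ("qdc", "sqksvm", "qksvm-ref")


# ---------------------------------------------------------------------------
# I/O

def load_csv(path, label_column: str = "label") -> LabeledDataset:
    """Read a two-class tabular CSV (header required) into a LabeledDataset."""
    df = pd.read_csv(path, float_precision="round_trip")
    if label_column not in df.columns:
        raise ValueError(
            f"label column {label_column!r} not found in {list(df.columns)}"
        )
    labels = df[label_column].to_numpy()
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(
            f"label column {label_column!r} must hold exactly two distinct "
            f"values, found {np.asarray(uniq).tolist()!r}"
        )
    feats = df.drop(columns=[label_column])
    bad = [c for c in feats.columns if not pd.api.types.is_numeric_dtype(feats[c])]
    if bad:
        raise ValueError(f"non-numeric feature columns: {bad!r}")
    if feats.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    return LabeledDataset(
        feats.to_numpy(dtype=float), labels, [str(c) for c in feats.columns]
    )


def save_csv(data: LabeledDataset, path, label_column: str = "label") -> None:
    df = pd.DataFrame(data.features, columns=data.feature_names)
    df[label_column] = data.labels
    # %.17g keeps doubles exact so write/read round-trips bit-identically
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Preprocessing

def reduce_redundancy(data: LabeledDataset, threshold: float = 0.9) -> LabeledDataset:
    """Drop the later member of any feature pair correlated beyond threshold.

    Constant columns (undefined correlation) are dropped first with a
    warning.  The scan is greedy in column order, so the result is
    deterministic: a column is kept iff its absolute Pearson correlation with
    every previously kept column is <= threshold.
    """
    kept = redundancy_kept_columns(data.features, threshold)
    return data.select_features(kept)


def redundancy_kept_columns(X, threshold: float = 0.9) -> list[int]:
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    X = np.asarray(X, dtype=float)
    stds = X.std(axis=0)
    candidates = [j for j in range(X.shape[1]) if stds[j] > 0.0]
    if len(candidates) < X.shape[1]:
        dropped = sorted(set(range(X.shape[1])) - set(candidates))
        warnings.warn(f"dropping constant feature columns {dropped}", stacklevel=3)
    kept: list[int] = []
    for j in candidates:
        redundant = False
        for i in kept:
            r = np.corrcoef(X[:, i], X[:, j])[0, 1]
            if abs(r) > threshold:
                redundant = True
                break
        if not redundant:
            kept.append(j)
    return kept


def point_biserial_scores(X, labels) -> np.ndarray:
    """Absolute point-biserial correlation of each feature with the label."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    uniq = pd.unique(y)
    if len(uniq) != 2:
        raise ValueError("feature ranking needs exactly two classes")
    yb = (y == uniq[1]).astype(float)
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        if col.std() == 0.0:
            continue  # constant feature carries no signal
        scores[j] = abs(stats.pointbiserialr(yb, col).correlation)
    return scores


def rank_and_select(X, labels, k: int, scorer=None) -> list[int]:
    """Indices of the top-k features by univariate class separation.

    ``scorer(X, labels) -> scores`` is pluggable; the default is absolute
    point-biserial correlation.  Returned in rank order (best first); ties
    break toward the lower column index.
    """
    X = np.asarray(X, dtype=float)
    if k > X.shape[1]:
        raise ValueError(
            f"requested {k} features but only {X.shape[1]} are available"
        )
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = (scorer or point_biserial_scores)(X, labels)
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    return [int(j) for j in order[:k]]


# ---------------------------------------------------------------------------
# Metrics

def auc(scores, labels, positive=None) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 0.5."""
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    uniq = pd.unique(y)
    if len(uniq) != 2:
        raise ValueError("AUC needs exactly two classes in the labels")
    if positive is None:
        positive = uniq[1]
    pos = y == positive
    n1 = int(pos.sum())
    n0 = s.size - n1
    ranks = stats.rankdata(s)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def imbalance_ratio(labels) -> float:
    """Minority-class count over total sample count, in (0, 0.5]."""
    y = np.asarray(labels)
    uniq = pd.unique(y)
    if len(uniq) != 2:
        raise ValueError("imbalance ratio needs exactly two classes")
    counts = [int(np.sum(y == c)) for c in uniq]
    return min(counts) / y.shape[0]


def linear_kernel_matrix(X) -> KernelMatrix:
    """Classical linear Gram matrix, for the kernel-geometry comparison."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ids = list(range(X.shape[0]))
    return KernelMatrix(X @ X.T, ids, ids)


def gcq_score(
    K_classical, K_quantum, reg: float = 1e-8
) -> float:
    """Geometric-difference score between a quantum and a classical kernel.

    Both kernels are trace-normalised to ``tr(K) = M``; the score is
    ``sqrt(|| sqrt(K_Q) K_C^{-1} sqrt(K_Q) ||_inf)`` with the classical
    kernel's eigenvalues floored at ``reg`` before inversion.  Experimental:
    absolute values depend on the regularisation choice.
    """
    KC = np.asarray(
        K_classical.entries if isinstance(K_classical, KernelMatrix) else K_classical,
        dtype=float,
    )
    KQ = np.asarray(
        K_quantum.entries if isinstance(K_quantum, KernelMatrix) else K_quantum,
        dtype=float,
    )
    if KC.shape != KQ.shape or KC.ndim != 2 or KC.shape[0] != KC.shape[1]:
        raise ValueError("kernels must be square matrices of the same size")
    m = KC.shape[0]
    KC = 0.5 * (KC + KC.T) * (m / np.trace(KC))
    KQ = 0.5 * (KQ + KQ.T) * (m / np.trace(KQ))
    wq, vq = np.linalg.eigh(KQ)
    sqrt_kq = (vq * np.sqrt(np.clip(wq, 0.0, None))) @ vq.T
    wc, vc = np.linalg.eigh(KC)
    inv_kc = (vc * (1.0 / np.maximum(wc, reg))) @ vc.T
    S = sqrt_kq @ inv_kc @ sqrt_kq
    spectral_norm = float(np.linalg.eigvalsh(0.5 * (S + S.T)).max())
    return float(np.sqrt(spectral_norm))


# ---------------------------------------------------------------------------
# Synthetic data

def generate_two_class(
    M: int,
    N: int,
    separation: float,
    IR: float = 0.5,
    seed: int = 0,
    correlation: float = 0.0,
) -> LabeledDataset:
    """Two Gaussian clusters with controlled separation and imbalance.

    Cluster means sit along two random *orthogonal* unit directions at radius
    ``separation`` (in units of the within-class standard deviation), rather
    than at antipodal points — the squared-overlap kernel cannot tell
    antipodal clusters apart, so opposite means would make kernel classifiers
    blind by construction.  The minority class (label 1) holds
    ``round(IR * M)`` samples.  ``correlation`` adds uniform pairwise feature
    correlation via an equicorrelated covariance.
    """
    if M < 4 or N < 2:
        raise ValueError("need M >= 4 samples and N >= 2 features")
    if not 0.0 < IR <= 0.5:
        raise ValueError(f"imbalance ratio must be in (0, 0.5], got {IR}")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if not 0.0 <= correlation < 1.0:
        raise ValueError("correlation must be in [0, 1)")
    n_min = int(round(IR * M))
    if n_min < 1 or M - n_min < 1:
        raise ValueError(f"IR={IR} infeasible for M={M}")
    rng = np.random.default_rng(seed)
    d1 = rng.standard_normal(N)
    d1 /= np.linalg.norm(d1)
    d2 = rng.standard_normal(N)
    d2 -= (d2 @ d1) * d1
    d2 /= np.linalg.norm(d2)
    cov = (1.0 - correlation) * np.eye(N) + correlation * np.ones((N, N))
    chol = np.linalg.cholesky(cov)
    X = rng.standard_normal((M, N)) @ chol.T
    y = np.zeros(M, dtype=int)
    y[:n_min] = 1
    X[:n_min] += separation * d1
    X[n_min:] += separation * d2
    perm = rng.permutation(M)
    return LabeledDataset(X[perm], y[perm])


# ---------------------------------------------------------------------------
# Cross-validated evaluation

@dataclass(frozen=True)
class CVConfig:
    """Evaluation protocol: repeated stratified Monte-Carlo 80/20 splits."""

    n_folds: int = 10
    train_fraction: float = 0.8
    n_features: int | None = None  # None = use all surviving features
    corr_threshold: float = 0.9
    seed: int = 0
    backend: str = "exact"  # "exact" | "shots"
    shots: int = DEFAULT_SHOTS
    lam: float = 0.0
    kernel_method: str = "swap"  # "swap" | "hadamard2"
    svm_C: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class EvaluationReport:
    classifier: str
    encoding: str
    n_features: int
    fold_aucs: list[float]
    imbalance: float
    gcq: float | None = None
    config: dict = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "encoding": self.encoding,
            "n_features": self.n_features,
            "fold_aucs": [round(a, 12) for a in self.fold_aucs],
            "mean_auc": round(self.mean_auc, 12),
            "imbalance_ratio": round(self.imbalance, 12),
            "gcq": None if self.gcq is None else round(self.gcq, 12),
            "config": self.config,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _stratified_splits(labels, cfg: CVConfig):
    from sklearn.model_selection import StratifiedShuffleSplit

    splitter = StratifiedShuffleSplit(
        n_splits=cfg.n_folds,
        train_size=cfg.train_fraction,
        random_state=cfg.seed,
    )
    dummy = np.zeros(len(labels))
    yield from splitter.split(dummy.reshape(-1, 1), labels)


def _fold_scores(
    train: LabeledDataset,
    val: LabeledDataset,
    classifier: str,
    encoder,
    backend: Backend,
    cfg: CVConfig,
    positive_class,
):
    """Continuous decision scores (higher = positive class) for one fold."""
    if classifier == "qdc":
        # pre-encode the training set once; qdc_scores would rebuild the
        # train circuits for every validation sample
        train_circuits = [encoder.circuit(x) for x in train.features]
        mask_p = train.class_mask(positive_class)
        scores = []
        for x in val.features:
            v = encoder.circuit(x)
            d = np.array(
                [1.0 - backend.overlap(c, v, test="hadamard") for c in train_circuits]
            )
            scores.append(d[~mask_p].min() - d[mask_p].min())
        return np.asarray(scores)
    y_signed = train.signed_labels(positive_class=positive_class)
    if classifier == "sqksvm":
        ir = imbalance_ratio(train.labels)
        alpha = sqksvm_alpha(train.labels, ir)
        K = backend.kernel(
            train.features, val.features, encoder, method=cfg.kernel_method
        )
        return np.asarray(
            [sqksvm_decision(y_signed, alpha, K.entries[:, j]) for j in range(val.n_samples)]
        )
    if classifier == "qksvm-ref":
        K_tt = backend.kernel(
            train.features, train.features, encoder, method=cfg.kernel_method
        )
        K_vt = backend.kernel(
            val.features, train.features, encoder, method=cfg.kernel_method
        )
        model = QKSVMReference(C=cfg.svm_C).fit(K_tt.entries, y_signed)
        return model.decision_function(K_vt.entries)
    raise ValueError(f"unknown classifier {classifier!r} (expected {CLASSIFIERS})")


def cross_validate(
    data: LabeledDataset,
    classifier: str,
    encoding: str = "log2n",
    cfg: CVConfig = CVConfig(),
    compute_gcq: bool = False,
) -> EvaluationReport:
    """Repeated stratified 80/20 evaluation with per-fold leakage isolation.

    Redundancy reduction and feature ranking are refitted on each fold's
    training rows; validation AUC is computed from continuous scores with the
    minority class as positive.
    """
    data.require_two_classes()
    positive_class = data.minority_class()
    fold_aucs: list[float] = []
    n_features_used = None
    root = np.random.SeedSequence(cfg.seed)
    fold_seeds = [int(s.generate_state(1)[0]) for s in root.spawn(cfg.n_folds)]

    for fold, (tr_idx, va_idx) in enumerate(_stratified_splits(data.labels, cfg)):
        train, val = data.subset(tr_idx), data.subset(va_idx)
        kept = redundancy_kept_columns(train.features, cfg.corr_threshold)
        train, val = train.select_features(kept), val.select_features(kept)
        if cfg.n_features is not None:
            top = rank_and_select(train.features, train.labels, cfg.n_features)
            train, val = train.select_features(top), val.select_features(top)
        n_features_used = train.n_features
        encoder = get_encoder(encoding)
        encoder.fit(train.features)
        backend = Backend(
            mode=cfg.backend, shots=cfg.shots, lam=cfg.lam, seed=fold_seeds[fold]
        )
        scores = _fold_scores(
            train, val, classifier, encoder, backend, cfg, positive_class
        )
        fold_aucs.append(auc(scores, val.labels, positive=positive_class))

    gcq = None
    if compute_gcq:
        ds = data
        kept = redundancy_kept_columns(ds.features, cfg.corr_threshold)
        ds = ds.select_features(kept)
        if cfg.n_features is not None:
            ds = ds.select_features(
                rank_and_select(ds.features, ds.labels, cfg.n_features)
            )
        encoder = get_encoder(encoding)
        encoder.fit(ds.features)
        kq = Backend(mode="exact").kernel(
            ds.features, ds.features, encoder, method=cfg.kernel_method
        )
        gcq = gcq_score(linear_kernel_matrix(ds.features), kq)

    return EvaluationReport(
        classifier=classifier,
        encoding=encoding,
        n_features=int(n_features_used),
        fold_aucs=fold_aucs,
        imbalance=imbalance_ratio(data.labels),
        gcq=gcq,
        config={
            "n_folds": cfg.n_folds,
            "train_fraction": cfg.train_fraction,
            "corr_threshold": cfg.corr_threshold,
            "seed": cfg.seed,
            "backend": cfg.backend,
            "shots": cfg.shots if cfg.backend == "shots" else 0,
            "lambda": cfg.lam,
            "kernel_method": cfg.kernel_method,
        },
    )
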