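"""Distance and kernel classifiers for two-class tabular data.

* :func:`qdc_classify` — nearest-labelled-set distance classifier: the test
  state gets the label of whichever class subset contains the closest encoded
  training state, with distance ``1 - Re<u|v>`` from the Hadamard test.
* :func:`sqksvm_classify` — kernel vote with fixed per-class weights set from
  the class imbalance ratio instead of an optimised support vector.
* :class:`QKSVMReference` — conventional soft-margin SVM on the same
  precomputed quantum kernel, as the optimised point of comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .inner_product import DEFAULT_SHOTS, hadamard_test, kernel_matrix

__all__ = [
    "LabeledDataset",
    "WeightVector",
    "Prediction",
    "Backend",
    "quantum_distance",
    "qdc_classify",
    "qdc_scores",
    "sqksvm_alpha",
    "sqksvm_classify",
    "QKSVMReference",
]


@dataclass
class LabeledDataset:
    """Feature matrix plus binary labels.

    ``classes`` lists the two labels in order of first appearance; class
    ``classes[0]`` plays the role of label *a* (the tie-winning set in the
    distance classifier) unless overridden.  ``signed_labels`` maps the
    minority class to +1 by default.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("feature rows and labels disagree in length")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.features.shape[1])]
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length mismatch")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> list:
        seen: list = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    def require_two_classes(self) -> None:
        if len(self.classes) != 2:
            raise ValueError(
                f"need exactly two classes, found {self.classes!r}"
            )

    def class_mask(self, label) -> np.ndarray:
        return self.labels == label

    def minority_class(self):
        self.require_two_classes()
        a, b = self.classes
        na, nb = int(np.sum(self.labels == a)), int(np.sum(self.labels == b))
        if na == nb:
            return b  # tie: second-seen class is "minority" for determinism
        return a if na < nb else b

    def signed_labels(self, positive_class=None) -> np.ndarray:
        """Labels as -1/+1; by default the minority class maps to +1."""
        if positive_class is None:
            positive_class = self.minority_class()
        return np.where(self.labels == positive_class, 1.0, -1.0)

    def subset(self, idx) -> "LabeledDataset":
        return LabeledDataset(
            self.features[idx], self.labels[idx], list(self.feature_names)
        )

    def select_features(self, cols) -> "LabeledDataset":
        cols = list(cols)
        return LabeledDataset(
            self.features[:, cols],
            self.labels,
            [self.feature_names[c] for c in cols],
        )


@dataclass(frozen=True)
class WeightVector:
    alpha: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        if np.any(a <= 0.0) or np.any(a > 1.0):
            raise ValueError("weights must lie in (0, 1]")
        object.__setattr__(self, "alpha", a)


@dataclass(frozen=True)
class Prediction:
    label: object
    score: float


class Backend:
    """How overlaps are evaluated: exact statevector, shot sampling, or
    shot sampling through a depolarizing channel (``lam > 0``)."""

    def __init__(
        self,
        mode: str = "exact",
        shots: int = DEFAULT_SHOTS,
        lam: float = 0.0,
        seed: int = 0,
    ) -> None:
        if mode not in ("exact", "shots"):
            raise ValueError(f"mode must be 'exact' or 'shots', got {mode!r}")
        self.mode = mode
        self.shots = shots
        self.lam = lam
        self.seed = seed
        self._seed_seq = np.random.SeedSequence(seed)

    def _next_rng(self) -> np.random.Generator:
        (child,) = self._seed_seq.spawn(1)
        return np.random.default_rng(child)

    def noise_model(self):
        from .noise import NoiseModel

        if self.lam == 0.0 and self.mode == "exact":
            return None
        return NoiseModel(
            lam=self.lam, shots=self.shots if self.mode == "shots" else 0
        )

    def overlap(self, U, V, test: str = "hadamard") -> float:
        model = self.noise_model()
        if model is not None:
            from .noise import noisy_overlap_run

            return noisy_overlap_run(U, V, test, model, self._next_rng()).value
        fn = hadamard_test if test == "hadamard" else None
        if fn is None:
            from .inner_product import swap_test as fn
        return fn(U, V, mode="exact").value

    def kernel(self, A, B, encoder, method: str = "swap"):
        model = self.noise_model()
        return kernel_matrix(
            A,
            B,
            encoder,
            method=method,
            mode=self.mode,
            shots=self.shots,
            seed=int(self._seed_seq.spawn(1)[0].generate_state(1)[0]),
            noise_model=model,
        )


def quantum_distance(u_circuit, v_circuit, backend: Backend | None = None) -> float:
    """Distance ``1 - Re<u|v>`` between two encoded unit states."""
    backend = backend or Backend()
    return 1.0 - backend.overlap(u_circuit, v_circuit, test="hadamard")


def qdc_scores(
    train: LabeledDataset,
    test_sample,
    encoder,
    backend: Backend | None = None,
    class_a=None,
) -> tuple[float, float]:
    """Minimum distances (min_P, min_Q) from the test state to each class set."""
    backend = backend or Backend()
    train.require_two_classes()
    classes = train.classes
    if class_a is None:
        class_a = classes[0]
    class_b = classes[1] if class_a == classes[0] else classes[0]
    v = encoder.circuit(np.asarray(test_sample, dtype=float))
    dists = {class_a: [], class_b: []}
    for x, y in zip(train.features, train.labels):
        dists[y].append(quantum_distance(encoder.circuit(x), v, backend))
    if not dists[class_a] or not dists[class_b]:
        raise ValueError("both class subsets must be non-empty")
    return min(dists[class_a]), min(dists[class_b])


def qdc_classify(
    train: LabeledDataset,
    test_sample,
    encoder,
    backend: Backend | None = None,
    class_a=None,
) -> Prediction:
    """Assign the label of the closest class subset (ties go to class *a*).

    The continuous score is ``min_Q - min_P`` (positive favours class *a*),
    so downstream AUC can use scores rather than hard labels.
    """
    train.require_two_classes()
    classes = train.classes
    if class_a is None:
        class_a = classes[0]
    class_b = classes[1] if class_a == classes[0] else classes[0]
    min_p, min_q = qdc_scores(train, test_sample, encoder, backend, class_a)
    label = class_a if min_p <= min_q else class_b
    return Prediction(label=label, score=min_q - min_p)


def sqksvm_alpha(labels, IR: float) -> WeightVector:
    """Fixed per-class weights from the imbalance ratio.

    All ones when ``IR == 0.5``; otherwise ``IR`` for the majority class and
    ``1 - IR`` for the minority class.
    """
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two classes, found {uniq!r}")
    if not 0.0 < IR <= 0.5:
        raise ValueError(f"imbalance ratio must be in (0, 0.5], got {IR}")
    if IR == 0.5:
        return WeightVector(np.ones(labels.shape[0]))
    n0 = int(np.sum(labels == uniq[0]))
    n1 = labels.shape[0] - n0
    minority = uniq[0] if n0 < n1 else uniq[1]
    alpha = np.where(labels == minority, 1.0 - IR, IR)
    return WeightVector(alpha)


def sqksvm_decision(signed_labels, alpha: WeightVector, kernel_row) -> float:
    """The kernel vote ``sum_i y_i alpha_i K(x_i, x~)``."""
    y = np.asarray(signed_labels, dtype=float)
    k = np.asarray(kernel_row, dtype=float).ravel()
    if y.shape[0] != alpha.alpha.shape[0] or y.shape[0] != k.shape[0]:
        raise ValueError(
            f"length mismatch: labels {y.shape[0]}, alpha "
            f"{alpha.alpha.shape[0]}, kernel row {k.shape[0]}"
        )
    return float(np.sum(y * alpha.alpha * k))


def sqksvm_classify(signed_labels, alpha: WeightVector, kernel_row) -> Prediction:
    """Threshold the kernel vote at zero: +1 when the score is >= 0."""
    score = sqksvm_decision(signed_labels, alpha, kernel_row)
    return Prediction(label=1 if score >= 0.0 else -1, score=score)


class QKSVMReference:
    """Soft-margin SVM trained on a precomputed quantum kernel.

    A deterministic reference: the dual problem is solved by scikit-learn's
    SVC with ``kernel='precomputed'``.  Kernels that are indefinite beyond
    tolerance are repaired by shifting the spectrum up to zero (with a
    warning), since shot noise can push small eigenvalues negative.
    """

    def __init__(self, C: float = 1.0, psd_tol: float = 1e-8, tol: float = 1e-8) -> None:
        self.C = C
        self.psd_tol = psd_tol
        self.tol = tol  # libsvm's default 1e-3 is too loose for oracle checks
        self._svc = None

    @staticmethod
    def _repair_psd(K: np.ndarray, tol: float) -> np.ndarray:
        K = 0.5 * (K + K.T)
        w = np.linalg.eigvalsh(K)
        lo = float(w.min())
        if lo < -tol:
            warnings.warn(
                f"kernel is indefinite (min eigenvalue {lo:.3g}); "
                "shifting spectrum to restore PSD",
                stacklevel=3,
            )
            K = K + (-lo + tol) * np.eye(K.shape[0])
        return K

    def fit(self, K: np.ndarray, signed_labels) -> "QKSVMReference":
        from sklearn.svm import SVC

        K = np.asarray(K, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("training kernel must be square")
        K = self._repair_psd(K, self.psd_tol)
        self._svc = SVC(C=self.C, kernel="precomputed", tol=self.tol)
        self._svc.fit(K, np.asarray(signed_labels, dtype=float))
        return self

    def decision_function(self, K_test_train: np.ndarray) -> np.ndarray:
        if self._svc is None:
            raise RuntimeError("fit() must be called first")
        return self._svc.decision_function(np.asarray(K_test_train, dtype=float))

    def predict(self, K_test_train: np.ndarray) -> np.ndarray:
        scores = self.decision_function(K_test_train)
        return np.where(scores >= 0.0, 1.0, -1.0)

    @property
    def dual_coef(self) -> np.ndarray:
        if self._svc is None:
            raise RuntimeError("fit() must be called first")
        coef = np.zeros(self._svc.shape_fit_[0])
        coef[self._svc.support_] = self._svc.dual_coef_.ravel()
        return coef

    @property
    def intercept(self) -> float:
        if self._svc is None:
            raise RuntimeError("fit() must be called first")
        return float(self._svc.intercept_[0])
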