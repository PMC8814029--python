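"""Data-encoding circuits.

Two strategies are provided:

* :func:`build_log2n_circuit` — amplitude encoding of an l2-normalised
  feature vector into ``ceil(log2 N)`` qubits using only RY and CNOT gates
  (uniformly-controlled rotations expanded through a Gray-code ladder).
* :func:`build_n_qubit_circuit` — one qubit per feature: a layer of Hadamards,
  per-qubit RZ rotations with the feature values as angles, and a single
  forward pass of nearest-neighbour CNOTs.

The angle hierarchy for amplitude encoding is a binary tree: the level-k angle
for block ``j`` splits the block's probability mass between its two halves,
``cos(theta) = |left half| / |block|``.  At the deepest level the signed
amplitudes themselves fix the angle via ``atan2``, so real vectors (including
negative entries) are reproduced exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circuit_sim import CNOT, RY, RZ, Circuit, H, run_circuit

__all__ = [
    "AngleTree",
    "normalize_and_pad",
    "ry_tree_angles",
    "build_log2n_circuit",
    "build_n_qubit_circuit",
    "Log2NEncoder",
    "NQubitEncoder",
    "get_encoder",
]


@dataclass(frozen=True)
class AngleTree:
    """Hierarchical rotation half-angles; ``levels[k]`` holds ``2**k`` angles."""

    levels: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "levels", tuple(tuple(float(a) for a in lvl) for lvl in self.levels)
        )
        for k, lvl in enumerate(self.levels):
            if len(lvl) != 2**k:
                raise ValueError(f"level {k} must hold {2**k} angles, got {len(lvl)}")

    @property
    def depth(self) -> int:
        return len(self.levels)

    @property
    def n_angles(self) -> int:
        return sum(len(lvl) for lvl in self.levels)


def _next_pow2(n: int) -> int:
    return 1 << max(int(math.ceil(math.log2(n))), 0) if n > 1 else 1


def normalize_and_pad(x) -> np.ndarray:
    """Zero-pad to the next power of two, then l2-normalise."""
    v = np.asarray(x, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty feature vector")
    if not np.all(np.isfinite(v)):
        raise ValueError("feature vector contains non-finite entries")
    norm = np.linalg.norm(v)
    if norm == 0.0:
        raise ValueError("all-zero feature vector cannot be amplitude-encoded")
    size = max(_next_pow2(v.size), 2)
    out = np.zeros(size, dtype=float)
    out[: v.size] = v / norm
    return out


def ry_tree_angles(u) -> AngleTree:
    """Half-angles reproducing unit vector ``u`` through the RY/CNOT circuit.

    Internal levels split non-negative block norms (angles in ``[0, pi/2]``);
    the leaf level uses the signed amplitude pair, so the round trip through
    :func:`build_log2n_circuit` is exact for real vectors.
    """
    v = np.asarray(u, dtype=float).ravel()
    m = v.size
    if m < 2 or m & (m - 1):
        raise ValueError(f"length must be a power of two >= 2, got {m}")
    if abs(np.linalg.norm(v) - 1.0) > 1e-8:
        raise ValueError("input must be l2-normalised")
    n = int(math.log2(m))
    levels: list[tuple[float, ...]] = []
    for k in range(n):
        block = m >> k
        half = block >> 1
        angles = []
        for j in range(2**k):
            seg = v[j * block : (j + 1) * block]
            if half == 1:
                left, right = seg[0], seg[1]
                angles.append(0.0 if left == 0.0 and right == 0.0 else math.atan2(right, left))
            else:
                ln = np.linalg.norm(seg[:half])
                rn = np.linalg.norm(seg[half:])
                angles.append(0.0 if ln == 0.0 and rn == 0.0 else math.atan2(rn, ln))
        levels.append(tuple(angles))
    return AngleTree(tuple(levels))


def _gray(i: int) -> int:
    return i ^ (i >> 1)


def _ucry_gates(half_angles, controls: tuple[int, ...], target: int) -> list:
    """Uniformly-controlled RY expanded into a Gray-code RY/CNOT ladder.

    ``half_angles[j]`` is the half-angle applied when the control register
    (``controls[0]`` = most significant bit of ``j``) is in state ``|j>``.
    """
    k = len(controls)
    full = 2.0 * np.asarray(half_angles, dtype=float)
    if full.size != 2**k:
        raise ValueError("angle count must be 2**len(controls)")
    if k == 0:
        return [RY(target, float(full[0]))]
    # M[i, j] = (-1)^{popcount(g(i) & j)}; ladder angles = M @ full / 2^k
    dim = 2**k
    M = np.array(
        [[(-1) ** bin(_gray(i) & j).count("1") for j in range(dim)] for i in range(dim)],
        dtype=float,
    )
    ladder = (M @ full) / dim
    gates = []
    for i in range(dim):
        gates.append(RY(target, float(ladder[i])))
        # the CNOT control is the bit where consecutive Gray codes differ
        diff = _gray(i) ^ _gray((i + 1) % dim)
        bit = diff.bit_length() - 1  # bit index, 0 = least significant
        gates.append(CNOT(controls[k - 1 - bit], target))
    return gates


def build_log2n_circuit(angles: AngleTree) -> Circuit:
    """Amplitude-encoding circuit on ``angles.depth`` qubits (RY + CNOT only).

    Level-k rotations target qubit ``n-1-k``; the level's ``2**k`` half-angles
    are conditioned on the previously rotated (more significant) qubits.
    """
    n = angles.depth
    if n < 1:
        raise ValueError("empty angle tree")
    circ = Circuit(n)
    for k, level in enumerate(angles.levels):
        target = n - 1 - k
        controls = tuple(n - 1 - i for i in range(k))  # MSB of block index first
        circ.extend(_ucry_gates(level, controls, target))
    return circ


def build_n_qubit_circuit(x, scale: tuple | None = None) -> Circuit:
    """One-qubit-per-feature circuit: H layer, RZ(feature) layer, CNOT chain.

    ``scale``, if given, is a ``(lo, hi)`` pair of per-feature arrays; features
    are affinely mapped so that ``[lo, hi] -> [0, pi]`` before use as angles
    (degenerate features with ``hi == lo`` map to 0).
    """
    v = np.asarray(x, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty feature vector")
    if scale is not None:
        lo, hi = (np.asarray(a, dtype=float) for a in scale)
        span = np.where(hi > lo, hi - lo, 1.0)
        v = np.where(hi > lo, np.clip((v - lo) / span, 0.0, 1.0) * math.pi, 0.0)
    n = v.size
    circ = Circuit(n)
    for q in range(n):
        circ.append(H(q))
    for q in range(n):
        circ.append(RZ(q, float(v[q])))
    for q in range(n - 1):
        circ.append(CNOT(q, q + 1))
    return circ


class Log2NEncoder:
    """Amplitude encoder: ``N`` features on ``ceil(log2 N)`` qubits."""

    name = "log2n"

    def fit(self, X) -> "Log2NEncoder":
        return self  # stateless

    def circuit(self, x) -> Circuit:
        return build_log2n_circuit(ry_tree_angles(normalize_and_pad(x)))

    def state(self, x) -> np.ndarray:
        return run_circuit(self.circuit(x)).amplitudes

    def n_qubits(self, n_features: int) -> int:
        return max(int(math.ceil(math.log2(n_features))), 1)


class NQubitEncoder:
    """Phase encoder: ``N`` features on ``N`` qubits (H / RZ / CNOT chain).

    ``fit`` records per-feature min/max from the training matrix so that RZ
    angles land in ``[0, pi]``; pass ``scaled=False`` to use raw feature
    values as angles.
    """

    name = "nqubit"

    def __init__(self, scaled: bool = True) -> None:
        self.scaled = scaled
        self._lo = None
        self._hi = None

    def fit(self, X) -> "NQubitEncoder":
        X = np.asarray(X, dtype=float)
        self._lo = X.min(axis=0)
        self._hi = X.max(axis=0)
        return self

    def circuit(self, x) -> Circuit:
        scale = None
        if self.scaled:
            if self._lo is None:
                raise RuntimeError("NQubitEncoder used before fit() with scaled=True")
            scale = (self._lo, self._hi)
        return build_n_qubit_circuit(x, scale=scale)

    def state(self, x) -> np.ndarray:
        return run_circuit(self.circuit(x)).amplitudes

    def n_qubits(self, n_features: int) -> int:
        return n_features


def get_encoder(name: str, **kwargs):
    if name == "log2n":
        return Log2NEncoder()
    if name == "nqubit":
        return NQubitEncoder(**kwargs)
    raise ValueError(f"unknown encoding {name!r} (expected 'log2n' or 'nqubit')")
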