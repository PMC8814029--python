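"""Overlap estimation circuits and quantum kernel matrices.

The Hadamard test estimates ``Re<u|v>`` from a single ancilla:
``Pr(ancilla=0) = (1 + Re<u|v>) / 2``.  The Swap test estimates the squared
overlap on two data registers: ``Pr(ancilla=0) = (1 + |<u|v>|^2) / 2``.
Both are assembled from the raw encoding circuits; the ancilla is qubit 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit_sim import (
    SWAP,
    Circuit,
    H,
    StateVector,
    X,
    controlled_circuit,
    marginal_probability,
    run_circuit,
    sample_counts,
    shift_qubits,
)

__all__ = [
    "OverlapEstimate",
    "KernelMatrix",
    "hadamard_test_circuit",
    "swap_test_circuit",
    "hadamard_test",
    "swap_test",
    "kernel_matrix",
    "DEFAULT_SHOTS",
]

DEFAULT_SHOTS = 8192


@dataclass(frozen=True)
class OverlapEstimate:
    """Result of a single overlap-estimation run."""

    value: float
    mode: str  # "exact" | "shots"
    shots: int = 0
    seed: int | None = None
    pr0: float | None = None  # ancilla Pr(0) that produced `value`


@dataclass
class KernelMatrix:
    entries: np.ndarray
    row_ids: list
    col_ids: list

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("entry shape does not match identifier lists")

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.entries, index=self.row_ids, columns=self.col_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "KernelMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


def _check_same_width(U: Circuit, V: Circuit) -> int:
    if U.n_qubits != V.n_qubits:
        raise ValueError(
            f"encoders act on different qubit counts: {U.n_qubits} vs {V.n_qubits}"
        )
    return U.n_qubits


def hadamard_test_circuit(U: Circuit, V: Circuit) -> Circuit:
    """Interference circuit on ``n+1`` qubits; ancilla is qubit 0.

    Sequence: H on ancilla, controlled-U, X, controlled-V, X, H.  Just before
    the final H the register holds ``(|0>|v> + |1>|u>)/sqrt(2)``.
    """
    n = _check_same_width(U, V)
    circ = Circuit(n + 1)
    circ.append(H(0))
    circ.extend(controlled_circuit(shift_qubits(U, 1), 0).gates)
    circ.append(X(0))
    circ.extend(controlled_circuit(shift_qubits(V, 1), 0).gates)
    circ.append(X(0))
    circ.append(H(0))
    return circ


def swap_test_circuit(U: Circuit, V: Circuit) -> Circuit:
    """Controlled-SWAP circuit on ``2n+1`` qubits; ancilla is qubit 0.

    U prepares qubits ``1..n``, V prepares ``n+1..2n``; each qubit pair is
    swapped under ancilla control, then the ancilla is interfered with H.
    """
    n = _check_same_width(U, V)
    circ = Circuit(2 * n + 1)
    circ.append(H(0))
    circ.extend(shift_qubits(U, 1, n_qubits=2 * n + 1).gates)
    circ.extend(shift_qubits(V, n + 1, n_qubits=2 * n + 1).gates)
    for q in range(1, n + 1):
        circ.append(SWAP(q, q + n, controls=(0,)))
    circ.append(H(0))
    return circ


def _estimate_pr0(
    state: StateVector, mode: str, shots: int, seed
) -> tuple[float, int]:
    if mode == "exact":
        return marginal_probability(state, 0, 0), 0
    if mode == "shots":
        counts = sample_counts(state, 0, shots, seed)
        return counts.frequency0, shots
    raise ValueError(f"mode must be 'exact' or 'shots', got {mode!r}")


def hadamard_test(
    U: Circuit,
    V: Circuit,
    mode: str = "exact",
    shots: int = DEFAULT_SHOTS,
    seed=0,
) -> OverlapEstimate:
    """Estimate ``Re<u|v>`` as ``2 * Pr(ancilla=0) - 1``."""
    state = run_circuit(hadamard_test_circuit(U, V))
    pr0, used = _estimate_pr0(state, mode, shots, seed)
    value = 2.0 * pr0 - 1.0
    if mode == "exact":
        value = float(np.clip(value, -1.0, 1.0))
    return OverlapEstimate(
        value=float(value),
        mode=mode,
        shots=used,
        seed=None if mode == "exact" else (seed if isinstance(seed, int) else None),
        pr0=float(pr0),
    )


def swap_test(
    U: Circuit,
    V: Circuit,
    mode: str = "exact",
    shots: int = DEFAULT_SHOTS,
    seed=0,
) -> OverlapEstimate:
    """Estimate ``|<u|v>|^2`` as ``2 * Pr(ancilla=0) - 1``, clipped to [0, 1].

    Clipping only matters in shot mode, where sampling noise can push the raw
    estimator slightly negative; the exact-mode value is non-negative up to
    floating-point rounding.
    """
    state = run_circuit(swap_test_circuit(U, V))
    pr0, used = _estimate_pr0(state, mode, shots, seed)
    value = float(np.clip(2.0 * pr0 - 1.0, 0.0, 1.0))
    return OverlapEstimate(
        value=value,
        mode=mode,
        shots=used,
        seed=None if mode == "exact" else (seed if isinstance(seed, int) else None),
        pr0=float(pr0),
    )


def kernel_matrix(
    A,
    B,
    encoder,
    method: str = "swap",
    mode: str = "exact",
    shots: int = DEFAULT_SHOTS,
    seed: int = 0,
    row_ids=None,
    col_ids=None,
    noise_model=None,
) -> KernelMatrix:
    """Pairwise squared-overlap matrix between encoded sample sets.

    ``method='swap'`` runs the Swap test per pair; ``method='hadamard2'``
    squares the Hadamard-test real part (equivalent for real-valued data).
    Each entry draws an independent child seed from ``seed`` in shot mode.
    ``noise_model`` (a :class:`qclin.noise.NoiseModel`) routes every run
    through the depolarizing channel.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"feature counts differ: {A.shape[1]} vs {B.shape[1]}"
        )
    if method not in ("swap", "hadamard2"):
        raise ValueError(f"method must be 'swap' or 'hadamard2', got {method!r}")

    circs_a = [encoder.circuit(a) for a in A]
    circs_b = [encoder.circuit(b) for b in B]
    out = np.empty((len(circs_a), len(circs_b)))
    child_seeds = np.random.SeedSequence(seed).spawn(out.size)
    idx = 0
    for i, ca in enumerate(circs_a):
        for j, cb in enumerate(circs_b):
            rng = np.random.default_rng(child_seeds[idx])
            idx += 1
            if noise_model is not None:
                from .noise import noisy_overlap_run

                test = "swap" if method == "swap" else "hadamard"
                est = noisy_overlap_run(ca, cb, test, noise_model, rng)
            elif method == "swap":
                est = swap_test(ca, cb, mode=mode, shots=shots, seed=rng)
            else:
                est = hadamard_test(ca, cb, mode=mode, shots=shots, seed=rng)
            val = est.value**2 if method == "hadamard2" else est.value
            out[i, j] = min(max(val, 0.0), 1.0)
    rid = list(row_ids) if row_ids is not None else list(range(len(circs_a)))
    cid = list(col_ids) if col_ids is not None else list(range(len(circs_b)))
    return KernelMatrix(out, rid, cid)
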