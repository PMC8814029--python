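"""Minimal dense statevector simulator.

Amplitude ordering: basis state ``|q_{n-1} ... q_1 q_0>`` lives at the integer
index whose *least-significant* bit is qubit 0.  All gates are applied by
in-place tensor contraction on a ``(2,)*n`` view of the amplitude array, so a
gate with ``c`` controls acting on ``t`` targets touches ``2**(n-c)``
amplitudes and never builds a ``2**n x 2**n`` matrix.

Supported gate kinds: ``RY``, ``RZ``, ``H``, ``X``, ``Z``, ``CNOT``, ``SWAP``;
any gate may additionally carry an arbitrary number of control qubits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StateVector",
    "Gate",
    "Circuit",
    "MeasurementCounts",
    "apply_gate",
    "run_circuit",
    "controlled_circuit",
    "shift_qubits",
    "marginal_probability",
    "sample_counts",
    "zero_state",
]

_SQRT2_INV = 1.0 / np.sqrt(2.0)

#: gate kinds that take an angle argument
ROTATION_KINDS = frozenset({"RY", "RZ"})
#: gate kinds acting on two target qubits
TWO_TARGET_KINDS = frozenset({"SWAP"})
GATE_KINDS = frozenset({"RY", "RZ", "H", "X", "Z", "CNOT", "SWAP"})


@dataclass(frozen=True)
class StateVector:
    """A pure state on ``n_qubits`` qubits as a dense complex amplitude array."""

    n_qubits: int
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=complex)
        if self.n_qubits < 1:
            raise ValueError(f"n_qubits must be >= 1, got {self.n_qubits}")
        if amps.shape != (2**self.n_qubits,):
            raise ValueError(
                f"expected {2**self.n_qubits} amplitudes for {self.n_qubits} "
                f"qubits, got shape {amps.shape}"
            )
        object.__setattr__(self, "amplitudes", amps)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.amplitudes))

    def probabilities(self) -> np.ndarray:
        return np.abs(self.amplitudes) ** 2


def zero_state(n_qubits: int) -> StateVector:
    """``|0...0>`` on ``n_qubits`` qubits."""
    amps = np.zeros(2**n_qubits, dtype=complex)
    amps[0] = 1.0
    return StateVector(n_qubits, amps)


@dataclass(frozen=True)
class Gate:
    kind: str
    targets: tuple[int, ...]
    controls: tuple[int, ...] = ()
    angle: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        object.__setattr__(self, "controls", tuple(self.controls))
        if self.kind not in GATE_KINDS:
            raise ValueError(f"unknown gate kind {self.kind!r}")
        if self.kind in ROTATION_KINDS:
            if self.angle is None:
                raise ValueError(f"{self.kind} requires an angle")
        elif self.angle is not None:
            raise ValueError(f"angle given for non-rotation gate {self.kind}")
        n_targets = 2 if self.kind in TWO_TARGET_KINDS else 1
        if self.kind == "CNOT":
            if len(self.targets) != 1 or len(self.controls) < 1:
                raise ValueError("CNOT needs one target and >= 1 control")
        elif len(self.targets) != n_targets:
            raise ValueError(
                f"{self.kind} acts on {n_targets} target(s), got {self.targets}"
            )
        seen = self.targets + self.controls
        if len(set(seen)) != len(seen):
            raise ValueError(
                f"targets {self.targets} and controls {self.controls} overlap"
            )

    @property
    def qubits(self) -> tuple[int, ...]:
        return self.targets + self.controls

    def matrix(self) -> np.ndarray:
        """Base (uncontrolled) unitary on the target register."""
        k = self.kind
        if k == "RY":
            h = 0.5 * self.angle
            c, s = np.cos(h), np.sin(h)
            return np.array([[c, -s], [s, c]], dtype=complex)
        if k == "RZ":
            h = 0.5 * self.angle
            return np.array(
                [[np.exp(-1j * h), 0.0], [0.0, np.exp(1j * h)]], dtype=complex
            )
        if k == "H":
            return np.array([[1, 1], [1, -1]], dtype=complex) * _SQRT2_INV
        if k in ("X", "CNOT"):
            return np.array([[0, 1], [1, 0]], dtype=complex)
        if k == "Z":
            return np.array([[1, 0], [0, -1]], dtype=complex)
        if k == "SWAP":
            m = np.eye(4, dtype=complex)
            m[[1, 2]] = m[[2, 1]]
            return m
        raise AssertionError(k)


# convenience constructors ------------------------------------------------

def RY(target: int, angle: float, controls: Iterable[int] = ()) -> Gate:
    return Gate("RY", (target,), tuple(controls), angle)


def RZ(target: int, angle: float, controls: Iterable[int] = ()) -> Gate:
    return Gate("RZ", (target,), tuple(controls), angle)


def H(target: int, controls: Iterable[int] = ()) -> Gate:
    return Gate("H", (target,), tuple(controls))


def X(target: int, controls: Iterable[int] = ()) -> Gate:
    return Gate("X", (target,), tuple(controls))


def Z(target: int, controls: Iterable[int] = ()) -> Gate:
    return Gate("Z", (target,), tuple(controls))


def CNOT(control: int, target: int) -> Gate:
    return Gate("CNOT", (target,), (control,))


def SWAP(q1: int, q2: int, controls: Iterable[int] = ()) -> Gate:
    return Gate("SWAP", (q1, q2), tuple(controls))


@dataclass
class Circuit:
    n_qubits: int
    gates: list[Gate] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.gates:
            self._check(g)

    def _check(self, gate: Gate) -> None:
        for q in gate.qubits:
            if not 0 <= q < self.n_qubits:
                raise IndexError(
                    f"qubit {q} out of range for {self.n_qubits}-qubit circuit"
                )

    def append(self, gate: Gate) -> "Circuit":
        self._check(gate)
        self.gates.append(gate)
        return self

    def extend(self, gates: Iterable[Gate]) -> "Circuit":
        for g in gates:
            self.append(g)
        return self

    def __len__(self) -> int:
        return len(self.gates)


@dataclass(frozen=True)
class MeasurementCounts:
    qubit: int
    shots: int
    count0: int
    count1: int

    def __post_init__(self) -> None:
        if self.count0 + self.count1 != self.shots:
            raise ValueError("count0 + count1 must equal shots")

    @property
    def frequency0(self) -> float:
        return self.count0 / self.shots


# core application --------------------------------------------------------

def _apply_inplace(amps: np.ndarray, n: int, gate: Gate) -> None:
    mat = gate.matrix()
    targets, controls = gate.targets, gate.controls
    psi = amps.reshape((2,) * n)
    # axis of qubit q in the C-ordered tensor is n-1-q
    ctrl_axes = [n - 1 - q for q in controls]
    targ_axes = [n - 1 - q for q in targets]
    moved = np.moveaxis(psi, ctrl_axes + targ_axes, range(len(controls) + len(targets)))
    block = moved[(1,) * len(controls)]  # view of the sub-tensor where every control is |1>
    t = len(targets)
    updated = (mat @ block.reshape(2**t, -1)).reshape(block.shape)
    block[...] = updated  # assignment through the view mutates `amps`


def apply_gate(state: StateVector, gate: Gate) -> StateVector:
    """Apply one (possibly controlled) gate; the input state is not mutated."""
    for q in gate.qubits:
        if not 0 <= q < state.n_qubits:
            raise IndexError(f"qubit {q} out of range for {state.n_qubits} qubits")
    amps = state.amplitudes.copy()
    _apply_inplace(amps, state.n_qubits, gate)
    return StateVector(state.n_qubits, amps)


def run_circuit(circuit: Circuit, initial: StateVector | None = None) -> StateVector:
    """Apply the circuit's gates in order to ``initial`` (default ``|0...0>``)."""
    if initial is None:
        initial = zero_state(circuit.n_qubits)
    if circuit.n_qubits != initial.n_qubits:
        raise ValueError(
            f"circuit acts on {circuit.n_qubits} qubits but state has "
            f"{initial.n_qubits}"
        )
    amps = initial.amplitudes.copy()
    for gate in circuit.gates:
        _apply_inplace(amps, circuit.n_qubits, gate)
    return StateVector(circuit.n_qubits, amps)


def controlled_circuit(circuit: Circuit, control: int) -> Circuit:
    """Promote every gate of ``circuit`` to be controlled on a fresh qubit.

    The returned circuit acts on ``max(control+1, n_qubits)`` qubits; applied
    to ``|0>_control (x) psi`` it leaves ``psi`` untouched, on
    ``|1>_control (x) psi`` it applies the original circuit.
    """
    used = {q for g in circuit.gates for q in g.qubits}
    if control in used:
        raise ValueError(f"control qubit {control} collides with circuit qubits")
    n = max(circuit.n_qubits, control + 1)
    gates = [replace(g, controls=g.controls + (control,)) for g in circuit.gates]
    return Circuit(n, gates)


def shift_qubits(circuit: Circuit, offset: int, n_qubits: int | None = None) -> Circuit:
    """Relabel every qubit ``q -> q + offset`` (used to place encoders on registers)."""
    if offset < 0:
        raise ValueError("offset must be non-negative")
    n = n_qubits if n_qubits is not None else circuit.n_qubits + offset
    gates = [
        replace(
            g,
            targets=tuple(q + offset for q in g.targets),
            controls=tuple(q + offset for q in g.controls),
        )
        for g in circuit.gates
    ]
    return Circuit(n, gates)


def marginal_probability(state: StateVector, qubit: int, outcome: int) -> float:
    """Probability that measuring ``qubit`` in the Z basis yields ``outcome``."""
    if not 0 <= qubit < state.n_qubits:
        raise IndexError(f"qubit {qubit} out of range")
    if outcome not in (0, 1):
        raise ValueError("outcome must be 0 or 1")
    probs = state.probabilities()
    idx = np.arange(2**state.n_qubits)
    mask = ((idx >> qubit) & 1) == outcome
    return float(probs[mask].sum())


def sample_counts(
    state: StateVector, qubit: int, shots: int, seed: int | np.random.Generator
) -> MeasurementCounts:
    """Binomial sampling of repeated single-qubit Z measurements."""
    if shots < 1:
        raise ValueError(f"shots must be >= 1, got {shots}")
    p0 = marginal_probability(state, qubit, 0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count0 = int(rng.binomial(shots, min(max(p0, 0.0), 1.0)))
    return MeasurementCounts(qubit=qubit, shots=shots, count0=count0, count1=shots - count0)
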