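import numpy as np
import pytest

from qclin.circuit_sim import CNOT, RY, RZ, Circuit, H, SWAP, X, Z


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_unit_vector(rng, n):
    v = rng.standard_normal(n)
    return v / np.linalg.norm(v)


def random_circuit(rng, n_qubits, n_gates):
    """Random circuit over the full supported gate vocabulary."""
    gates = []
    kinds = ["RY", "RZ", "H", "X", "Z"]
    if n_qubits >= 2:
        kinds += ["CNOT", "SWAP"]
    for _ in range(n_gates):
        kind = rng.choice(kinds)
        qubits = rng.permutation(n_qubits)
        if kind == "CNOT":
            gates.append(CNOT(int(qubits[0]), int(qubits[1])))
        elif kind == "SWAP":
            ctl = (int(qubits[2]),) if n_qubits > 2 and rng.random() < 0.3 else ()
            gates.append(SWAP(int(qubits[0]), int(qubits[1]), controls=ctl))
        else:
            ctl = (int(qubits[1]),) if n_qubits >= 2 and rng.random() < 0.3 else ()
            target = int(qubits[0])
            if kind in ("RY", "RZ"):
                angle = float(rng.uniform(-2 * np.pi, 2 * np.pi))
                g = RY(target, angle, ctl) if kind == "RY" else RZ(target, angle, ctl)
            else:
                g = {"H": H, "X": X, "Z": Z}[kind](target, ctl)
            gates.append(g)
    return Circuit(n_qubits, gates)


# --- independent dense-matrix oracle ---------------------------------------

_M1 = {
    "H": np.array([[1, 1], [1, -1]]) / np.sqrt(2),
    "X": np.array([[0, 1], [1, 0]]),
    "Z": np.array([[1, 0], [0, -1]]),
}


def _base_matrix(gate):
    if gate.kind == "RY":
        h = gate.angle / 2
        return np.array([[np.cos(h), -np.sin(h)], [np.sin(h), np.cos(h)]])
    if gate.kind == "RZ":
        h = gate.angle / 2
        return np.diag([np.exp(-1j * h), np.exp(1j * h)])
    if gate.kind in ("X", "CNOT"):
        return _M1["X"]
    if gate.kind == "SWAP":
        m = np.eye(4)
        return m[[0, 2, 1, 3]]
    return _M1[gate.kind]


def gate_matrix_full(gate, n_qubits):
    """Full 2^n x 2^n unitary built by explicit basis-state enumeration."""
    dim = 2**n_qubits
    base = np.asarray(_base_matrix(gate), dtype=complex)
    targets = gate.targets
    out = np.zeros((dim, dim), dtype=complex)
    for col in range(dim):
        if any((col >> c) & 1 == 0 for c in gate.controls):
            out[col, col] = 1.0
            continue
        # sub-index of the target register, targets[0] most significant
        sub = 0
        for t in targets:
            sub = (sub << 1) | ((col >> t) & 1)
        for new_sub in range(base.shape[0]):
            amp = base[new_sub, sub]
            if amp == 0:
                continue
            row = col
            s = new_sub
            for t in reversed(targets):
                row = (row & ~(1 << t)) | ((s & 1) << t)
                s >>= 1
            out[row, col] += amp
    return out


def circuit_matrix(circuit):
    """Dense product of the individual full gate matrices."""
    dim = 2**circuit.n_qubits
    M = np.eye(dim, dtype=complex)
    for g in circuit.gates:
        M = gate_matrix_full(g, circuit.n_qubits) @ M
    return M
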