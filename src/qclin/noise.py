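"""Depolarizing noise channel, noisy overlap runs, and linear noise fits.

The channel replaces a state with the maximally mixed state with probability
``lam``: ``rho -> (1 - lam) * rho + lam * I / 2^n``.  Expectation values
contract accordingly, which for the ancilla Z observable maps the measurement
probability ``p`` to ``(1 - lam) * p + lam / 2``.  Fitting noisy-vs-ideal
overlap scatters with ordinary least squares recovers ``lam`` as one minus
the slope; the paper-style fidelity summary is one minus the RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit_sim import marginal_probability, run_circuit
from .inner_product import (
    DEFAULT_SHOTS,
    OverlapEstimate,
    hadamard_test_circuit,
    swap_test_circuit,
)

__all__ = [
    "NoiseModel",
    "NoiseFitReport",
    "noisy_expectation",
    "depolarize_probability",
    "noisy_overlap_run",
    "fit_noise",
]


@dataclass(frozen=True)
class NoiseModel:
    """Depolarizing channel strength plus a shot budget.

    ``shots=0`` means the infinite-shot limit: the depolarized probability is
    used directly instead of being sampled.
    """

    lam: float
    n_qubits: int = 1
    shots: int = DEFAULT_SHOTS

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {self.lam}")
        if self.shots < 0:
            raise ValueError("shots must be >= 0 (0 = exact limit)")


def noisy_expectation(ideal: float, O_trace: float, model: NoiseModel) -> float:
    """Expectation of observable O under the depolarizing channel.

    ``(1 - lam) * <O> + lam / 2^n * tr(O)``.
    """
    return (1.0 - model.lam) * ideal + model.lam / 2**model.n_qubits * O_trace


def depolarize_probability(p: float, lam: float) -> float:
    """Single-qubit measurement probability after depolarization.

    Writing ``p = (1 + <Z>) / 2`` and contracting ``<Z>`` by ``(1 - lam)``
    (the Z observable is traceless) gives ``(1 - lam) * p + lam / 2``.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    return (1.0 - lam) * p + lam / 2.0


def noisy_overlap_run(
    U,
    V,
    test: str,
    model: NoiseModel,
    seed=0,
) -> OverlapEstimate:
    """Overlap estimate with depolarization applied before measurement.

    The exact ancilla probability is computed from the assembled test
    circuit, pushed through the channel, then (if ``model.shots > 0``)
    sampled binomially; the usual ``2 * p - 1`` estimator is applied to the
    result (clipped to [0, 1] for the swap test).
    """
    if test == "hadamard":
        circ = hadamard_test_circuit(U, V)
    elif test == "swap":
        circ = swap_test_circuit(U, V)
    else:
        raise ValueError(f"test must be 'hadamard' or 'swap', got {test!r}")
    p0 = marginal_probability(run_circuit(circ), 0, 0)
    p_noisy = depolarize_probability(p0, model.lam)
    if model.shots > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        p_hat = rng.binomial(model.shots, p_noisy) / model.shots
        mode, shots = "shots", model.shots
    else:
        p_hat = p_noisy
        mode, shots = "exact", 0
    value = 2.0 * p_hat - 1.0
    if test == "swap":
        value = float(np.clip(value, 0.0, 1.0))
    return OverlapEstimate(
        value=float(value),
        mode=mode,
        shots=shots,
        seed=seed if isinstance(seed, int) else None,
        pr0=float(p_hat),
    )


@dataclass(frozen=True)
class NoiseFitReport:
    slope: float
    intercept: float
    lambda_hat: float
    rmse: float
    fidelity: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "lambda_hat": self.lambda_hat,
            "rmse": self.rmse,
            "fidelity": self.fidelity,
            "n_points": self.n_points,
        }


def fit_noise(ideal, noisy) -> NoiseFitReport:
    """Ordinary least-squares fit of noisy overlaps against ideal ones.

    Returns the fitted line, ``lambda_hat = 1 - slope``, the RMSE between the
    two sequences, and ``fidelity = 1 - rmse``.
    """
    x = np.asarray(ideal, dtype=float).ravel()
    y = np.asarray(noisy, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("ideal and noisy sequences must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 points to fit")
    if np.ptp(x) == 0.0:
        raise ValueError("ideal values have zero variance; slope is undefined")
    from scipy import stats

    res = stats.linregress(x, y)
    rmse = float(np.sqrt(np.mean((y - x) ** 2)))
    return NoiseFitReport(
        slope=float(res.slope),
        intercept=float(res.intercept),
        lambda_hat=float(1.0 - res.slope),
        rmse=rmse,
        fidelity=1.0 - rmse,
        n_points=int(x.size),
    )
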