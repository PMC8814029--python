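# qclin

Quantum distance and kernel classifiers for two-class tabular data, running
entirely on a bundled dense statevector simulator.

Feature vectors are embedded into quantum states in one of two ways:

- **log2n (amplitude) encoding** — an l2-normalised, zero-padded feature
  vector becomes the amplitudes of a `ceil(log2 N)`-qubit state, prepared by
  a hierarchical tree of RY rotations expanded into pure RY/CNOT circuits.
- **nqubit (phase) encoding** — one qubit per feature: a Hadamard layer,
  per-qubit RZ rotations with (min–max scaled) feature values as angles, and
  a forward chain of nearest-neighbour CNOTs.

Overlaps between encoded states are estimated with interference circuits:
the **Hadamard test** (`Pr(ancilla=0) = (1 + Re<u|v>)/2`) for signed inner
products and the **Swap test** (`Pr(ancilla=0) = (1 + |<u|v>|^2)/2`) for
squared overlaps — exactly from the statevector, or from binomially sampled
measurement shots (default 8192), optionally through a depolarizing channel
`p -> (1-λ)p + λ/2`.

On top of that sit:

- **qDC** — a nearest-labelled-set distance classifier (`d = 1 - Re<u|v>`),
- **sqKSVM** — a kernel vote `Σ y_i α*_i K(x_i, x̃)` with fixed per-class
  weights derived from the class imbalance ratio,
- **qksvm-ref** — a conventional soft-margin SVM on the same precomputed
  quantum kernel,
- an evaluation pipeline: correlation-based redundancy reduction, univariate
  feature ranking, repeated stratified 80/20 cross-validation with rank-based
  AUC, the experimental `g_CQ` kernel-geometry score, and a synthetic
  two-class Gaussian generator,
- a noise-analysis module: depolarizing expectation values, noisy overlap
  runs, and ordinary-least-squares fits recovering λ as `1 - slope` with
  `fidelity = 1 - RMSE`.

## CLI

```sh
qclin generate -m 100 -n 8 --separation 3 --imbalance 0.3 --seed 1 --out data.csv
qclin encode data.csv --encoding log2n --row 0
qclin kernel data.csv --method swap --backend shots --shots 8192 --out kernel.csv
qclin classify train.csv test.csv --classifier sqksvm --out predictions.csv
qclin evaluate data.csv --classifier qdc --features 8 --folds 10 --out report.json
qclin noise-fit --pairs 200 --lam 0.1 --shots 8192 --out scatter.csv
```

All commands accept `--seed`; fixed seeds give byte-identical outputs.
`--backend shots --shots S --lam L` switches any overlap evaluation to
binomial sampling through a depolarizing channel of strength `L`.

## Library example

```python
import numpy as np
from qclin import Backend, Log2NEncoder, hadamard_test, swap_test
from qclin.pipeline import CVConfig, cross_validate, generate_two_class

enc = Log2NEncoder()
u, v = enc.circuit([3, 4, 0, 0]), enc.circuit([4, 3, 0, 0])
hadamard_test(u, v).value          # Re<u|v> = 0.96, exact
swap_test(u, v, mode="shots", seed=7).value  # |<u|v>|^2 from 8192 shots

data = generate_two_class(M=60, N=8, separation=3.0, IR=0.4, seed=0)
report = cross_validate(data, "sqksvm", "log2n", CVConfig(n_folds=10, seed=0))
report.mean_auc
```
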