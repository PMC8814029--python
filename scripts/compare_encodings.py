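#!/usr/bin/env python
"""Compare the two data encodings under shot noise across seeded datasets.

For each seed a synthetic two-class dataset is generated and the chosen
classifier is cross-validated with the amplitude (log2n) and the
one-qubit-per-feature (nqubit) encodings on a shot-sampling backend.  The
per-seed and average AUCs are reported; this is a reported comparison, not a
hard assertion.

Usage: python scripts/compare_encodings.py [--datasets 20] [--samples 40] ...
"""

from __future__ import annotations

import argparse

import numpy as np

from qclin.pipeline import CVConfig, cross_validate, generate_two_class


def main() -> int:
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--datasets", type=int, default=20)
    p.add_argument("--samples", type=int, default=40)
    p.add_argument("--features", type=int, default=4)
    p.add_argument("--separation", type=float, default=2.5)
    p.add_argument("--classifier", default="sqksvm",
                   choices=["qdc", "sqksvm", "qksvm-ref"])
    p.add_argument("--folds", type=int, default=3)
    p.add_argument("--shots", type=int, default=1024)
    p.add_argument("--seed", type=int, default=0)
    args = p.parse_args()

    cfg = CVConfig(n_folds=args.folds, seed=args.seed, backend="shots",
                   shots=args.shots)
    results = {"log2n": [], "nqubit": []}
    for i in range(args.datasets):
        data = generate_two_class(
            args.samples, args.features, args.separation, seed=args.seed + i
        )
        row = {}
        for enc in ("log2n", "nqubit"):
            rep = cross_validate(data, args.classifier, enc, cfg)
            results[enc].append(rep.mean_auc)
            row[enc] = rep.mean_auc
        print(f"seed {args.seed + i:3d}  log2n {row['log2n']:.3f}  "
              f"nqubit {row['nqubit']:.3f}")
    m_log, m_n = np.mean(results["log2n"]), np.mean(results["nqubit"])
    wins = int(np.sum(np.array(results["log2n"]) >= np.array(results["nqubit"])))
    print(f"\nmean AUC: log2n {m_log:.3f}   nqubit {m_n:.3f}   "
          f"(log2n >= nqubit in {wins}/{args.datasets} datasets)")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
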