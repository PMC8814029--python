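#!/usr/bin/env python
"""Optional: evaluate a downloaded clinical CSV with the full method grid.

Not an acceptance surface — fold splits and the published feature-ranking
method are not fully specified, so published AUC tables are not expected to
be reproduced exactly.

The input must be a numeric CSV with a binary label column, e.g. the UCI
Wisconsin Diagnostic data after mapping the diagnosis column to 0/1.

Usage:
    python scripts/real_data_eval.py data.csv --label-column label \
        --features 8 16 --classifiers qdc sqksvm qksvm-ref
"""

from __future__ import annotations

import argparse

from qclin.pipeline import CVConfig, cross_validate, imbalance_ratio, load_csv


def main() -> int:
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("csv_path")
    p.add_argument("--label-column", default="label")
    p.add_argument("--features", type=int, nargs="+", default=[8])
    p.add_argument("--classifiers", nargs="+",
                   default=["qdc", "sqksvm", "qksvm-ref"])
    p.add_argument("--encodings", nargs="+", default=["log2n"])
    p.add_argument("--folds", type=int, default=10)
    p.add_argument("--seed", type=int, default=0)
    p.add_argument("--gcq", action="store_true")
    args = p.parse_args()

    data = load_csv(args.csv_path, label_column=args.label_column)
    print(f"{data.n_samples} samples, {data.n_features} features, "
          f"IR = {imbalance_ratio(data.labels):.2f}\n")
    print(f"{'classifier':<12}{'encoding':<10}{'#feat':<7}{'mean AUC':<10}{'gcq'}")
    for k in args.features:
        for enc in args.encodings:
            for clf in args.classifiers:
                cfg = CVConfig(n_folds=args.folds, n_features=k, seed=args.seed)
                rep = cross_validate(data, clf, enc, cfg, compute_gcq=args.gcq)
                gcq = "-" if rep.gcq is None else f"{rep.gcq:.2f}"
                print(f"{clf:<12}{enc:<10}{rep.n_features:<7}"
                      f"{rep.mean_auc:<10.3f}{gcq}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
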