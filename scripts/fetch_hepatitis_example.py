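#!/usr/bin/env python
"""Optional real-data demo: two-phase stratification of a large survival
cohort (OpenML data id 269, "BNG(hepatitis)", ~1e6 rows).

Requires network access; nothing in the package or test suite depends on
it.  Downloads the data, keeps sex as the stratum feature and four
continuous predictors (albumin, alkaline phosphatase, prothrombin time,
age), draws a biased learning set of n=2000 via two-phase selection
(enriching death and the rarer sex), holds out 10,000 unbiased test rows,
and compares the seven corrections for a chosen classifier by test AUC.

Usage: python scripts/fetch_hepatitis_example.py --classifier logistic --out results/hepatitis
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from twophase import auc, fit_corrected, two_phase_sample
from twophase.correctors import METHODS


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--classifier", default="logistic")
    ap.add_argument("--trees", type=int, default=500)
    ap.add_argument("--m", type=int, default=100)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, required=True)
    args = ap.parse_args()

    from sklearn.datasets import fetch_openml  # network access happens here

    ds = fetch_openml(data_id=269, as_frame=True)
    df = ds.frame
    keep = ["SEX", "ALBUMIN", "ALK_PHOSPHATE", "PROTIME", "AGE", "Class"]
    df = df[keep].dropna().reset_index(drop=True)
    df["y"] = (df.pop("Class").astype(str).str.upper() == "DIE").astype(int)
    sex = df.pop("SEX").astype(str)
    df["x_e"] = (sex == sex.value_counts().idxmin()).astype(int)  # rarer sex = exposed

    rng = np.random.default_rng(args.seed)
    test_idx = rng.choice(len(df), size=10_000, replace=False)
    test = df.iloc[test_idx]
    population = df.drop(index=df.index[test_idx]).reset_index(drop=True)

    learn, table = two_phase_sample(population, 2000, seed=args.seed + 1)
    print(table.table)

    results = {}
    for method in METHODS:
        scorer = fit_corrected(learn, table, correction=method,
                               classifier=args.classifier, m=args.m,
                               n_trees=args.trees, seed=args.seed + 2)
        results[method] = auc(scorer.predict_score(test), test["y"].to_numpy())
        print(f"{method:30s} AUC = {results[method]:.4f}")

    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "aucs.json").write_text(json.dumps(results, indent=2) + "\n")


if __name__ == "__main__":
    main()
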