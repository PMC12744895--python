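#!/usr/bin/env python
"""Simulate the study cohort and compare pCR vs non-pCR groups.

Draws a 56-patient cohort (30 non-pCR / 26 pCR) whose kinetic features
follow the published group distributions, then runs the group-comparison
battery: Wilcoxon rank-sum per continuous feature, chi-square per clinical
covariate, and single-feature ROC AUC with a bootstrap CI — the analogue of
the study's group-difference tables.
"""

import argparse
from pathlib import Path

import kmcdce as K
from kmcdce.pipeline import comparisons_to_frame, run_cohort


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-boot", type=int, default=1000)
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = K.generate_cohort(K.CohortSpec(seed=args.seed))
    cohort.to_csv(args.out / "cohort.csv", index=False, float_format="%.6g")
    comparisons, _ = run_cohort(cohort, n_boot=args.n_boot, seed=args.seed,
                                families=())
    frame = comparisons_to_frame(comparisons)
    frame.to_csv(args.out / "group_comparisons.csv", index=False,
                 float_format="%.4g")

    kbpe = frame[frame.feature.str.startswith("kBPE_")]
    print("kBPE I/C group comparisons (non-pCR vs pCR):")
    print(kbpe[["feature", "nonpCR_mean", "pCR_mean", "p_value", "auc"]]
          .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    sig = kbpe[kbpe.p_value < 0.05].feature.tolist()
    print(f"\nsignificant at p<0.05: {sig}")
    print(f"outputs in {args.out}")


if __name__ == "__main__":
    main()
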