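#!/usr/bin/env python
"""Run the per-patient kinetic pipeline on the asymmetric phantom.

Regenerates the phantom of 01_build_phantom.py (same seed) and runs the
whole chain: voxelwise two-parameter enhancement fits, K = 5 clustering of
the A*alpha map per region, cluster-curve three-parameter fits with AUC30,
concentration conversion, extended Tofts fits, and the weighted
average / I/C summary. Reports how well the recovered A*alpha I/C matches
the imposed ground truth of 1.4.
"""

import argparse
from pathlib import Path

import pandas as pd

import kmcdce as K


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/patient"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    spec = K.PhantomSpec(seed=args.seed, asymmetry_r=1.4, noise="rician",
                         noise_sd_frac=0.02)
    series, labels, truth = K.generate_phantom(spec)
    patient, inter = K.analyze_patient(series, labels,
                                       K.PipelineConfig(seed=args.seed),
                                       patient_id=f"phantom-{args.seed}")

    inter["cluster_table"].to_csv(args.out / "cluster_fits.csv", index=False,
                                  float_format="%.12g")
    pd.DataFrame([patient.to_row()]).to_csv(args.out / "patient_summary.csv",
                                            index=False, float_format="%.12g")

    print("per-cluster voxel counts:")
    print(inter["cluster_table"][["region", "cluster", "n_voxels"]]
          .pivot(index="cluster", columns="region", values="n_voxels")
          .to_string())
    print("\nbilateral asymmetry (I/C) of the weighted parenchymal averages:")
    for p in ("A", "alpha", "A_alpha", "AUC30", "Ktrans", "ve", "Kep"):
        ic = patient.values[p]["IC"]
        print(f"  {p:8s} I/C = {ic:.4f}")
    got = patient.values["A_alpha"]["IC"]
    print(f"\nimposed A*alpha I/C = {spec.asymmetry_r}, recovered = "
          f"{got:.3f} ({100 * abs(got - spec.asymmetry_r) / spec.asymmetry_r:.1f}% off)")
    print(f"tumor volume: {patient.tumor_volume_cm3:.2f} cm^3")
    print(f"outputs in {args.out}")


if __name__ == "__main__":
    main()
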