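"""Phenotype every animal's 3-point-bending curve and check recovery.

Each animal's simulated force-displacement record (noise 0.5% of ultimate
force) is analyzed for stiffness, yield and ultimate force, post-yield
displacement and work-to-fracture; material properties come from beam theory
with section properties estimated from the morphology traits.  Because the
cohort is synthetic, the analyzed values can be compared with the generative
ground truth: the median relative recovery error per parameter is printed.
"""

import argparse

import numpy as np
import pandas as pd

from osteophen.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/pipeline")
    args = ap.parse_args()

    cfg = PipelineConfig(
        out_dir=args.out, seed=args.seed,
        heritability=False, adjustment=False, correlations=False,
        pca=False, raman=False, posthoc=False,
    )
    report = run_pipeline(cfg)
    truth = pd.read_csv(report.manifest["cohort"]).set_index("animal_id")
    mech = pd.read_csv(report.manifest["mechanics"])
    mech["error"] = mech["error"].fillna("")
    mech["flags"] = mech.get("flags", "").fillna("")
    ok = mech[mech["error"] == ""].set_index("curve_id")
    print(f"analyzed {len(ok)}/{len(mech)} curves")
    print("median relative recovery error vs generative truth:")
    for col in ("K", "Fy", "Fu", "PYD"):
        t = truth.loc[ok.index, col]
        rel = ((ok[col] - t).abs() / t.abs()).median()
        print(f"  {col:>4}: {100 * rel:.2f}%")
    print("(truth values clamped into the admissible region — Fy <= 0.95 Fu, "
          "PYD >= 0.02 mm — before curve synthesis; errors are vs clamped truth "
          "where applicable)")
    print(f"curves with flags: {int((ok['flags'] != '').sum())}")


if __name__ == "__main__":
    main()
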