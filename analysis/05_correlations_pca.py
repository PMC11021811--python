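"""Trait correlation structure, lacunar clustering, founder PCA and DO
projection.

Computes Pearson correlation matrices (founders and DO separately) with a
P > 0.05 significance mask, clusters the lacunar traits into 3 groups with
Ward.D2 on d = 1 - r, fits a PCA on the standardized founder panel, projects
the DO animals onto the founder PC space, and draws the PC1-PC2 scatter with
1-SD strain ellipses.  Prints the explained variance of the leading PCs, the
top PC1/PC2 loadings and the fraction of DO projections inside the founder
convex hull.
"""

import argparse

import ast

import pandas as pd
from scipy.spatial import Delaunay

from osteophen import multivar, plots
from osteophen.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/pipeline")
    args = ap.parse_args()

    cfg = PipelineConfig(
        out_dir=args.out, seed=args.seed,
        heritability=False, adjustment=False, posthoc=False,
    )
    report = run_pipeline(cfg)

    explained = pd.read_csv(report.manifest["pca_explained"], index_col=0)["explained"]
    print("explained variance: " + ", ".join(
        f"{pc} {100 * v:.1f}%" for pc, v in explained.head(4).items()))
    print(f"PC1+PC2 together: {100 * explained.iloc[:2].sum():.1f}%")

    loadings = pd.read_csv(report.manifest["pca_loadings"], index_col=0)
    for pc in ("PC1", "PC2"):
        top = loadings[pc].abs().nlargest(5).index.tolist()
        print(f"top {pc} contributors: {', '.join(top)}")

    scores = pd.read_csv(report.manifest["pca_scores"], index_col=0)
    founders = scores[scores["population"] == "founder"]
    do = scores[scores["population"] == "DO"]
    if not do.empty:
        tri = Delaunay(founders[["PC1", "PC2"]].to_numpy())
        inside = tri.find_simplex(do[["PC1", "PC2"]].to_numpy()) >= 0
        print(f"DO projections inside founder PC1-PC2 hull: "
              f"{inside.sum()}/{len(inside)} ({100 * inside.mean():.0f}%)")
        print(f"DO PC1-PC2 SD vs founder SD: "
              f"{do['PC1'].std() / founders['PC1'].std():.2f}, "
              f"{do['PC2'].std() / founders['PC2'].std():.2f} (smaller, central region)")

    clusters = pd.read_csv(report.manifest["lacunar_clusters"], index_col=0)["cluster"]
    print("lacunar trait clusters (Ward.D2, k=3):")
    for c in sorted(clusters.unique()):
        print(f"  group {c}: {', '.join(clusters.index[clusters == c])}")

    # figures
    cohort = pd.read_csv(report.manifest["cohort_analyzed"])
    panel = [t for t in cfg.pca_traits if t in cohort.columns]
    corr = multivar.pearson_matrix(cohort[cohort["population"] == "founder"], panel)
    plots.correlation_heatmap(corr, f"{report.out_dir}/corr_founder.png",
                              "Founder radial + whole-body traits")
    ell = pd.read_csv(report.manifest["pca_ellipses"])
    ellipses = [
        multivar.EllipseSpec(r.group, ast.literal_eval(r.center), ast.literal_eval(r.axes), r.angle_deg,
                             r.level, r.degenerate)
        for r in ell.itertuples()
    ]
    plots.pca_scatter(scores, scores["strain"], ellipses,
                      f"{report.out_dir}/pca_scatter.png",
                      "Founder strains and projected DO animals")
    print(f"figures written to {report.out_dir}/corr_founder.png, pca_scatter.png")


if __name__ == "__main__":
    main()
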