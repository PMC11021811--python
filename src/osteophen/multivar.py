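"""Trait correlation, hierarchical clustering, founder PCA and DO projection.

Pairwise-complete Pearson correlation matrices with a significance mask
(nonsignificant at P > 0.05), Ward.D2 agglomerative clustering of traits on
the distance d = 1 - r, principal component analysis of standardized founder
traits (prcomp convention: center to mean 0, scale to SD 1), projection of
new (outbred) animals onto the founder-defined component space, and 1-SD
normal data ellipses for group visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import DesignError, ValidationError

__all__ = [
    "CorrelationMatrix",
    "PCAModel",
    "EllipseSpec",
    "pearson_matrix",
    "cluster_traits",
    "fit_pca",
    "project_onto_pca",
    "normal_ellipse",
]


@dataclass
class CorrelationMatrix:
    traits: list[str]
    r: pd.DataFrame  # symmetric, unit diagonal; NaN where unavailable
    p: pd.DataFrame  # two-sided t-test p; 0 on the diagonal
    n: pd.DataFrame  # pairwise-complete counts
    mask: pd.DataFrame  # True where p > alpha (nonsignificant)
    alpha: float = 0.05
    unavailable: list[tuple[str, str]] = field(default_factory=list)


def pearson_matrix(
    table: pd.DataFrame, traits: list[str], alpha: float = 0.05, min_pairs: int = 3
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations with significance mask.

    Pairs with fewer than ``min_pairs`` complete observations, or involving a
    constant trait, are marked unavailable (NaN) and listed.
    """
    missing = [t for t in traits if t not in table.columns]
    if missing:
        raise DesignError(f"traits absent from table: {missing}")
    k = len(traits)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    unavailable: list[tuple[str, str]] = []
    cols = {t: table[t].to_numpy(dtype=float) for t in traits}
    for i, ti in enumerate(traits):
        n[i, i] = int(np.isfinite(cols[ti]).sum())
        for j in range(i + 1, k):
            tj = traits[j]
            x, y = cols[ti], cols[tj]
            m = np.isfinite(x) & np.isfinite(y)
            n[i, j] = n[j, i] = int(m.sum())
            if m.sum() < min_pairs or np.std(x[m]) == 0 or np.std(y[m]) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                unavailable.append((ti, tj))
                continue
            res = stats.pearsonr(x[m], y[m])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = list(traits)
    rdf = pd.DataFrame(r, index=idx, columns=idx)
    pdf = pd.DataFrame(p, index=idx, columns=idx)
    mask = (pdf > alpha) & np.isfinite(rdf)
    np.fill_diagonal(mask.values, False)
    return CorrelationMatrix(
        idx, rdf, pdf, pd.DataFrame(n, index=idx, columns=idx), mask, alpha, unavailable
    )


def cluster_traits(
    corr: CorrelationMatrix, k: int, signed: bool = True
) -> pd.Series:
    """Cut a Ward.D2 hierarchy of traits at k clusters.

    Traits are clustered on the dissimilarity d = 1 - r (``signed=False``
    uses 1 - |r|); the linkage applies the Ward.D2 (squared-distance
    Lance-Williams) update, matching R ``hclust(..., method="ward.D2")``.
    Cluster labels are renumbered 1..k in order of first appearance over the
    trait order, so the labeling is deterministic.
    """
    if not 1 <= k <= len(corr.traits):
        raise ValidationError(f"k must lie in [1, {len(corr.traits)}], got {k}")
    rmat = corr.r.to_numpy(dtype=float).copy()
    if np.isnan(rmat).any():
        bad = corr.unavailable
        raise ValidationError(
            f"correlation entries unavailable for {bad}; impute or drop those traits"
        )
    d = 1.0 - (np.abs(rmat) if not signed else rmat)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    z = linkage(squareform(d, checks=False), method="ward")
    raw = fcluster(z, t=k, criterion="maxclust")
    order: dict[int, int] = {}
    labels = []
    for lab in raw:
        if lab not in order:
            order[lab] = len(order) + 1
        labels.append(order[lab])
    return pd.Series(labels, index=corr.traits, name="cluster")


@dataclass
class PCAModel:
    traits: list[str]
    center: pd.Series  # per-trait founder means
    scale: pd.Series  # per-trait founder SDs (ddof=1)
    weightings: pd.DataFrame  # traits x PCs, orthonormal columns
    explained: np.ndarray  # variance proportions, nonincreasing, sums to 1
    scores: pd.DataFrame  # fitted animal coordinates (index = animal_id)
    n_fit: int = 0


def fit_pca(table: pd.DataFrame, traits: list[str]) -> PCAModel:
    """PCA of standardized traits (prcomp convention).

    Complete cases only; each trait is centered to mean 0 and scaled to SD 1
    (ddof=1) before a singular-value decomposition.  Each weighting column is
    sign-flipped so its largest-magnitude entry is positive, making runs
    comparable (component signs are otherwise arbitrary).
    """
    missing = [t for t in traits if t not in table.columns]
    if missing:
        raise DesignError(f"traits absent from table: {missing}")
    sub = table[traits].dropna()
    if len(sub) < len(traits) + 1:
        raise DesignError(
            f"need at least {len(traits) + 1} complete cases, got {len(sub)}"
        )
    center = sub.mean()
    scale = sub.std(ddof=1)
    constant = scale[scale <= 0].index.tolist()
    if constant:
        raise DesignError(f"constant trait(s): {constant}")
    x = ((sub - center) / scale).to_numpy()
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    ncomp = min(len(sub) - 1, len(traits))
    u, s, vt = u[:, :ncomp], s[:ncomp], vt[:ncomp]
    w = vt.T
    flip = np.sign(w[np.argmax(np.abs(w), axis=0), np.arange(ncomp)])
    flip[flip == 0] = 1.0
    w = w * flip
    scores = u * s * flip
    lam = s**2
    pcs = [f"PC{i + 1}" for i in range(ncomp)]
    idx = (
        table.loc[sub.index, "animal_id"]
        if "animal_id" in table.columns
        else sub.index
    )
    return PCAModel(
        traits=list(traits),
        center=center,
        scale=scale,
        weightings=pd.DataFrame(w, index=traits, columns=pcs),
        explained=lam / lam.sum(),
        scores=pd.DataFrame(scores, index=pd.Index(idx, name="animal_id"), columns=pcs),
        n_fit=len(sub),
    )


def project_onto_pca(model: PCAModel, table: pd.DataFrame) -> pd.DataFrame:
    """Project rows onto a fitted founder PC space (no refitting).

    Each animal's traits are centered and scaled with the founder parameters
    and linearly combined with the founder PC weightings.  Rows missing any
    model trait are skipped (logged in ``attrs['skipped']``).  Projecting the
    training rows reproduces the fitted scores.
    """
    missing = [t for t in model.traits if t not in table.columns]
    if missing:
        raise DesignError(f"traits absent from table: {missing}")
    sub = table[model.traits]
    complete = sub.notna().all(axis=1)
    x = ((sub[complete] - model.center) / model.scale).to_numpy()
    scores = x @ model.weightings.to_numpy()
    idx = (
        table.loc[complete[complete].index, "animal_id"]
        if "animal_id" in table.columns
        else sub[complete].index
    )
    out = pd.DataFrame(scores, index=pd.Index(idx, name="animal_id"),
                       columns=model.weightings.columns)
    out.attrs["skipped"] = int((~complete).sum())
    return out


@dataclass(frozen=True)
class EllipseSpec:
    group: str
    center: tuple[float, float]
    axes: tuple[float, float]  # semi-axis lengths, descending
    angle_deg: float  # orientation of the major axis
    level: float = 1.0
    degenerate: bool = False


def normal_ellipse(
    scores: pd.DataFrame | np.ndarray,
    groups,
    level: float = 1.0,
    cols: tuple[str, str] = ("PC1", "PC2"),
) -> list[EllipseSpec]:
    """Per-group normal data ellipses spanning ``level`` SD.

    The ellipse is the Mahalanobis contour {x : (x-mu)' Sigma^-1 (x-mu) =
    level^2} of the group's sample mean and covariance; semi-axes are
    level * sqrt(eigenvalues), the angle comes from the leading eigenvector.
    Groups with fewer than 3 points or a singular covariance are flagged
    degenerate.
    """
    if isinstance(scores, pd.DataFrame):
        xy = scores[list(cols)].to_numpy(dtype=float)
    else:
        xy = np.asarray(scores, dtype=float)[:, :2]
    groups = np.asarray(groups)
    out = []
    for g in pd.unique(groups):
        pts = xy[groups == g]
        if len(pts) < 3:
            raise ValidationError(f"group {g!r}: need >= 3 points, got {len(pts)}")
        mu = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        degenerate = evals[-1] <= 1e-12 * max(evals[0], 1.0)
        angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
        out.append(
            EllipseSpec(
                group=str(g),
                center=(float(mu[0]), float(mu[1])),
                axes=(float(level * np.sqrt(max(evals[0], 0.0))),
                      float(level * np.sqrt(max(evals[1], 0.0)))),
                angle_deg=angle,
                level=level,
                degenerate=bool(degenerate),
            )
        )
    return out
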