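"""Ontogeny classification from habitat-guild diet profiles.

Two complementary views of whether juvenile and mature fish split into
distinct feeding groups:

* Ward minimum-variance hierarchical clustering (Euclidean distance) of
  per-fish guild percentage profiles, cut at two clusters and cross-tabulated
  against maturity; and
* two-group canonical discriminant analysis on arcsine-square-root
  transformed guild percentages: the single canonical eigenvalue lambda_1,
  Wilks' Lambda = 1/(1 + lambda_1), its F approximation with df (p, N-p-1),
  per-variable F-to-remove, structure correlations with the canonical axis,
  and a resubstitution classification table from the linear discriminant
  rule with group-size-proportional priors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import f as f_dist

from .core import DietTable, ValidationError

__all__ = ["arcsine_transform", "guild_percent_profiles", "ClusterResult",
           "ward_two_clusters", "DfaResult", "dfa_two_group",
           "wilks_from_eigenvalue", "f_from_wilks"]


def wilks_from_eigenvalue(eigenvalue: float) -> float:
    """Wilks' Lambda of a two-group discriminant with canonical eigenvalue
    lambda_1: Lambda = 1/(1 + lambda_1)."""
    if eigenvalue < 0:
        raise ValidationError("canonical eigenvalue must be >= 0")
    return 1.0 / (1.0 + eigenvalue)


def f_from_wilks(wilks: float, p: int, n: int) -> tuple[float, tuple[int, int], float]:
    """F approximation of a two-group Wilks' Lambda with p variables and N
    observations: F = ((1 - L)/L) (N - p - 1)/p on df (p, N - p - 1).
    Returns (F, (df1, df2), p-value)."""
    if not (0 < wilks <= 1):
        raise ValidationError("Wilks' Lambda must be in (0, 1]")
    df1, df2 = p, n - p - 1
    if df2 <= 0:
        raise ValidationError("need N > p + 1")
    f_stat = (1.0 - wilks) / wilks * (df2 / df1)
    return f_stat, (df1, df2), float(f_dist.sf(f_stat, df1, df2))


def arcsine_transform(pct):
    """Variance-stabilising arcsin(sqrt(pct/100)); input in [0, 100],
    output in [0, pi/2] radians."""
    a = np.asarray(pct, dtype=float)
    if (a < 0).any() or (a > 100).any():
        raise ValidationError("percentages must lie in [0, 100]")
    out = np.arcsin(np.sqrt(a / 100.0))
    return out if out.shape else float(out)


def guild_percent_profiles(table: DietTable, include_empty: bool = False,
                           drop: tuple[str, ...] = ()) -> pd.DataFrame:
    """Per-fish guild percentages (rows sum to 100) from a guild-aggregated
    table.  Empty fish are excluded by default (all-zero profiles otherwise).
    """
    t = table if include_empty else table.non_empty()
    bm = t.biomass.drop(columns=list(drop), errors="ignore")
    totals = bm.sum(axis=1)
    pct = bm.div(totals.where(totals > 0, 1.0), axis=0) * 100.0
    return pct


@dataclass(frozen=True)
class ClusterResult:
    """Two-cluster Ward solution cross-tabulated against maturity.

    ``heights`` are variance increments (the increase in total within-cluster
    sum of squares at each merge); ``misclassified`` counts, per group, the
    fish falling outside their group's majority cluster.
    """

    linkage: np.ndarray
    heights: np.ndarray
    assignment: pd.Series
    crosstab: pd.DataFrame
    misclassified: dict[str, int]
    degenerate: bool


def ward_two_clusters(profiles: pd.DataFrame, labels: pd.Series) -> ClusterResult:
    """Ward clustering of per-fish profiles, cut at two clusters.

    ``profiles``: fish x variables (e.g. guild percentages), indexed by
    fish_id; ``labels``: maturity group per fish (same index).
    """
    if profiles.index.duplicated().any():
        raise ValidationError("duplicate fish ids in profiles")
    if len(profiles) < 2:
        raise ValidationError("need >= 2 fish to cluster")
    x = profiles.to_numpy(dtype=float)
    labels = pd.Series(labels).reindex(profiles.index)
    z = linkage(x, method="ward")
    # scipy's ward heights h relate to the ESS increase by dESS = h^2 / 2
    heights = z[:, 2] ** 2 / 2.0
    degenerate = bool(np.allclose(z[:, 2], 0.0))
    cut = fcluster(z, t=2, criterion="maxclust")
    if degenerate or len(np.unique(cut)) == 1:
        # identical profiles: deterministic arbitrary split on input order
        cut = np.ones(len(x), dtype=int)
        cut[-1] = 2
        degenerate = True
    assignment = pd.Series(cut, index=profiles.index, name="cluster")
    crosstab = pd.crosstab(assignment, labels)
    mis = {}
    for g in crosstab.columns:
        majority = crosstab[g].idxmax()
        mis[g] = int(crosstab[g].sum() - crosstab.loc[majority, g])
    return ClusterResult(linkage=z, heights=heights, assignment=assignment,
                         crosstab=crosstab, misclassified=mis,
                         degenerate=degenerate)


@dataclass(frozen=True)
class DfaResult:
    """Two-group canonical discriminant analysis summary."""

    eigenvalue: float
    wilks: float
    f: float
    df: tuple[int, int]
    p: float
    structure_corr: pd.Series
    partial: pd.DataFrame       # per variable: wilks_without, f_remove, p
    scores: pd.Series           # canonical scores per fish
    classification: pd.DataFrame
    pct_correct: float


def _wilks_two_group(x: np.ndarray, g: np.ndarray) -> float:
    """Wilks' Lambda for two groups = 1/(1 + lambda_1) via the within-scatter
    solve; raises on singular within-group scatter."""
    n = len(x)
    means = {}
    w = np.zeros((x.shape[1], x.shape[1]))
    for lab in np.unique(g):
        xg = x[g == lab]
        means[lab] = xg.mean(axis=0)
        c = xg - xg.mean(axis=0)
        w += c.T @ c
    labs = sorted(means)
    d = means[labs[0]] - means[labs[1]]
    n1 = int((g == labs[0]).sum())
    n2 = int((g == labs[1]).sum())
    try:
        wd = np.linalg.solve(w, d)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "singular within-group scatter; remove constant or collinear "
            "variables") from exc
    lam1 = (n1 * n2 / n) * float(d @ wd)
    if lam1 < 0:
        lam1 = 0.0
    return 1.0 / (1.0 + lam1)


def dfa_two_group(profiles: pd.DataFrame, labels: pd.Series) -> DfaResult:
    """Canonical discriminant analysis for exactly two groups.

    ``profiles`` should already be transformed as desired (e.g. arcsine);
    requires N > p + 1 and >= 2 fish per group.
    """
    labels = pd.Series(labels).reindex(profiles.index).astype(str)
    x = profiles.to_numpy(dtype=float)
    g = labels.to_numpy()
    uniq, counts = np.unique(g, return_counts=True)
    if len(uniq) != 2:
        raise ValidationError(f"exactly two groups required, got {list(uniq)}")
    if (counts < 2).any():
        raise ValidationError("both groups need >= 2 fish")
    n, p = x.shape
    if n <= p + 1:
        raise ValidationError(f"need N > p + 1 (N={n}, p={p})")
    wilks = _wilks_two_group(x, g)
    lam1 = 1.0 / wilks - 1.0
    df1, df2 = p, n - p - 1
    f_stat = ((1.0 - wilks) / wilks) * (df2 / df1)
    p_val = float(f_dist.sf(f_stat, df1, df2))

    # canonical axis: a = W^-1 d, unit pooled within-group variance,
    # signed so the second (alphabetically) group scores positive
    w = np.zeros((p, p))
    mu = {}
    for lab in uniq:
        xg = x[g == lab]
        mu[lab] = xg.mean(axis=0)
        c = xg - mu[lab]
        w += c.T @ c
    s_pooled = w / (n - 2)
    d = mu[uniq[0]] - mu[uniq[1]]
    a = np.linalg.solve(s_pooled, d)
    a = a / np.sqrt(a @ s_pooled @ a)
    scores = x @ a
    if scores[g == uniq[1]].mean() < scores[g == uniq[0]].mean():
        a, scores = -a, -scores
    with np.errstate(invalid="ignore"):
        struct = np.array([
            np.corrcoef(x[:, j], scores)[0, 1] if x[:, j].std() > 0 else np.nan
            for j in range(p)])

    # F-to-remove from the Lambda ratio with one variable dropped
    rows = []
    for j in range(p):
        keep = [k for k in range(p) if k != j]
        if keep:
            w_wo = _wilks_two_group(x[:, keep], g)
        else:
            w_wo = 1.0
        f_rem = (w_wo / wilks - 1.0) * df2
        rows.append({"wilks_without": w_wo, "f_remove": f_rem,
                     "p": float(f_dist.sf(f_rem, 1, df2))})
    partial = pd.DataFrame(rows, index=profiles.columns)

    # linear discriminant rule, proportional priors, resubstitution
    priors = {lab: c / n for lab, c in zip(uniq, counts)}
    s_inv = np.linalg.inv(s_pooled)
    disc = np.column_stack([
        x @ (s_inv @ mu[lab]) - 0.5 * mu[lab] @ s_inv @ mu[lab]
        + np.log(priors[lab]) for lab in uniq])
    pred = uniq[np.argmax(disc, axis=1)]
    ct = pd.crosstab(pd.Series(g, name="actual"),
                     pd.Series(pred, name="predicted")).reindex(
        index=uniq, columns=uniq, fill_value=0)
    pct_correct = 100.0 * float(np.mean(pred == g))
    return DfaResult(
        eigenvalue=lam1, wilks=wilks, f=float(f_stat), df=(df1, df2),
        p=p_val, structure_corr=pd.Series(struct, index=profiles.columns),
        partial=partial,
        scores=pd.Series(scores, index=profiles.index, name="canonical_score"),
        classification=ct, pct_correct=pct_correct)
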