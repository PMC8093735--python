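"""Community-level comparison of per-fish diets.

Bray-Curtis dissimilarity d(x, y) = sum|x_c - y_c| / sum(x_c + y_c) between
fish (rows scaled to proportions by default, so the comparison is of diet
composition rather than ration size), one-way ANOSIM with a seeded
permutation p-value (exhaustive enumeration when the number of distinct
two-group relabelings is within the permutation budget), and the SIMPER
decomposition of the average between-group dissimilarity into per-category
contributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .core import DietTable, ValidationError

__all__ = ["bray_curtis", "AnosimResult", "anosim", "anosim_r",
           "SimperTable", "simper", "simper_from_average"]


def _scaled_matrix(table: DietTable, scale: str) -> tuple[np.ndarray, pd.Index]:
    if scale not in ("proportions", "raw"):
        raise ValueError(f"unknown scale {scale!r}")
    ne = table.non_empty()
    if len(ne) < 2:
        raise ValidationError("need >= 2 non-empty fish")
    x = ne.biomass.to_numpy(dtype=float)
    if scale == "proportions":
        x = x / x.sum(axis=1, keepdims=True)
    return x, ne.biomass.index


def bray_curtis(table: DietTable, scale: str = "proportions") -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between non-empty fish, in [0, 1]."""
    x, ids = _scaled_matrix(table, scale)
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def anosim_r(dm: np.ndarray | pd.DataFrame, labels) -> float:
    """Clarke's R: (mean between-group rank - mean within-group rank)
    divided by N(N-1)/4, ranks over the condensed distances with ties
    averaged.  R is in [-1, 1]; ~0 means no separation."""
    d = np.asarray(dm, dtype=float)
    labels = np.asarray(labels)
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])
    within = labels[iu[0]] == labels[iu[1]]
    if within.all() or not within.any():
        raise ValidationError("ANOSIM needs >= 2 groups with >= 2 members")
    return float((ranks[~within].mean() - ranks[within].mean())
                 / (n * (n - 1) / 4.0))


@dataclass(frozen=True)
class AnosimResult:
    r: float
    p: float
    n_perm: int
    exhaustive: bool
    seed: int | None


def anosim(table_or_dm, labels=None, n_perm: int = 9999,
           seed: int | None = None, scale: str = "proportions",
           exact: bool | None = None) -> AnosimResult:
    """One-way ANOSIM on a DietTable (Bray-Curtis) or a precomputed
    dissimilarity matrix.

    p = (# permutations with R >= R_obs + 1) / (n_perm + 1) under random
    relabeling with group sizes preserved.  For two groups, when the number
    of distinct relabelings C(N, n1) is <= n_perm the null is enumerated
    exactly and p = (# >= R_obs) / total (the identity relabeling included).
    ``exact`` forces enumeration (True; error when infeasible) or sampling
    (False); None picks automatically as above.
    """
    if isinstance(table_or_dm, DietTable):
        dm = bray_curtis(table_or_dm, scale)
        labels = table_or_dm.non_empty().group_labels().reindex(dm.index)
        d = dm.to_numpy()
        labels = labels.to_numpy()
    else:
        if labels is None:
            raise ValueError("labels required with a precomputed matrix")
        d = np.asarray(table_or_dm, dtype=float)
        labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("ANOSIM needs >= 2 groups")
    if (counts < 2).any():
        raise ValidationError("every group needs >= 2 members")
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])
    denom = n * (n - 1) / 4.0

    def r_of(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return float((ranks[~within].mean() - ranks[within].mean()) / denom)

    r_obs = r_of(labels)
    can_enumerate = len(uniq) == 2 and comb(n, int(counts[0])) <= n_perm
    if exact is True and not (len(uniq) == 2):
        raise ValidationError("exact enumeration implemented for two groups")
    exhaustive = can_enumerate if exact is None else exact
    if exhaustive:
        g0 = uniq[0]
        total = 0
        ge = 0
        for idx in combinations(range(n), int(counts[0])):
            lab = np.full(n, uniq[1], dtype=labels.dtype)
            lab[list(idx)] = g0
            total += 1
            if r_of(lab) >= r_obs - 1e-12:
                ge += 1
        return AnosimResult(r=r_obs, p=ge / total, n_perm=total,
                            exhaustive=True, seed=seed)
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        if r_of(rng.permutation(labels)) >= r_obs - 1e-12:
            ge += 1
    return AnosimResult(r=r_obs, p=(ge + 1) / (n_perm + 1), n_perm=n_perm,
                        exhaustive=False, seed=seed)


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimperTable:
    """Per-category decomposition of the average between-group Bray-Curtis
    dissimilarity, sorted by contribution; percentages are on the 0-100
    scale (avg_dissim sums to 100 x the mean between-group dissimilarity).
    ``degenerate`` flags an all-zero decomposition (identical groups)."""

    table: pd.DataFrame
    overall_dissimilarity: float
    degenerate: bool


def simper(table: DietTable, groups: tuple[str, str],
           scale: str = "proportions") -> SimperTable:
    """SIMPER: average each category's share |x_c - y_c| / sum(x + y) of the
    Bray-Curtis dissimilarity over all between-group fish pairs."""
    if scale not in ("proportions", "raw"):
        raise ValueError(f"unknown scale {scale!r}")
    gx, gy = groups
    cats = table.categories

    def group_matrix(g: str) -> np.ndarray:
        m = table.subset(g).non_empty().biomass.to_numpy(dtype=float)
        if len(m) == 0:
            raise ValidationError(f"group {g!r} has no non-empty fish")
        if scale == "proportions":
            m = m / m.sum(axis=1, keepdims=True)
        return m

    x = group_matrix(gx)
    y = group_matrix(gy)
    # pairwise |x_c - y_c| and totals, averaged over all between-group pairs
    diff = np.abs(x[:, None, :] - y[None, :, :])           # (nx, ny, C)
    tot = (x.sum(axis=1)[:, None] + y.sum(axis=1)[None, :])  # (nx, ny)
    contrib = (diff / tot[:, :, None]).mean(axis=(0, 1)) * 100.0
    overall = float(contrib.sum())
    degenerate = overall <= 1e-12
    if degenerate:
        pct = np.zeros_like(contrib)
    else:
        pct = 100.0 * contrib / overall
    out = pd.DataFrame({
        "avg_dissim": contrib,
        "contribution_pct": pct,
        f"mean_{gx}": x.mean(axis=0) * (100.0 if scale == "proportions" else 1.0),
        f"mean_{gy}": y.mean(axis=0) * (100.0 if scale == "proportions" else 1.0),
    }, index=pd.Index(cats, name="category"))
    out = out.sort_values("contribution_pct", ascending=False)
    out["cumulative_pct"] = out["contribution_pct"].cumsum()
    return SimperTable(table=out, overall_dissimilarity=overall / 100.0,
                       degenerate=degenerate)


def simper_from_average(avg_dissim: pd.Series,
                        total: float | None = None) -> pd.DataFrame:
    """Rebuild contribution% and cumulative% from per-category average
    dissimilarities, e.g. from a published (possibly truncated) SIMPER table.

    ``total`` is the overall average dissimilarity on the same scale; when
    None the listed categories are assumed exhaustive (total = their sum).
    """
    avg = pd.Series(avg_dissim, dtype=float)
    tot = float(avg.sum()) if total is None else float(total)
    if tot <= 0:
        raise ValidationError("total dissimilarity must be positive")
    out = pd.DataFrame({"avg_dissim": avg})
    out["contribution_pct"] = 100.0 * out["avg_dissim"] / tot
    out = out.sort_values("contribution_pct", ascending=False)
    out["cumulative_pct"] = out["contribution_pct"].cumsum()
    return out
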