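"""Trophic niche breadth, diet overlap, and resampling uncertainty.

Breadth indices on a composition p (biomass proportions):

  S   richness (number of categories with p_i > 0)
  D   Simpson dominance  sum p_i^2
  B   Levins breadth     1 / sum p_i^2
  H'  Shannon diversity  -sum p_i log p_i   (log base configurable)
  Ba  standardised Levins  (B - 1) / (S - 1)
  J'  Pielou evenness      H' / log S

Overlap between two compositions p, q:

  Schoener alpha = 1 - 0.5 sum |p_i - q_i|
  Horn Ro = [sum (p+q) log (p+q) - sum p log p - sum q log q] / (2 log 2)

Both lie in [0, 1]: 0 for disjoint diets, 1 for identical diets.  Horn's Ro
is base-invariant; 0 log 0 := 0 throughout.

Uncertainty follows the delete-one-fish jackknife (the fish is the only
replicated unit), and the two-group comparison of a breadth index is a
seeded label-permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .core import DietTable, ValidationError, composition

__all__ = [
    "NicheBreadth", "niche_breadth", "JackknifeEstimate", "jackknife",
    "schoener_alpha", "horn_ro", "OverlapResult", "overlap",
    "diversity_permutation_test", "BREADTH_INDICES",
]

_LOG_BASES = {"e": np.e, "10": 10.0, 10: 10.0, np.e: np.e, 2: 2.0, "2": 2.0}


def _log(x: np.ndarray, base) -> np.ndarray:
    b = _LOG_BASES.get(base)
    if b is None:
        b = float(base)
    return np.log(x) / np.log(b)


def _plogp(p: np.ndarray, base) -> float:
    """sum p log p with the 0 log 0 := 0 convention."""
    nz = p > 0
    return float(np.sum(p[nz] * _log(p[nz], base)))


@dataclass(frozen=True)
class NicheBreadth:
    """Niche-breadth indices of a single composition; `ba` and `j` are NaN
    for a single-category diet (S = 1), where they are undefined."""

    s: int
    d: float
    b: float
    h: float
    ba: float
    j: float


def _as_composition(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("composition must be 1-D")
    if (p < 0).any():
        raise ValidationError("composition has negative entries")
    tot = p.sum()
    if tot <= 0:
        raise ValidationError("all-zero composition")
    if abs(tot - 1.0) > 1e-9:
        p = p / tot
    return p


def niche_breadth(p, log_base="e") -> NicheBreadth:
    """Breadth indices of one composition vector (renormalised if needed)."""
    p = _as_composition(p)
    s = int(np.count_nonzero(p))
    d = float(np.sum(p ** 2))
    b = 1.0 / d
    h = -_plogp(p, log_base)
    if s > 1:
        ba = (b - 1.0) / (s - 1.0)
        j = h / float(_log(np.array([s]), log_base)[0])
    else:
        ba = float("nan")
        j = float("nan")
    return NicheBreadth(s=s, d=d, b=b, h=h, ba=ba, j=j)


BREADTH_INDICES: dict[str, Callable] = {
    "S": lambda p, base="e": float(niche_breadth(p, base).s),
    "D": lambda p, base="e": niche_breadth(p, base).d,
    "B": lambda p, base="e": niche_breadth(p, base).b,
    "H": lambda p, base="e": niche_breadth(p, base).h,
    "Ba": lambda p, base="e": niche_breadth(p, base).ba,
    "J": lambda p, base="e": niche_breadth(p, base).j,
}


# ---------------------------------------------------------------------------
# jackknife
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JackknifeEstimate:
    """Delete-one jackknife: plug-in value, pseudovalue mean and SE.

    Pseudovalues are theta_i = n theta_hat - (n-1) theta_(-i); the SE is
    sd(pseudovalues)/sqrt(n).  For a linear statistic (the mean) the
    pseudovalue mean equals the plug-in value exactly.
    """

    theta_hat: float
    jack_mean: float
    se: float
    n: int


def jackknife(statistic: Callable[[DietTable], float],
              table: DietTable) -> JackknifeEstimate:
    """Delete-one-fish jackknife of ``statistic`` over the non-empty fish."""
    ne = table.non_empty()
    ids = ne.fish_ids
    n = len(ids)
    if n < 2:
        raise ValidationError("jackknife needs >= 2 non-empty fish")
    theta = float(statistic(ne))
    pseudo = np.empty(n)
    for i, fid in enumerate(ids):
        try:
            loo = float(statistic(ne.drop_fish(fid)))
        except Exception as exc:  # noqa: BLE001 - reported with fish context
            raise ValidationError(
                f"statistic undefined after deleting fish {fid!r}: {exc}"
            ) from exc
        if not np.isfinite(loo):
            raise ValidationError(
                f"statistic undefined after deleting fish {fid!r}")
        pseudo[i] = n * theta - (n - 1) * loo
    jack_mean = float(pseudo.mean())
    se = float(pseudo.std(ddof=1) / np.sqrt(n))
    return JackknifeEstimate(theta_hat=theta, jack_mean=jack_mean, se=se, n=n)


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------

def schoener_alpha(p, q) -> float:
    """Schoener's proportional-similarity overlap, in [0, 1]."""
    p = _as_composition(p)
    q = _as_composition(q)
    if p.shape != q.shape:
        raise ValueError("compositions must share the category axis")
    return float(1.0 - 0.5 * np.abs(p - q).sum())


def horn_ro(p, q, log_base="e") -> float:
    """Horn's information-theoretic overlap, in [0, 1]; base-invariant."""
    p = _as_composition(p)
    q = _as_composition(q)
    if p.shape != q.shape:
        raise ValueError("compositions must share the category axis")
    num = _plogp(p + q, log_base) - _plogp(p, log_base) - _plogp(q, log_base)
    ro = num / (2.0 * float(_log(np.array([2.0]), log_base)[0]))
    return float(min(1.0, max(0.0, ro)))


@dataclass(frozen=True)
class OverlapResult:
    schoener: JackknifeEstimate
    horn: JackknifeEstimate


def overlap(table: DietTable, group_x: str, group_y: str,
            basis: str = "per_fish", log_base="e") -> OverlapResult:
    """Schoener and Horn overlap between two groups, with jackknife SEs.

    The jackknife deletes one fish at a time from the combined two-group
    sample, recomputing both group compositions each time.
    """
    cats = table.categories

    def stat_factory(fn):
        def stat(t: DietTable) -> float:
            px = composition(t, group_x, basis).reindex(cats).to_numpy()
            py = composition(t, group_y, basis).reindex(cats).to_numpy()
            return fn(px, py)
        return stat

    both = DietTable(
        pd.concat([table.subset(group_x).df, table.subset(group_y).df]), cats)
    sch = jackknife(stat_factory(schoener_alpha), both)
    horn = jackknife(stat_factory(lambda p, q: horn_ro(p, q, log_base)), both)
    return OverlapResult(schoener=sch, horn=horn)


# ---------------------------------------------------------------------------
# permutation comparison of breadth indices
# ---------------------------------------------------------------------------

def diversity_permutation_test(table: DietTable, index: str,
                               groups: tuple[str, str],
                               n_perm: int = 9999, seed: int | None = None,
                               basis: str = "per_fish", log_base="e",
                               resample_cap: int = 1000) -> dict:
    """Two-group permutation test of a breadth index.

    The observed statistic is |index(group x) - index(group y)|; the null
    distribution comes from ``n_perm`` random reassignments of the non-empty
    fish to the two groups with sizes preserved.  p uses the add-one
    convention (count >= observed + 1)/(n_perm + 1), so p > 0 always.
    Permutations on which the index is undefined (e.g. Ba with S = 1) are
    redrawn, up to ``resample_cap`` extra draws, with a warning.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if index not in BREADTH_INDICES:
        raise KeyError(f"unknown index {index!r}; choose from "
                       f"{sorted(BREADTH_INDICES)}")
    gx, gy = groups
    fn = BREADTH_INDICES[index]
    ne = DietTable(
        pd.concat([table.subset(gx).non_empty().df,
                   table.subset(gy).non_empty().df]), table.categories)
    bm = ne.biomass.to_numpy()
    labels = ne.group_labels().to_numpy()
    nx = int((labels == gx).sum())
    n = len(labels)
    props = bm / bm.sum(axis=1, keepdims=True)

    def stat(idx_x: np.ndarray) -> float:
        mask = np.zeros(n, dtype=bool)
        mask[idx_x] = True
        if basis == "per_fish":
            px = props[mask].mean(axis=0)
            py = props[~mask].mean(axis=0)
        else:
            px = bm[mask].sum(axis=0)
            py = bm[~mask].sum(axis=0)
            px = px / px.sum()
            py = py / py.sum()
        return abs(fn(px, log_base) - fn(py, log_base))

    obs = stat(np.flatnonzero(labels == gx))
    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    redraws = 0
    while done < n_perm:
        perm = rng.permutation(n)[:nx]
        val = stat(perm)
        if not np.isfinite(val):
            redraws += 1
            if redraws > resample_cap:
                raise ValidationError(
                    f"index {index!r} undefined on > {resample_cap} permuted "
                    "splits; test not meaningful for these data")
            continue
        if val >= obs - 1e-12:
            count += 1
        done += 1
    if redraws:
        warnings.warn(f"{redraws} permutation(s) redrawn because {index!r} "
                      "was undefined on the split", stacklevel=2)
    return {"index": index, "observed_abs_diff": float(obs),
            "p": (count + 1) / (n_perm + 1), "n_perm": n_perm, "seed": seed}
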