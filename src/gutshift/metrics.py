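"""Classical gut-content description metrics.

%FO   frequency of occurrence: share of non-empty guts containing a category.
%W    percentage of biomass, either as the mean of per-fish proportions
      (matching per-fish mean +/- SD summary tables) or as the group-pooled
      biomass share.
IRI   index of relative importance, here the two-term form %FO x %W (numeric
      prey abundance is not recorded in biomass-only gut data), normalised
      to %IRI summing to 100.
FC    gut fullness coefficient, gut-content mass as % of fish body mass.

Also provides the Welch unequal-variance t comparison used for gut-content
mass between groups, callable on raw vectors or printed summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DietTable, ValidationError, composition

__all__ = ["percent_occurrence", "diet_summary", "fullness", "FullnessResult",
           "welch_t", "welch_t_summary"]


def _non_empty_group(table: DietTable, group: str) -> DietTable:
    sub = table.subset(group)
    ne = sub.non_empty() if (~sub.is_empty).any() else None
    if ne is None or len(ne) == 0:
        raise ValidationError(f"group {group!r} has no non-empty fish")
    return ne


def percent_occurrence(table: DietTable, group: str) -> pd.Series:
    """%FO per category: 100 x (non-empty fish containing it) / (non-empty fish)."""
    ne = _non_empty_group(table, group)
    return 100.0 * (ne.biomass > 0).mean(axis=0)


def diet_summary(table: DietTable, group: str,
                 basis: str = "per_fish") -> pd.DataFrame:
    """Per-category diet summary: %W (mean, SD, CV), %FO, IRI and %IRI.

    Rows are sorted by %IRI descending.  The SD/CV columns describe the
    spread of per-fish biomass proportions and are reported regardless of
    the %W basis used inside IRI; CV is NaN where the mean is 0.
    """
    ne = _non_empty_group(table, group)
    props = ne.biomass.div(ne.biomass.sum(axis=1), axis=0) * 100.0
    mean_w = props.mean(axis=0)
    sd_w = props.std(axis=0, ddof=1) if len(ne) > 1 else props.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = (100.0 * sd_w / mean_w).where(mean_w > 0)
    fo = percent_occurrence(table, group)
    w_for_iri = mean_w if basis == "per_fish" else 100.0 * composition(
        table, group, basis="pooled")
    iri = fo * w_for_iri
    total = iri.sum()
    pct_iri = 100.0 * iri / total if total > 0 else iri * np.nan
    out = pd.DataFrame({
        "pct_w_mean": mean_w, "pct_w_sd": sd_w, "cv": cv,
        "pct_fo": fo, "iri": iri, "pct_iri": pct_iri,
    })
    out.index.name = "category"
    return out.sort_values("pct_iri", ascending=False)


@dataclass(frozen=True)
class FullnessResult:
    """Gut fullness coefficient per fish plus the group mean +/- SD (%)."""

    fc_per_fish: pd.Series
    mean: float
    sd: float


def fullness(table: DietTable, group: str | None = None,
             include_empty: bool = True) -> FullnessResult:
    """FC = 100 x gut mass / body mass, with mg -> g conversion internally."""
    sub = table.subset(group) if group is not None else table
    if not include_empty:
        sub = sub.non_empty()
    meta = sub.df.set_index("fish_id")
    if (meta["body_mass_g"] <= 0).any():
        raise ValidationError("body mass must be positive for FC")
    fc = 100.0 * (meta["gut_mass_mg"] / 1000.0) / meta["body_mass_g"]
    sd = float(fc.std(ddof=1)) if len(fc) > 1 else 0.0
    return FullnessResult(fc, float(fc.mean()), sd)


def welch_t_summary(mean1: float, sd1: float, n1: int,
                    mean2: float, sd2: float, n2: int) -> tuple[float, float]:
    """Welch t statistic and Welch-Satterthwaite df from summary statistics.

    Returns (t, df); t is NaN when both SDs are zero and the means equal
    (the statistic is undefined).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    se2 = v1 + v2
    if se2 == 0:
        return (float("nan"), float("nan")) if mean1 == mean2 else (
            float("inf") if mean1 > mean2 else float("-inf"), float(n1 + n2 - 2))
    t = (mean1 - mean2) / np.sqrt(se2)
    df = se2 ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return float(t), float(df)


def welch_t(x, y) -> tuple[float, float]:
    """Welch t and df from raw per-fish vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return welch_t_summary(x.mean(), x.std(ddof=1), len(x),
                           y.mean(), y.std(ddof=1), len(y))
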