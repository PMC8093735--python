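"""Core domain types for per-fish gut-content data.

A diet table is one row per fish: identifier, group label (e.g. juvenile /
mature), total length (cm), body mass (g), gut-content mass (mg), and one
biomass column (mg) per food category.  Fish whose biomass columns are all
zero are "empty" — they stay in the file model but are excluded from every
composition-based statistic downstream, mirroring how empty guts are handled
in gut-content studies.

A guild map assigns each food category to a habitat guild: benthic (BE),
epiphytic (EP), epiphytic/benthic (EP_BE), planktonic (PL) or detritus (DE),
with an optional "others" bucket for categories outside the five guilds.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GUILDS",
    "OTHERS",
    "META_COLUMNS",
    "DietTable",
    "GuildMap",
    "SchemaError",
    "ValidationError",
    "read_diet_table",
    "write_diet_table",
    "read_guild_map",
    "aggregate_by_guild",
    "composition",
    "load_table1_composition",
    "load_table1_guild_summary",
    "load_table2_simper",
    "load_weatherfish_guild_map",
    "table1_reference_cohort",
]

#: Closed set of habitat guilds.
GUILDS = ("BE", "EP", "EP_BE", "PL", "DE")
#: Label of the explicit bucket for categories outside the five guilds.
OTHERS = "others"

META_COLUMNS = ("fish_id", "group", "tl_cm", "body_mass_g", "gut_mass_mg")

_GUILD_ALIASES = {
    "BE": "BE",
    "EP": "EP",
    "EP_BE": "EP_BE",
    "EP/BE": "EP_BE",
    "PL": "PL",
    "DE": "DE",
    OTHERS: OTHERS,
}


class SchemaError(ValueError):
    """A required column is missing or the file layout is unusable."""


class ValidationError(ValueError):
    """Values violate a domain invariant (negative biomass, bad guild...)."""


@dataclass(frozen=True)
class Schema:
    """Column-naming configuration for diet-table CSV files.

    ``biomass_columns`` lists the category columns explicitly; when None,
    every column not in the metadata set (optionally restricted to those
    starting with ``biomass_prefix``) is treated as a food category.
    """

    fish_id: str = "fish_id"
    group: str = "group"
    tl_cm: str = "tl_cm"
    body_mass_g: str = "body_mass_g"
    gut_mass_mg: str = "gut_mass_mg"
    biomass_columns: tuple[str, ...] | None = None
    biomass_prefix: str | None = None

    @property
    def meta(self) -> tuple[str, ...]:
        return (self.fish_id, self.group, self.tl_cm, self.body_mass_g,
                self.gut_mass_mg)


class DietTable:
    """Per-fish biomass-by-category matrix with fish metadata.

    Parameters
    ----------
    df : DataFrame with canonical metadata columns followed by one numeric
        biomass column (mg) per food category.
    categories : optional explicit category ordering; defaults to every
        non-metadata column.
    """

    def __init__(self, df: pd.DataFrame, categories: Sequence[str] | None = None):
        df = df.copy()
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {missing}")
        if categories is None:
            categories = [c for c in df.columns if c not in META_COLUMNS]
        categories = list(categories)
        if not categories:
            raise SchemaError("diet table has no food-category columns")
        if len(set(categories)) != len(categories):
            dupes = sorted({c for c in categories if categories.count(c) > 1})
            raise ValidationError(f"duplicate category names: {dupes}")
        if df["fish_id"].duplicated().any():
            dupes = df.loc[df["fish_id"].duplicated(), "fish_id"].tolist()
            raise ValidationError(f"duplicate fish ids: {dupes}")
        for col in ("tl_cm", "body_mass_g", "gut_mass_mg", *categories):
            df[col] = pd.to_numeric(df[col])
        for fid, row in df.set_index("fish_id")[list(categories)].iterrows():
            bad = row.index[row < 0]
            if len(bad):
                raise ValidationError(
                    f"negative biomass for fish {fid!r}, category {bad[0]!r}")
        if (df["gut_mass_mg"] < 0).any():
            raise ValidationError("gut_mass_mg must be >= 0")
        if (df["tl_cm"] <= 0).any() or (df["body_mass_g"] <= 0).any():
            raise ValidationError("tl_cm and body_mass_g must be > 0")
        self._df = df.reset_index(drop=True)
        self._categories = categories

    # -- basic accessors -------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        """The underlying frame (metadata + biomass columns)."""
        return self._df

    @property
    def categories(self) -> list[str]:
        return list(self._categories)

    @property
    def fish_ids(self) -> list:
        return self._df["fish_id"].tolist()

    @property
    def groups(self) -> list[str]:
        return sorted(self._df["group"].astype(str).unique())

    @property
    def biomass(self) -> pd.DataFrame:
        """Biomass matrix (mg), indexed by fish_id, one column per category."""
        return self._df.set_index("fish_id")[self._categories]

    @property
    def is_empty(self) -> pd.Series:
        """True for fish with no biomass in any category, indexed by fish_id."""
        return (self.biomass <= 0).all(axis=1)

    def __len__(self) -> int:
        return len(self._df)

    def __repr__(self) -> str:
        return (f"DietTable({len(self)} fish, {len(self._categories)} "
                f"categories, groups={self.groups})")

    # -- subsetting -------------------------------------------------------
    def non_empty(self) -> "DietTable":
        """Fish with at least one non-zero biomass entry."""
        keep = ~self.is_empty.values
        return DietTable(self._df.loc[keep], self._categories)

    def subset(self, group: str) -> "DietTable":
        sub = self._df[self._df["group"].astype(str) == str(group)]
        if sub.empty:
            raise ValidationError(f"no fish in group {group!r}")
        return DietTable(sub, self._categories)

    def drop_fish(self, fish_id) -> "DietTable":
        keep = self._df["fish_id"] != fish_id
        if keep.all():
            raise KeyError(fish_id)
        return DietTable(self._df.loc[keep], self._categories)

    def group_labels(self) -> pd.Series:
        return self._df.set_index("fish_id")["group"].astype(str)


@dataclass(frozen=True)
class GuildMap:
    """Mapping from food category to habitat guild (closed five-value set
    plus the explicit ``others`` bucket)."""

    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        norm = {}
        for cat, guild in self.mapping.items():
            g = _GUILD_ALIASES.get(str(guild).strip())
            if g is None:
                raise ValidationError(
                    f"unknown guild {guild!r} for category {cat!r}; "
                    f"valid guilds: {list(GUILDS) + [OTHERS]}")
            if cat in norm:
                raise ValidationError(f"duplicate category {cat!r}")
            norm[cat] = g
        object.__setattr__(self, "mapping", norm)

    def __len__(self) -> int:
        return len(self.mapping)

    def __getitem__(self, category: str) -> str:
        return self.mapping[category]

    def __contains__(self, category: str) -> bool:
        return category in self.mapping

    def guilds_present(self) -> list[str]:
        order = list(GUILDS) + [OTHERS]
        present = set(self.mapping.values())
        return [g for g in order if g in present]

    def categories_in(self, guild: str) -> list[str]:
        return [c for c, g in self.mapping.items() if g == guild]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_diet_table(path, schema: Schema | None = None) -> DietTable:
    """Read a diet-table CSV (UTF-8, header row) into a validated DietTable.

    Empty-gut fish are retained (see :attr:`DietTable.is_empty`).
    """
    schema = schema or Schema()
    df = pd.read_csv(path)
    missing = [c for c in schema.meta if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    rename = dict(zip(schema.meta, META_COLUMNS))
    df = df.rename(columns=rename)
    if schema.biomass_columns is not None:
        cats = [rename.get(c, c) for c in schema.biomass_columns]
        absent = [c for c in cats if c not in df.columns]
        if absent:
            raise SchemaError(f"declared biomass column(s) not in file: {absent}")
        df = df[list(META_COLUMNS) + cats]
    elif schema.biomass_prefix is not None:
        cats = [c for c in df.columns if c.startswith(schema.biomass_prefix)]
        strip = len(schema.biomass_prefix)
        df = df[list(META_COLUMNS) + cats]
        df = df.rename(columns={c: c[strip:] for c in cats})
        cats = [c[strip:] for c in cats]
    else:
        cats = [c for c in df.columns if c not in META_COLUMNS]
    return DietTable(df, cats)


def write_diet_table(table: DietTable, path) -> None:
    """Write the canonical CSV dialect (metadata columns then categories)."""
    cols = list(META_COLUMNS) + table.categories
    table.df[cols].to_csv(path, index=False)


def read_guild_map(path) -> GuildMap:
    """Read a category->guild map from a two-column CSV or a YAML mapping."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise SchemaError("guild-map YAML must be a flat mapping")
        return GuildMap(dict(raw))
    df = pd.read_csv(path)
    if not {"category", "guild"}.issubset(df.columns):
        raise SchemaError("guild-map CSV needs 'category' and 'guild' columns")
    if df["category"].duplicated().any():
        dupes = df.loc[df["category"].duplicated(), "category"].tolist()
        raise ValidationError(f"duplicate category {dupes[0]!r}")
    return GuildMap(dict(zip(df["category"], df["guild"])))


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def aggregate_by_guild(table: DietTable, gmap: GuildMap, *,
                       strict: bool = True) -> DietTable:
    """Sum biomass within habitat guild for every fish.

    Per-fish total biomass is conserved exactly.  Categories absent from the
    map raise in strict mode; otherwise they fall into the ``others`` bucket.
    """
    unmapped = [c for c in table.categories if c not in gmap]
    if unmapped and strict:
        raise ValidationError(
            f"unmapped categor{'y' if len(unmapped) == 1 else 'ies'}: "
            f"{unmapped}; pass strict=False to bucket into {OTHERS!r}")
    order = [g for g in (*GUILDS, OTHERS)]
    assignment = {c: gmap[c] if c in gmap else OTHERS for c in table.categories}
    present = [g for g in order if g in set(assignment.values())]
    out = table.df[list(META_COLUMNS)].copy()
    bm = table.df[table.categories]
    for g in present:
        cols = [c for c, gg in assignment.items() if gg == g]
        out[g] = bm[cols].sum(axis=1)
    return DietTable(out, present)


def composition(table: DietTable, group: str | None = None,
                basis: str = "per_fish") -> pd.Series:
    """Diet composition p_i (biomass proportions summing to 1).

    basis="per_fish": mean over fish of each fish's own proportions — the
    convention behind per-fish mean +/- SD summaries.
    basis="pooled": total biomass over the group, normalised.
    Empty-gut fish are excluded; a group with none raises.
    """
    if basis not in ("per_fish", "pooled"):
        raise ValueError(f"unknown basis {basis!r}")
    sub = table.subset(group) if group is not None else table
    bm = sub.biomass
    totals = bm.sum(axis=1)
    bm = bm.loc[totals > 0]
    if bm.empty:
        raise ValidationError(
            f"group {group!r} has no non-empty fish; composition undefined")
    if basis == "per_fish":
        p = bm.div(bm.sum(axis=1), axis=0).mean(axis=0)
    else:
        pooled = bm.sum(axis=0)
        p = pooled / pooled.sum()
    return p


# ---------------------------------------------------------------------------
# packaged reference tables (published group-level summaries)
# ---------------------------------------------------------------------------

def _data_text(name: str) -> io.StringIO:
    return io.StringIO(
        resources.files("gutshift.data").joinpath(name).read_text("utf-8"))


def load_table1_composition() -> pd.DataFrame:
    """Published per-category diet summary for the two maturity groups.

    Columns: category, guild, then per group the %W mean/SD/CV, %FO and %IRI.
    NaN marks categories absent from a group's diet.
    """
    return pd.read_csv(_data_text("table1_composition.csv"))


def load_table1_guild_summary() -> pd.DataFrame:
    """Published habitat-guild-level diet summary (five guilds + others)."""
    return pd.read_csv(_data_text("table1_guild_summary.csv"))


def load_table2_simper() -> pd.DataFrame:
    """Published SIMPER decomposition of the between-group dissimilarity."""
    return pd.read_csv(_data_text("table2_simper.csv"))


def load_weatherfish_guild_map() -> GuildMap:
    """Packaged category->guild map for the weatherfish food categories."""
    df = pd.read_csv(_data_text("weatherfish_guilds.csv"))
    return GuildMap(dict(zip(df["category"], df["guild"])))


def table1_reference_cohort() -> DietTable:
    """One synthetic fish per group whose diet equals the published group-mean
    composition (useful as a desk-scale stand-in; clearly not raw data)."""
    t1 = load_table1_composition()
    rows = []
    for group, w_col, gut in (("juvenile", "w_mean_juvenile", 73.98),
                              ("mature", "w_mean_mature", 142.65)):
        w = t1[w_col].fillna(0.0).to_numpy()
        p = w / w.sum()
        rows.append({"fish_id": f"{group}_mean", "group": group,
                     "tl_cm": 11.4 if group == "juvenile" else 17.3,
                     "body_mass_g": 6.5 if group == "juvenile" else 19.8,
                     "gut_mass_mg": gut,
                     **dict(zip(t1["category"], p * gut))})
    return DietTable(pd.DataFrame(rows), t1["category"].tolist())
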