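"""Fuzzy-coded trait tables and their dictionaries.

Freshwater-macroinvertebrate trait databases score each taxon's affinity to
every state of a trait group on a small integer scale: 0 (no affinity) up to
3 or 5 (high affinity), the range depending on how many states the group has.
States within a group are *related* — "absorber" is read against the other
feeding-habit states, not in isolation — so all transformations here operate
group-wise, and unknown cells are kept as genuinely missing rather than
zero-filled.

This module provides the dictionary of trait groups, reading/writing of
taxa-by-traits affinity tables, merging of tables recorded with slightly
different trait sets, and group-wise standardization to [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trait",
    "TraitGroup",
    "TraitDictionary",
    "FuzzyTraitTable",
    "StandardizedTraitTable",
    "TraitDataError",
    "load_trait_dictionary",
    "default_dictionary",
    "load_fuzzy_table",
    "write_fuzzy_table",
    "merge_tables",
    "standardize_by_group",
    "summarize_missing",
]

#: cell contents treated as missing when reading tables (case-insensitive)
DEFAULT_NA_SENTINELS = ("", "na", "nan")


class TraitDataError(ValueError):
    """Raised for invalid dictionaries, tables, or merge requests."""


@dataclass(frozen=True)
class Trait:
    name: str
    abbr: str


@dataclass(frozen=True)
class TraitGroup:
    name: str
    max_code: int
    traits: tuple[Trait, ...]

    def __post_init__(self) -> None:
        if self.max_code <= 0:
            raise TraitDataError(
                f"trait group {self.name!r}: max_code must be positive, "
                f"got {self.max_code}"
            )
        if len(self.traits) == 0:
            raise TraitDataError(f"trait group {self.name!r} has no traits")


@dataclass(frozen=True)
class TraitDictionary:
    """Ordered trait groups, each with its states and maximum affinity code."""

    groups: tuple[TraitGroup, ...]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for g in self.groups:
            for t in g.traits:
                if t.abbr in seen:
                    raise TraitDataError(
                        f"duplicate trait abbreviation {t.abbr!r} in groups "
                        f"{seen[t.abbr]!r} and {g.name!r}"
                    )
                seen[t.abbr] = g.name

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_traits(self) -> int:
        return sum(len(g.traits) for g in self.groups)

    @property
    def abbreviations(self) -> list[str]:
        return [t.abbr for g in self.groups for t in g.traits]

    @property
    def trait_names(self) -> list[str]:
        return [t.name for g in self.groups for t in g.traits]

    def column_max_codes(self) -> np.ndarray:
        """Per-trait-column maximum affinity code, in dictionary order."""
        return np.array(
            [g.max_code for g in self.groups for _ in g.traits], dtype=int
        )

    def group_of_column(self) -> list[str]:
        return [g.name for g in self.groups for _ in g.traits]

    def column_index(self) -> dict[str, int]:
        """Map abbreviation AND full name to column position."""
        idx: dict[str, int] = {}
        j = 0
        for g in self.groups:
            for t in g.traits:
                idx[t.abbr] = j
                idx[t.name] = j
                j += 1
        return idx

    def subset_columns(self, group_name: str) -> np.ndarray:
        """Column positions belonging to one trait group."""
        cols, j = [], 0
        for g in self.groups:
            for _ in g.traits:
                if g.name == group_name:
                    cols.append(j)
                j += 1
        return np.array(cols, dtype=int)


def _dictionary_from_mapping(payload: Mapping) -> TraitDictionary:
    if "groups" not in payload:
        raise TraitDataError("trait dictionary is missing the 'groups' key")
    groups = []
    for g in payload["groups"]:
        for key in ("name", "max_code", "traits"):
            if key not in g:
                raise TraitDataError(f"trait group record is missing {key!r}")
        traits = tuple(Trait(t["name"], t["abbr"]) for t in g["traits"])
        groups.append(TraitGroup(g["name"], int(g["max_code"]), traits))
    return TraitDictionary(tuple(groups))


def load_trait_dictionary(path: str | Path) -> TraitDictionary:
    """Load a trait dictionary from JSON or TSV.

    JSON layout: ``{"groups": [{"name", "max_code", "traits": [{"name",
    "abbr"}]}]}``.  TSV layout: columns ``group``, ``max_code``, ``trait``,
    ``abbr``, one row per trait, groups contiguous and in order.
    """
    path = Path(path)
    if not path.exists():
        raise TraitDataError(f"trait dictionary not found: {path}")
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as fh:
            return _dictionary_from_mapping(json.load(fh))
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"group", "max_code", "trait", "abbr"}
    if not required.issubset(frame.columns):
        raise TraitDataError(
            f"TSV dictionary needs columns {sorted(required)}, "
            f"got {list(frame.columns)}"
        )
    groups: list[dict] = []
    for _, row in frame.iterrows():
        if not groups or groups[-1]["name"] != row["group"]:
            groups.append(
                {"name": row["group"], "max_code": int(row["max_code"]), "traits": []}
            )
        groups[-1]["traits"].append({"name": row["trait"], "abbr": row["abbr"]})
    return _dictionary_from_mapping({"groups": groups})


def default_dictionary() -> TraitDictionary:
    """The bundled dictionary: 11 trait groups, 63 traits (FH1 … RP8)."""
    ref = resources.files("traitspace").joinpath("data/trait_dictionary.json")
    return _dictionary_from_mapping(json.loads(ref.read_text(encoding="utf-8")))


@dataclass
class FuzzyTraitTable:
    """Taxa × traits integer affinity matrix with an observed-cell mask.

    ``groups`` holds the pooled taxonomic labels used for reporting (rare
    groups aggregated into e.g. "Others"); ``full_groups``, when present,
    holds the original un-pooled labels so analyses can be repeated at full
    taxonomic resolution.
    """

    taxon_ids: list[str]
    groups: list[str]
    matrix: np.ndarray
    mask: np.ndarray
    dictionary: TraitDictionary
    full_groups: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        self.mask = np.asarray(self.mask, dtype=bool)
        n, p = self.matrix.shape
        if self.mask.shape != (n, p):
            raise TraitDataError("mask shape does not match matrix shape")
        if len(self.taxon_ids) != n or len(self.groups) != n:
            raise TraitDataError("taxon metadata length does not match matrix")
        if p != self.dictionary.n_traits:
            raise TraitDataError(
                f"matrix has {p} trait columns, dictionary defines "
                f"{self.dictionary.n_traits}"
            )
        if self.full_groups is not None and len(self.full_groups) != n:
            raise TraitDataError("full_groups length does not match matrix")
        if len(set(self.taxon_ids)) != n:
            dupes = {t for t in self.taxon_ids if self.taxon_ids.count(t) > 1}
            raise TraitDataError(f"duplicate taxon ids: {sorted(dupes)}")
        max_codes = self.dictionary.column_max_codes()
        observed = self.mask
        bad = observed & ((self.matrix < 0) | (self.matrix > max_codes))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise TraitDataError(
                f"affinity {self.matrix[i, j]} out of range [0, {max_codes[j]}] "
                f"at taxon {self.taxon_ids[i]!r}, trait "
                f"{self.dictionary.abbreviations[j]!r}"
            )

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_traits(self) -> int:
        return self.matrix.shape[1]


@dataclass
class StandardizedTraitTable:
    """Group-wise [0, 1]-standardized view of a :class:`FuzzyTraitTable`."""

    taxon_ids: list[str]
    groups: list[str]
    matrix: np.ndarray
    mask: np.ndarray
    dictionary: TraitDictionary
    standardization_mode: str
    full_groups: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        vals = self.matrix[self.mask]
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise TraitDataError("standardized cells must lie in [0, 1]")

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_traits(self) -> int:
        return self.matrix.shape[1]


def _read_delimited(path: Path) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def load_fuzzy_table(
    path: str | Path,
    dictionary: TraitDictionary,
    *,
    taxon_col: str = "taxon",
    group_col: str = "group",
    full_group_col: str | None = None,
    na_sentinels: Sequence[str] = DEFAULT_NA_SENTINELS,
) -> FuzzyTraitTable:
    """Read a taxa-by-traits affinity table from TSV/CSV.

    Trait columns are matched to the dictionary by abbreviation or full
    name and reordered to dictionary order.  Cells equal to a missing-value
    sentinel (default: empty, "NA", "NaN"; case-insensitive) are masked out.
    A column named ``full_group`` (as written by :func:`write_fuzzy_table`)
    is picked up automatically as the full-resolution label vector.
    """
    path = Path(path)
    frame = _read_delimited(path)
    for col in (taxon_col, group_col):
        if col not in frame.columns:
            raise TraitDataError(f"metadata column {col!r} not found in {path}")
    if full_group_col is None and "full_group" in frame.columns:
        full_group_col = "full_group"
    meta_cols = {taxon_col, group_col}
    if full_group_col is not None:
        if full_group_col not in frame.columns:
            raise TraitDataError(f"column {full_group_col!r} not found in {path}")
        meta_cols.add(full_group_col)

    col_index = dictionary.column_index()
    trait_cols = [c for c in frame.columns if c not in meta_cols]
    unknown = [c for c in trait_cols if c not in col_index]
    if unknown:
        raise TraitDataError(f"unknown trait columns: {unknown}")
    positions = [col_index[c] for c in trait_cols]
    if len(set(positions)) != len(positions):
        raise TraitDataError("two columns map to the same trait")
    missing_traits = sorted(
        set(range(dictionary.n_traits)) - set(positions)
    )
    if missing_traits:
        abbrs = [dictionary.abbreviations[j] for j in missing_traits]
        raise TraitDataError(f"table is missing trait columns: {abbrs}")

    n, p = len(frame), dictionary.n_traits
    matrix = np.zeros((n, p), dtype=int)
    mask = np.zeros((n, p), dtype=bool)
    sentinels = {s.lower() for s in na_sentinels}
    for c, j in zip(trait_cols, positions):
        raw = frame[c].astype(str).str.strip()
        is_na = raw.str.lower().isin(sentinels)
        present = ~is_na
        if present.any():
            try:
                vals = raw[present].astype(float)
            except ValueError as exc:
                raise TraitDataError(
                    f"non-numeric affinity in column {c!r}: {exc}"
                ) from None
            if not np.allclose(vals, np.round(vals)):
                raise TraitDataError(f"non-integer affinity in column {c!r}")
            matrix[present.to_numpy(), j] = vals.round().astype(int)
        mask[:, j] = present.to_numpy()

    return FuzzyTraitTable(
        taxon_ids=frame[taxon_col].tolist(),
        groups=frame[group_col].tolist(),
        matrix=matrix,
        mask=mask,
        dictionary=dictionary,
        full_groups=(
            frame[full_group_col].tolist() if full_group_col is not None else None
        ),
    )


def write_fuzzy_table(table: FuzzyTraitTable, path: str | Path) -> None:
    """Write a table as TSV (missing cells empty); round-trips bit-exactly."""
    path = Path(path)
    data: dict[str, list] = {
        "taxon": table.taxon_ids,
        "group": table.groups,
    }
    if table.full_groups is not None:
        data["full_group"] = table.full_groups
    for j, abbr in enumerate(table.dictionary.abbreviations):
        col = [
            str(int(table.matrix[i, j])) if table.mask[i, j] else ""
            for i in range(table.n_taxa)
        ]
        data[abbr] = col
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def merge_tables(
    base: FuzzyTraitTable,
    addition: FuzzyTraitTable,
    *,
    name_map: Mapping[str, str] | None = None,
    zero_fill: Sequence[str] = (),
) -> FuzzyTraitTable:
    """Row-concatenate two tables recorded against overlapping trait sets.

    ``addition`` may use different trait names (``name_map`` maps them onto
    ``base`` names/abbreviations) and may lack traits entirely; traits listed
    in ``zero_fill`` are filled with *observed* zeros for the added rows,
    i.e. the added taxa are asserted to have no affinity for them, which is
    distinct from the cells being unknown.  The merged table always carries
    ``base``'s full trait set and dictionary.
    """
    name_map = dict(name_map or {})
    col_index = base.dictionary.column_index()
    zero_cols = []
    for abbr in zero_fill:
        if abbr not in col_index:
            raise TraitDataError(f"zero_fill trait {abbr!r} not in base dictionary")
        zero_cols.append(col_index[abbr])

    # Map every addition column onto a base column position.
    add_abbrs = addition.dictionary.abbreviations
    add_names = addition.dictionary.trait_names
    target: list[int] = []
    for abbr, name in zip(add_abbrs, add_names):
        key = name_map.get(abbr, name_map.get(name, None))
        if key is None:
            key = abbr if abbr in col_index else name
        if key not in col_index:
            raise TraitDataError(
                f"addition trait {abbr!r} ({name!r}) has no match in base"
            )
        j = col_index[key]
        if j in zero_cols:
            raise TraitDataError(
                f"trait {abbr!r} is zero-filled but present in addition"
            )
        target.append(j)
    if len(set(target)) != len(target):
        raise TraitDataError("two addition traits map to the same base trait")

    collisions = set(base.taxon_ids) & set(addition.taxon_ids)
    if collisions:
        raise TraitDataError(f"taxon_id collision: {sorted(collisions)[:5]}")

    n_add, p = addition.n_taxa, base.n_traits
    add_matrix = np.zeros((n_add, p), dtype=int)
    add_mask = np.zeros((n_add, p), dtype=bool)
    for src_j, dst_j in enumerate(target):
        add_matrix[:, dst_j] = addition.matrix[:, src_j]
        add_mask[:, dst_j] = addition.mask[:, src_j]
    for j in zero_cols:
        add_matrix[:, j] = 0
        add_mask[:, j] = True  # explicit observed zero affinity

    def _full(t: FuzzyTraitTable) -> list[str]:
        return list(t.full_groups) if t.full_groups is not None else list(t.groups)

    keep_full = base.full_groups is not None or addition.full_groups is not None
    return FuzzyTraitTable(
        taxon_ids=list(base.taxon_ids) + list(addition.taxon_ids),
        groups=list(base.groups) + list(addition.groups),
        matrix=np.vstack([base.matrix, add_matrix]),
        mask=np.vstack([base.mask, add_mask]),
        dictionary=base.dictionary,
        full_groups=(_full(base) + _full(addition)) if keep_full else None,
    )


def standardize_by_group(
    table: FuzzyTraitTable, *, mode: str = "max_code"
) -> StandardizedTraitTable:
    """Rescale affinities of each trait group separately to [0, 1].

    ``max_code`` (default) divides every score by the group's maximum
    *possible* code (3 or 5), which removes the unequal weight that the two
    coding ranges would otherwise carry while preserving the relative affinity
    structure within each group.  ``observed_minmax`` instead min-max scales
    over the group's observed cells.  Missing cells stay missing.
    """
    if mode not in ("max_code", "observed_minmax"):
        raise TraitDataError(f"unknown standardization mode {mode!r}")
    out = table.matrix.astype(float).copy()
    if mode == "max_code":
        max_codes = table.dictionary.column_max_codes().astype(float)
        if (max_codes == 0).any():
            raise TraitDataError("max_code 0 cannot be used for standardization")
        out /= max_codes
    else:
        for g in table.dictionary.groups:
            cols = table.dictionary.subset_columns(g.name)
            sub, obs = out[:, cols], table.mask[:, cols]
            if not obs.any():
                continue
            lo, hi = sub[obs].min(), sub[obs].max()
            out[:, cols] = 0.0 if hi == lo else (sub - lo) / (hi - lo)
    out[~table.mask] = np.nan
    return StandardizedTraitTable(
        taxon_ids=list(table.taxon_ids),
        groups=list(table.groups),
        matrix=np.where(table.mask, out, np.nan),
        mask=table.mask.copy(),
        dictionary=table.dictionary,
        standardization_mode=mode,
        full_groups=list(table.full_groups) if table.full_groups else None,
    )


def summarize_missing(table: FuzzyTraitTable) -> dict:
    """Count missing cells and their percentage (2 decimals) of the matrix."""
    count = int((~table.mask).sum())
    total = table.mask.size
    return {"count": count, "percent": round(100.0 * count / total, 2)}
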