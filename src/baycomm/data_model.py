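"""Detection tables, species filters, and the binary community matrix.

The analysis operates on a samples x species presence/absence matrix built
from a long-format detection table (one row per sample/species detection)
and a sample metadata table (site, month, water layer, site depth). Species
are filtered before matrix construction: first names that could not be
matched against a reference database, then species whose known habitat
excludes the study system.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LAYERS = ("surface", "bottom")

#: columns of a long-format detection table
DETECTION_COLUMNS = ("sample_id", "species_name", "detected")
#: columns of a sample metadata table
METADATA_COLUMNS = ("sample_id", "site_id", "month", "layer", "site_depth")


class FormatError(ValueError):
    """A table does not conform to the expected layout."""


class ConsistencyError(ValueError):
    """Tables reference each other inconsistently."""


@dataclass(frozen=True)
class FilterConfig:
    """Species filter lists applied before matrix construction.

    ``unmatched_names`` is applied first; a species appearing in both sets
    is counted under the first criterion only.
    """

    unmatched_names: frozenset[str] = frozenset()
    excluded_habitat: frozenset[str] = frozenset()

    @classmethod
    def from_files(cls, unmatched_path=None, habitat_path=None) -> "FilterConfig":
        return cls(
            unmatched_names=frozenset(read_species_list(unmatched_path)) if unmatched_path else frozenset(),
            excluded_habitat=frozenset(read_species_list(habitat_path)) if habitat_path else frozenset(),
        )


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping of the two-step species filter.

    Invariant: ``n_retained == n_detected - n_removed_name - n_removed_habitat``.
    """

    n_detected: int
    n_removed_name: int
    n_removed_habitat: int
    n_retained: int

    def __post_init__(self):
        if self.n_retained != self.n_detected - self.n_removed_name - self.n_removed_habitat:
            raise ValueError("filter report arithmetic does not balance")

    def to_dict(self) -> dict:
        return asdict(self)


def read_species_list(path) -> list[str]:
    """Read a one-name-per-line species list; '#' starts a comment."""
    names = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            names.append(line)
    return names


def read_detection_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read a long-format detection table.

    The file must have a header with ``sample_id``, ``species_name`` and
    either ``detected`` (boolean/0-1) or ``count`` (nonnegative integer;
    any count > 0 maps to detected). Delimiter is sniffed unless ``sep``
    is given.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"sample_id", "species_name"}
    if not required.issubset(df.columns):
        raise FormatError(f"detection table missing columns: {sorted(required - set(df.columns))}")
    if "detected" in df.columns:
        col = df["detected"]
        if col.dtype == object:
            col = col.astype(str).str.strip().str.lower().map(
                {"true": True, "false": False, "1": True, "0": False}
            )
            if col.isna().any():
                raise FormatError("non-boolean values in 'detected' column")
        detected = col.astype(bool)
    elif "count" in df.columns:
        counts = pd.to_numeric(df["count"], errors="coerce")
        if counts.isna().any():
            raise FormatError("non-numeric values in 'count' column")
        detected = counts > 0
    else:
        raise FormatError("detection table needs a 'detected' or 'count' column")
    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"].astype(str).str.strip(),
            "species_name": df["species_name"].astype(str).str.strip(),
            "detected": detected.to_numpy(),
        }
    )
    if (out["sample_id"] == "").any() or (out["species_name"] == "").any():
        raise FormatError("empty sample_id or species_name")
    return out


def read_metadata_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read the sample metadata table and validate its invariants."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"metadata table missing columns: {sorted(missing)}")
    df = df[list(METADATA_COLUMNS)].copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["site_id"] = df["site_id"].astype(str)
    df["month"] = df["month"].astype(int)
    df["layer"] = df["layer"].astype(str).str.lower()
    df["site_depth"] = df["site_depth"].astype(float)
    validate_metadata(df)
    return df


def validate_metadata(metadata: pd.DataFrame) -> None:
    if metadata["sample_id"].duplicated().any():
        dupes = metadata.loc[metadata["sample_id"].duplicated(), "sample_id"].tolist()
        raise ConsistencyError(f"duplicate sample_id in metadata: {dupes[:5]}")
    if metadata.duplicated(["site_id", "month", "layer"]).any():
        raise ConsistencyError("(site_id, month, layer) does not uniquely identify samples")
    if not metadata["month"].between(1, 12).all():
        raise FormatError("month outside 1-12")
    if not metadata["layer"].isin(LAYERS).all():
        bad = sorted(set(metadata["layer"]) - set(LAYERS))
        raise FormatError(f"unknown layer values: {bad}")
    if not ((metadata["site_depth"] > 0) & (metadata["site_depth"] <= 200)).all():
        raise FormatError("site_depth outside (0, 200] m")


def apply_species_filters(
    records: pd.DataFrame, config: FilterConfig
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop filtered species from a detection table.

    Species listed under ``unmatched_names`` are removed first, then those
    under ``excluded_habitat``; the report counts unique species removed per
    criterion. Names in the lists that never occur in ``records`` are ignored
    with a warning.
    """
    detected_species = set(records.loc[records["detected"], "species_name"])
    all_species = set(records["species_name"])
    for listed, label in (
        (config.unmatched_names, "unmatched-name"),
        (config.excluded_habitat, "habitat-exclusion"),
    ):
        unknown = set(listed) - all_species
        if unknown:
            logger.warning(
                "%d names in the %s list not present in the detection table", len(unknown), label
            )
    removed_name = detected_species & set(config.unmatched_names)
    removed_habitat = (detected_species - removed_name) & set(config.excluded_habitat)
    removed = removed_name | removed_habitat
    kept = records[~records["species_name"].isin(removed)].reset_index(drop=True)
    report = FilterReport(
        n_detected=len(detected_species),
        n_removed_name=len(removed_name),
        n_removed_habitat=len(removed_habitat),
        n_retained=len(detected_species) - len(removed_name) - len(removed_habitat),
    )
    return kept, report


class CommunityMatrix:
    """Binary samples x species occupancy with aligned per-sample metadata.

    Parameters
    ----------
    occupancy:
        DataFrame indexed by sample_id with species names as columns and
        values in {0, 1}.
    metadata:
        DataFrame indexed by sample_id with columns site_id, month, layer,
        site_depth, in the same row order as ``occupancy``.
    """

    def __init__(self, occupancy: pd.DataFrame, metadata: pd.DataFrame):
        if not occupancy.index.equals(metadata.index):
            raise ConsistencyError("occupancy and metadata indices differ")
        if occupancy.index.duplicated().any():
            raise ConsistencyError("duplicate sample_id")
        values = occupancy.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValueError("occupancy entries must be 0 or 1")
        self.occupancy = occupancy.astype(np.int8)
        self.metadata = metadata

    @property
    def sample_ids(self) -> list[str]:
        return list(self.occupancy.index)

    @property
    def species(self) -> list[str]:
        return list(self.occupancy.columns)

    @property
    def n_samples(self) -> int:
        return self.occupancy.shape[0]

    @property
    def n_species(self) -> int:
        return self.occupancy.shape[1]

    def values(self) -> np.ndarray:
        return self.occupancy.to_numpy()

    def richness(self) -> pd.Series:
        """Per-sample species count (row sums)."""
        return self.occupancy.sum(axis=1).rename("richness")

    def subset_samples(self, sample_ids: Sequence[str]) -> "CommunityMatrix":
        ids = list(sample_ids)
        return CommunityMatrix(self.occupancy.loc[ids], self.metadata.loc[ids])

    def subset_species(self, species: Sequence[str]) -> "CommunityMatrix":
        return CommunityMatrix(self.occupancy[list(species)], self.metadata)

    def to_long(self) -> pd.DataFrame:
        """Export back to the long detection-table dialect (detected rows only)."""
        long = (
            self.occupancy.stack()
            .rename("detected")
            .reset_index()
            .rename(columns={"level_0": "sample_id", "level_1": "species_name"})
        )
        long.columns = ["sample_id", "species_name", "detected"]
        long["detected"] = long["detected"].astype(bool)
        return long[long["detected"]].reset_index(drop=True)

    def to_wide_csv(self, path) -> None:
        self.occupancy.to_csv(path, index_label="sample_id")

    def __repr__(self) -> str:  # pragma: no cover
        return f"CommunityMatrix({self.n_samples} samples x {self.n_species} species)"


def build_community_matrix(records: pd.DataFrame, metadata: pd.DataFrame) -> CommunityMatrix:
    """Pivot a detection table into a binary community matrix.

    Every metadata sample becomes a row (all-zero if nothing was detected);
    duplicate detections collapse to a single 1; species never detected in
    any retained sample are dropped.
    """
    validate_metadata(metadata)
    known = set(metadata["sample_id"])
    unknown = set(records["sample_id"]) - known
    if unknown:
        raise ConsistencyError(f"detection records reference unknown samples: {sorted(unknown)[:5]}")
    detected = records[records["detected"]]
    wide = (
        detected.assign(value=1)
        .pivot_table(index="sample_id", columns="species_name", values="value", aggfunc="max", fill_value=0)
        .reindex(index=metadata["sample_id"], fill_value=0)
    )
    wide = wide.loc[:, wide.sum(axis=0) > 0]
    wide = wide[sorted(wide.columns)]
    wide.index.name = "sample_id"
    wide.columns.name = None
    meta = metadata.set_index("sample_id")
    return CommunityMatrix(wide.astype(np.int8), meta)


def select_top_species(matrix: CommunityMatrix, fraction: float) -> list[str]:
    """The ``ceil(fraction * n_species)`` most frequently occurring species.

    Ties in occurrence count are broken by lexicographic species name so the
    selection is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if matrix.n_species == 0:
        raise ValueError("empty community matrix")
    k = math.ceil(fraction * matrix.n_species)
    counts = matrix.occupancy.sum(axis=0)
    order = sorted(counts.index, key=lambda s: (-counts[s], s))
    return order[:k]


def compute_richness(matrix: CommunityMatrix) -> pd.Series:
    """Per-sample species richness (row sums of the occupancy matrix)."""
    return matrix.richness()
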