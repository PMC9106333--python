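"""Cytoarchitectonic parcellation model.

A parcellation is an ordered list of named brain areas, each carrying an
analysis-group label and a volume in cubic millimetres. Volumes are the
weights of the volume-proportional chance null used by the tracing analysis:
under the null, a labeled cell falls into an area with probability equal to
that area's share of the total parcellation volume.

Raw atlas areas (e.g. ``10d``, ``9/46v``) are grouped into analysis groups
(e.g. ``10``, ``9``) by shared cytoarchitectonic character; all counting and
statistics downstream operate at the group level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BrainArea",
    "Parcellation",
    "load_parcellation",
    "default_grouping",
    "default_parcellation",
    "volume_fractions",
]

REQUIRED_COLUMNS = ("name", "group", "volume_mm3")


@dataclass(frozen=True)
class BrainArea:
    """One named area: identity, analysis-group label and volume in mm^3."""

    name: str
    group: str
    volume_mm3: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("area name must be non-empty")
        if not self.group:
            raise ValueError(f"area {self.name!r}: group label must be non-empty")
        if not np.isfinite(self.volume_mm3) or self.volume_mm3 <= 0:
            raise ValueError(
                f"area {self.name!r}: volume_mm3 must be a positive finite number, "
                f"got {self.volume_mm3!r}"
            )


@dataclass(frozen=True)
class Parcellation:
    """Ordered collection of :class:`BrainArea` with derived group labels.

    Group order follows first appearance in ``areas``. Area names must be
    unique. A single-group parcellation is permitted in memory (it is the
    degenerate case of the chance null); file loading additionally requires
    at least two groups.
    """

    areas: tuple[BrainArea, ...]

    def __post_init__(self) -> None:
        if not self.areas:
            raise ValueError("parcellation must contain at least one area")
        names = [a.name for a in self.areas]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate area name(s): {sorted(dupes)}")

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.areas]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.areas:
            seen.setdefault(a.group, None)
        return list(seen)

    @property
    def total_volume(self) -> float:
        return float(sum(a.volume_mm3 for a in self.areas))

    def group_volumes(self) -> pd.Series:
        """Volume per analysis group (sum of member areas), in group order."""
        vols = pd.Series(0.0, index=pd.Index(self.groups, name="group"))
        for a in self.areas:
            vols[a.group] += a.volume_mm3
        return vols

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "group": [a.group for a in self.areas],
                "volume_mm3": [a.volume_mm3 for a in self.areas],
            }
        )

    def aggregate_to_groups(self) -> "Parcellation":
        """Collapse to one area per analysis group (volumes summed)."""
        gv = self.group_volumes()
        return Parcellation(
            tuple(BrainArea(g, g, float(v)) for g, v in gv.items())
        )


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, comment="#", dtype={"name": str, "group": str})


def load_parcellation(path: str | Path) -> Parcellation:
    """Load a parcellation from a CSV/TSV with columns name, group, volume_mm3.

    Lines starting with ``#`` are ignored; file row order is preserved.
    Duplicate names, missing or non-positive volumes, and single-group tables
    are rejected.
    """
    df = _read_table(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df["volume_mm3"].isna().any():
        bad = df.loc[df["volume_mm3"].isna(), "name"].tolist()
        raise ValueError(f"{path}: missing volume for area(s) {bad}")
    areas = tuple(
        BrainArea(str(r["name"]), str(r["group"]), float(r["volume_mm3"]))
        for _, r in df.iterrows()
    )
    p = Parcellation(areas)
    if len(p.groups) < 2:
        raise ValueError(f"{path}: parcellation must define at least 2 groups")
    return p


def default_grouping() -> Mapping[str, str]:
    """The shipped raw-area -> analysis-group mapping (27 areas, 19 groups).

    Frontal areas collapse into 13 groups (10, 25, 14, 11, 13, 24, 32, 46, 9,
    8, 6m, 6d, 6v) and insular areas into 6 (OPAl, OPro, AI, DI, GI, IPro).
    """
    with resources.files("seedtrace.data").joinpath("default_grouping.csv").open() as f:
        df = pd.read_csv(f, comment="#", dtype=str)
    return dict(zip(df["name"], df["group"]))


def map_to_group(raw_name: str, grouping: Mapping[str, str] | None = None) -> str:
    """Look up the analysis group of a raw area name; unknown name -> KeyError."""
    grouping = default_grouping() if grouping is None else grouping
    try:
        return grouping[raw_name]
    except KeyError:
        raise KeyError(
            f"unknown raw area {raw_name!r}; known areas: {sorted(grouping)}"
        ) from None


def default_parcellation(level: Literal["raw", "group"] = "raw") -> Parcellation:
    """The shipped demonstration parcellation (synthetic volumes)."""
    with resources.files("seedtrace.data").joinpath("default_parcellation.csv").open() as f:
        df = pd.read_csv(f, comment="#", dtype={"name": str, "group": str})
    p = Parcellation(
        tuple(
            BrainArea(str(r["name"]), str(r["group"]), float(r["volume_mm3"]))
            for _, r in df.iterrows()
        )
    )
    return p.aggregate_to_groups() if level == "group" else p


def volume_fractions(p: Parcellation, level: Literal["raw", "group"] = "group") -> pd.Series:
    """Per-area (or per-group) volume fractions; non-negative, summing to 1.

    These are the chance-null probabilities: the probability that a randomly
    placed cell lands in a unit is that unit's share of total volume.
    """
    if level == "raw":
        v = pd.Series(
            [a.volume_mm3 for a in p.areas], index=pd.Index(p.names, name="name")
        )
    elif level == "group":
        v = p.group_volumes()
    else:
        raise ValueError(f"level must be 'raw' or 'group', got {level!r}")
    return v / v.sum()
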