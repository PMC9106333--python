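"""Retrograde tract-tracing quantification with a volume-weighted chance null.

For one injection case, the connectivity strength of area *i* is the fraction
of all labeled cells found in that area::

    CS_i = c_i / c_total

The chance level of CS_i is obtained by Monte Carlo: all ``c_total`` cells are
re-assigned at random to areas with probability proportional to area volume
(a multinomial draw), CS is recomputed, and the procedure is repeated many
times. An area is called above chance when its observed CS exceeds the upper
bound of the central confidence interval of its null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .parcellation import Parcellation, volume_fractions

__all__ = [
    "CellCountTable",
    "ConnectivityProfile",
    "NullDistribution",
    "NullTable",
    "compute_connectivity_strength",
    "sample_chance_null",
    "flag_above_chance",
    "spearman_profile_correlation",
    "load_cell_counts",
]

#: chunk size for vectorised multinomial null draws (bounds peak memory)
_CHUNK = 100_000


@dataclass(frozen=True)
class CellCountTable:
    """Labeled-cell counts for one injection case, aligned to analysis groups."""

    case_id: str
    counts: pd.Series  # index: group labels; values: non-negative ints

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if (c < 0).any() or not np.all(np.isfinite(c)):
            raise ValueError(f"case {self.case_id!r}: counts must be finite and >= 0")
        if not np.allclose(c, np.round(c)):
            raise ValueError(f"case {self.case_id!r}: counts must be integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ConnectivityProfile:
    """Per-group connectivity-strength fractions (CS) for one case."""

    case_id: str
    cs: pd.Series  # index: group labels; values in [0, 1], summing to 1

    def __post_init__(self) -> None:
        v = np.asarray(self.cs, dtype=float)
        if (v < 0).any() or (v > 1).any():
            raise ValueError("cs values must lie in [0, 1]")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"cs must sum to 1, got {v.sum()!r}")


@dataclass(frozen=True)
class NullDistribution:
    """Summary of a Monte-Carlo chance distribution for one target."""

    mean: float
    sd: float
    ci_low: float
    ci_high: float
    n_reps: int
    ci_level: float
    rng_seed: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not (self.ci_low <= self.mean + 1e-12 and self.mean - 1e-12 <= self.ci_high):
            raise ValueError("require ci_low <= mean <= ci_high")
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must lie in (0, 1)")


@dataclass(frozen=True)
class NullTable:
    """Per-group chance-null summaries for one total cell count."""

    table: pd.DataFrame  # index: groups; columns: mean, sd, ci_low, ci_high
    n_reps: int
    ci_level: float
    rng_seed: int

    def __getitem__(self, group: str) -> NullDistribution:
        r = self.table.loc[group]
        return NullDistribution(
            float(r["mean"]), float(r["sd"]), float(r["ci_low"]), float(r["ci_high"]),
            self.n_reps, self.ci_level, self.rng_seed,
        )


def compute_connectivity_strength(counts: CellCountTable) -> ConnectivityProfile:
    """CS_i = c_i / c_total. Errors if the case has no labeled cells."""
    total = counts.total
    if total <= 0:
        raise ValueError(
            f"case {counts.case_id!r}: total cell count is 0; CS undefined"
        )
    return ConnectivityProfile(counts.case_id, counts.counts.astype(float) / total)


def sample_chance_null(
    total_cells: int,
    p: Parcellation,
    n_reps: int = 1_000_000,
    ci_level: float = 0.95,
    rng_seed: int = 0,
    case_tag: str = "",
) -> NullTable:
    """Monte-Carlo chance null of CS per group under volume-proportional placement.

    Each replicate draws a multinomial allocation of ``total_cells`` over the
    parcellation's groups with probabilities equal to the group volume
    fractions, then converts to CS. Per-group mean, sd and the central
    ``ci_level`` interval (empirical percentiles, linear interpolation) are
    summarised. Reproducible for a fixed ``rng_seed`` (+ optional case tag).
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 (summaries unstable below)")
    if total_cells < 1:
        raise ValueError("total_cells must be >= 1")
    probs = volume_fractions(p, level="group")
    rng = substream(rng_seed, f"tracing-null:{case_tag}")
    k = len(probs)
    alpha = (1.0 - ci_level) / 2.0

    # accumulate moments exactly; keep only a quantile-worthy sample matrix
    # in chunks to bound memory at n_reps = 1e6
    s1 = np.zeros(k)
    s2 = np.zeros(k)
    chunks: list[np.ndarray] = []
    done = 0
    while done < n_reps:
        m = min(_CHUNK, n_reps - done)
        cs = rng.multinomial(total_cells, probs.to_numpy(), size=m) / total_cells
        s1 += cs.sum(axis=0)
        s2 += (cs * cs).sum(axis=0)
        chunks.append(cs.astype(np.float32))
        done += m
    draws = np.concatenate(chunks, axis=0)
    mean = s1 / n_reps
    var = np.maximum(s2 / n_reps - mean**2, 0.0)
    ci_low = np.quantile(draws, alpha, axis=0).astype(float)
    ci_high = np.quantile(draws, 1.0 - alpha, axis=0).astype(float)
    table = pd.DataFrame(
        {
            "mean": mean,
            "sd": np.sqrt(var),
            "ci_low": np.minimum(ci_low, mean),
            "ci_high": np.maximum(ci_high, mean),
        },
        index=probs.index,
    )
    return NullTable(table, n_reps, ci_level, int(rng_seed))


def flag_above_chance(profile: ConnectivityProfile, null: NullTable) -> pd.DataFrame:
    """Flag groups whose CS strictly exceeds the null's upper CI bound.

    Returns one row per group with the observed CS, the null summary, the
    boolean flag and the excess ratio CS / null mean (reported whether or not
    the group is flagged; equality with ci_high is not flagged).
    """
    if list(profile.cs.index) != list(null.table.index):
        if set(profile.cs.index) != set(null.table.index):
            raise ValueError(
                "profile and null are defined over different group sets: "
                f"{sorted(set(profile.cs.index) ^ set(null.table.index))}"
            )
        null = NullTable(
            null.table.loc[profile.cs.index], null.n_reps, null.ci_level, null.rng_seed
        )
    out = null.table.copy()
    out.insert(0, "cs", profile.cs.astype(float))
    out["flagged"] = out["cs"] > out["ci_high"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["excess_ratio"] = np.where(out["mean"] > 0, out["cs"] / out["mean"], np.inf)
    out.index.name = "group"
    return out


def spearman_profile_correlation(
    a: ConnectivityProfile,
    b: ConnectivityProfile,
    n_perm: int = 10_000,
    rng_seed: int = 0,
) -> tuple[float, float]:
    """Spearman rho between two cases' CS profiles, with a permutation p-value.

    Ranks use average ranks for ties. The p-value is two-sided: the fraction
    of label permutations of one profile whose |rho| reaches the observed
    |rho| (with the +1 add-one correction to avoid zero p-values).
    """
    if set(a.cs.index) != set(b.cs.index):
        raise ValueError("profiles are defined over different group sets")
    if len(a.cs) < 3:
        raise ValueError("need at least 3 groups for a rank correlation")
    x = a.cs.to_numpy(dtype=float)
    y = b.cs.reindex(a.cs.index).to_numpy(dtype=float)
    rho = float(stats.spearmanr(x, y).statistic)

    rng = substream(rng_seed, f"spearman:{a.case_id}|{b.case_id}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = len(x)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if abs(np.mean(rx[perm] * ry)) >= abs(rho) - 1e-12:
            hits += 1
    pval = (hits + 1) / (n_perm + 1)
    return rho, float(pval)


def load_cell_counts(path: str | Path, groups: Iterable[str]) -> list[CellCountTable]:
    """Read a CSV/TSV of cell counts: one row per case, columns = group names.

    A ``case_id`` column (or the first column) identifies the case. Columns
    must cover the parcellation's groups exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    id_col = "case_id" if "case_id" in df.columns else df.columns[0]
    groups = list(groups)
    missing = [g for g in groups if g not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing count column(s) for group(s) {missing}")
    return [
        CellCountTable(str(r[id_col]), pd.Series([int(r[g]) for g in groups],
                                                 index=pd.Index(groups, name="group")))
        for _, r in df.iterrows()
    ]
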