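"""Seed-based functional connectivity with a voxel-permutation chance null.

A spherical seed's mean time series is correlated with every in-brain voxel;
correlations are Fisher r-to-z transformed (z = arctanh r). The connectivity
strength between a seed and an anatomical mask is the average of |z| over the
mask's valid voxels (the absolute average; |mean z| is selectable). Chance
level comes from permuting the z values uniformly across the brain volume
and recomputing the mask strength; a seed-mask strength is called above
chance when it exceeds the upper bound of the permutation distribution's
central confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .preproc import VolumeImage
from .tracing import NullDistribution

__all__ = [
    "SeedSpec",
    "FCMap",
    "FCResult",
    "build_spherical_seed",
    "seed_timeseries",
    "fc_map",
    "mask_strength",
    "voxel_permutation_null",
    "seed_to_seed_matrix",
    "overlap_fraction",
    "load_seeds",
]

#: |r| is clipped here before arctanh so z stays finite at r = +-1
R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class SeedSpec:
    """A spherical seed: label, world-mm centre (template space), radius."""

    label: str
    center_mm: tuple[float, float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"seed {self.label!r}: radius_mm must be positive")


@dataclass(frozen=True)
class FCMap:
    """Voxel-wise Fisher-z map for one seed, with a validity mask.

    ``valid`` marks in-brain voxels whose series had non-zero variance;
    ``z`` is finite wherever ``valid``.
    """

    z: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.z.shape != self.valid.shape:
            raise ValueError("z and valid must share a shape")
        if not np.all(np.isfinite(self.z[self.valid])):
            raise ValueError("z must be finite at valid voxels")


@dataclass(frozen=True)
class FCResult:
    """Strength of one (seed, mask) pair against its permutation null."""

    seed_label: str
    mask_label: str
    strength: float
    null: NullDistribution
    flagged: bool
    overlap_fraction: float


def build_spherical_seed(spec: SeedSpec, grid: VolumeImage) -> np.ndarray:
    """Binary seed volume: voxels whose centre lies within radius of the seed.

    Membership is judged by Euclidean distance in world millimetres (so
    anisotropic grids are handled exactly), then intersected with the brain
    mask. An empty intersection (seed outside the brain) is an error.
    """
    centers = grid.voxel_centers_mm()
    lo = centers.reshape(-1, 3).min(axis=0)
    hi = centers.reshape(-1, 3).max(axis=0)
    c = np.asarray(spec.center_mm, dtype=float)
    if np.any(c < lo - spec.radius_mm) or np.any(c > hi + spec.radius_mm):
        raise ValueError(f"seed {spec.label!r}: centre {tuple(c)} outside the grid")
    d2 = ((centers - c) ** 2).sum(axis=-1)
    sphere = d2 <= spec.radius_mm**2
    seed = sphere & grid.mask_array()
    if not seed.any():
        raise ValueError(f"seed {spec.label!r}: outside brain (empty mask intersection)")
    return seed


def seed_timeseries(img: VolumeImage, seed_mask: np.ndarray) -> np.ndarray:
    """Unweighted mean time series over the seed's voxels."""
    if img.data.ndim != 4:
        raise ValueError("seed_timeseries requires a 4D image")
    if not np.asarray(seed_mask, dtype=bool).any():
        raise ValueError("empty seed mask")
    return img.data[np.asarray(seed_mask, dtype=bool)].mean(axis=0)


def fc_map(img: VolumeImage, seed_ts: np.ndarray) -> FCMap:
    """Pearson r of every in-brain voxel against the seed series, Fisher z'd.

    Voxels with zero temporal variance are marked invalid (z = 0 there by
    convention, excluded from all downstream statistics). |r| is clipped at
    1 - 1e-7 before arctanh.
    """
    if img.data.ndim != 4:
        raise ValueError("fc_map requires a 4D image")
    ts = np.asarray(seed_ts, dtype=float)
    t = img.data.shape[3]
    if ts.shape != (t,):
        raise ValueError(f"seed series length {ts.shape} != image time points {t}")
    if t < 3:
        raise ValueError("need at least 3 time points")
    s = ts - ts.mean()
    s_norm = np.linalg.norm(s)
    if s_norm < 1e-12:
        raise ValueError("seed time series is constant; correlation undefined")
    mask = img.mask_array()
    Y = img.data[mask]  # (n, t)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Yc, axis=1)
    nonzero = norms > 1e-12
    r = np.zeros(Y.shape[0])
    r[nonzero] = (Yc[nonzero] @ s) / (norms[nonzero] * s_norm)
    z_vals = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))

    z = np.zeros(img.spatial_shape)
    valid = np.zeros(img.spatial_shape, dtype=bool)
    z[mask] = np.where(nonzero, z_vals, 0.0)
    valid[mask] = nonzero
    return FCMap(z, valid)


def mask_strength(fcm: FCMap, mask: np.ndarray, convention: str = "mean_abs") -> float:
    """Connectivity strength of the map within a mask.

    ``mean_abs`` (default): mean of |z| over the mask's valid voxels —
    the absolute average. ``abs_mean``: |mean z|.
    """
    sel = np.asarray(mask, dtype=bool) & fcm.valid
    if not sel.any():
        raise ValueError("mask has no valid in-brain voxels")
    vals = fcm.z[sel]
    if convention == "mean_abs":
        return float(np.abs(vals).mean())
    if convention == "abs_mean":
        return float(abs(vals.mean()))
    raise ValueError(f"unknown strength convention {convention!r}")


def voxel_permutation_null(
    fcm: FCMap,
    mask: np.ndarray,
    n_reps: int = 1_000_000,
    ci_level: float = 0.95,
    rng_seed: int = 0,
    convention: str = "mean_abs",
    tag: str = "",
) -> tuple[NullDistribution, bool]:
    """Chance null of mask strength by permuting z values across the brain.

    Each replicate redistributes all valid-voxel z values uniformly over the
    brain volume and recomputes the mask strength — equivalently, it scores a
    uniformly random same-size voxel subset. Summaries (mean, sd, central
    ``ci_level`` percentile interval) mirror the tracing null. Returns the
    null and whether the observed strength strictly exceeds ci_high.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    maskb = np.asarray(mask, dtype=bool)
    if maskb.sum() > fcm.valid.sum():
        raise ValueError("mask is larger than the valid brain volume")
    observed = mask_strength(fcm, maskb, convention)
    m = int((maskb & fcm.valid).sum())
    pool = fcm.z[fcm.valid]
    if convention == "mean_abs":
        pool = np.abs(pool)
    rng = substream(rng_seed, f"fc-null:{tag}")
    draws = np.empty(n_reps)
    for i in range(n_reps):
        sample = rng.choice(pool, size=m, replace=False, shuffle=False)
        draws[i] = sample.mean() if convention == "mean_abs" else abs(sample.mean())
    alpha = (1.0 - ci_level) / 2.0
    mean = float(draws.mean())
    null = NullDistribution(
        mean=mean,
        sd=float(draws.std()),
        ci_low=min(float(np.quantile(draws, alpha)), mean),
        ci_high=max(float(np.quantile(draws, 1.0 - alpha)), mean),
        n_reps=n_reps,
        ci_level=ci_level,
        rng_seed=int(rng_seed),
    )
    return null, bool(observed > null.ci_high)


def overlap_fraction(seed_mask: np.ndarray, target_mask: np.ndarray) -> float:
    """Fraction of the target mask's voxels that lie inside the seed."""
    tm = np.asarray(target_mask, dtype=bool)
    if tm.sum() == 0:
        raise ValueError("target mask is empty")
    return float((tm & np.asarray(seed_mask, dtype=bool)).sum() / tm.sum())


def seed_to_seed_matrix(img: VolumeImage, seeds: list[SeedSpec]) -> pd.DataFrame:
    """Symmetric Fisher-z matrix of pairwise seed-mean-series correlations.

    The diagonal is reported as NaN (self-correlation is not a value).
    Overlapping or duplicated seeds are allowed; duplicates land at the
    clip bound arctanh(1 - 1e-7).
    """
    if len(seeds) < 2:
        raise ValueError("need at least 2 seeds")
    series = np.vstack(
        [seed_timeseries(img, build_spherical_seed(s, img)) for s in seeds]
    )
    r = np.corrcoef(series)
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    np.fill_diagonal(z, np.nan)
    z = (z + z.T) / 2.0  # enforce exact symmetry against fp asymmetry
    labels = [s.label for s in seeds]
    return pd.DataFrame(z, index=labels, columns=labels)


def load_seeds(path) -> list[SeedSpec]:
    """Read seeds from CSV with columns label, x_mm, y_mm, z_mm, radius_mm."""
    df = pd.read_csv(path, comment="#")
    required = ["label", "x_mm", "y_mm", "z_mm", "radius_mm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing seed column(s) {missing}")
    return [
        SeedSpec(str(r["label"]), (float(r["x_mm"]), float(r["y_mm"]), float(r["z_mm"])),
                 float(r["radius_mm"]))
        for _, r in df.iterrows()
    ]
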