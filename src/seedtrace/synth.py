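"""Synthetic data emulating both analysis arms.

Two generators:

* Tracing arm — multinomial labeled-cell counts over parcellation groups with
  a volume-proportional baseline and planted per-group enrichment multipliers
  (enrichment 1 everywhere reproduces the chance null exactly).

* Imaging arm — 4D voxel time series built from a small number of spatially
  coherent latent network signals (band-limited Gaussian processes) plus
  white noise, inside an ellipsoidal brain mask. Voxels sharing a network
  correlate; seeds placed inside a planted network show elevated strength
  against masks in the same network.

``make_demo_layout`` assembles a complete miniature study: a vlPFC-like seed
set with exactly one seed inside a planted salience-like network, dACC-like
and AI-like masks inside that network, and a 19-group parcellation with one
enriched group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from ._rng import substream
from .parcellation import Parcellation, default_parcellation, volume_fractions
from .preproc import VolumeImage
from .tracing import CellCountTable
from .fc import SeedSpec, build_spherical_seed

__all__ = [
    "TracingTruth",
    "NetworkTruth",
    "generate_tracing_case",
    "case_probabilities",
    "generate_synthetic_bold",
    "DemoLayout",
    "make_demo_layout",
]


@dataclass(frozen=True)
class TracingTruth:
    """Ground truth for one synthetic injection case.

    ``enrichment`` maps group -> positive multiplier on the volume-share
    probability (1 = at chance); groups not listed default to 1.
    """

    enrichment: Mapping[str, float]
    total_cells: int = 2000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.enrichment.values()):
            raise ValueError("enrichment multipliers must be positive")
        if self.total_cells < 1:
            raise ValueError("total_cells must be >= 1")


def case_probabilities(p: Parcellation, truth: TracingTruth) -> pd.Series:
    """Per-group sampling probabilities: volume fraction x enrichment, renormalised."""
    vf = volume_fractions(p, level="group")
    mult = pd.Series(1.0, index=vf.index)
    for g, m in truth.enrichment.items():
        if g not in mult.index:
            raise KeyError(f"enrichment names unknown group {g!r}")
        mult[g] = m
    w = vf * mult
    return w / w.sum()


def generate_tracing_case(
    p: Parcellation, truth: TracingTruth, case_id: str = "case"
) -> tuple[CellCountTable, TracingTruth]:
    """Draw one multinomial cell-count case from the enriched volume model."""
    probs = case_probabilities(p, truth)
    rng = substream(truth.rng_seed, f"tracing-case:{case_id}")
    counts = rng.multinomial(truth.total_cells, probs.to_numpy())
    return CellCountTable(case_id, pd.Series(counts, index=probs.index)), truth


@dataclass(frozen=True)
class NetworkTruth:
    """Ground truth for the synthetic BOLD generator.

    ``loadings`` (voxel-grid x network non-negative weights) may be None
    before generation; the generator fills it in. ``snr`` is the ratio of
    unit latent-signal standard deviation to noise standard deviation at a
    voxel with loading 1; noise is added as (1/snr) x white noise.
    """

    n_networks: int = 1
    snr: float = 1.0
    tr_seconds: float = 2.0
    rng_seed: int = 0
    loadings: np.ndarray | None = None
    band_hz: tuple[float, float] = (0.01, 0.08)

    def __post_init__(self) -> None:
        if self.n_networks < 1:
            raise ValueError("n_networks must be >= 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")


def _ellipsoid_mask(grid_shape, voxel_mm, affine) -> np.ndarray:
    idx = np.indices(grid_shape).reshape(3, -1)
    xyz = (affine @ np.vstack([idx, np.ones(idx.shape[1])]))[:3]
    semi = 0.45 * np.asarray(grid_shape) * np.asarray(voxel_mm)
    inside = ((xyz.T / semi) ** 2).sum(axis=1) <= 1.0
    return inside.reshape(grid_shape)


def _centered_affine(grid_shape, voxel_mm) -> np.ndarray:
    """RAS+ affine with voxel sizes on the diagonal and the grid centred at 0 mm."""
    affine = np.eye(4)
    affine[:3, :3] = np.diag(voxel_mm)
    affine[:3, 3] = -(np.asarray(grid_shape) - 1) / 2.0 * np.asarray(voxel_mm)
    return affine


def _bandlimited_latents(
    k: int, t: int, tr: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """k orthogonalised, variance-normalised series confined to the band."""
    low, high = band
    nyq = 1.0 / (2.0 * tr)
    freqs = np.fft.rfftfreq(t, d=tr)
    keep = (freqs >= low) & (freqs <= high)
    if not keep.any():
        raise ValueError(
            f"band [{low}, {high}] Hz contains no resolvable frequency at "
            f"TR={tr}s (Nyquist {nyq:.4g} Hz, T={t})"
        )
    white = rng.standard_normal((k, t))
    spec = np.fft.rfft(white, axis=1)
    spec[:, ~keep] = 0.0
    s = np.fft.irfft(spec, n=t, axis=1)
    # orthogonalise so distinct networks are exactly uncorrelated in-sample
    q, _ = np.linalg.qr(s.T)
    s = q.T[:k]
    s = s - s.mean(axis=1, keepdims=True)
    s = s / s.std(axis=1, keepdims=True)
    return s


def _gaussian_bump(centers_mm, xyz, sigma_mm, peaks) -> np.ndarray:
    """Max over bumps: peak_c * exp(-d^2 / (2 sigma^2)) at each voxel."""
    centers = np.atleast_2d(centers_mm)
    peaks = np.broadcast_to(np.asarray(peaks, dtype=float), (len(centers),))
    load = np.zeros(xyz.shape[0])
    for c, pk in zip(centers, peaks):
        d2 = ((xyz - np.asarray(c, dtype=float)) ** 2).sum(axis=1)
        load = np.maximum(load, pk * np.exp(-d2 / (2.0 * sigma_mm**2)))
    return load


def generate_synthetic_bold(
    grid_shape: tuple[int, int, int],
    voxel_mm: tuple[float, float, float],
    t_points: int,
    truth: NetworkTruth,
    network_centers_mm: list[list[tuple[float, float, float]]] | None = None,
    bump_sigma_mm: float = 3.0,
    bump_peak: float | list = 0.9,
    baseline: float = 100.0,
) -> tuple[VolumeImage, NetworkTruth]:
    """Simulate a 4D BOLD image with planted latent networks.

    Each network k has a smooth non-negative loading field (Gaussian bumps
    around its centres, peak > 0.5 so every network has core voxels) and a
    band-limited unit-variance latent series s_k. A voxel's series is
    ``baseline + sum_k loading_vk * s_k + (1/snr) * white noise`` inside the
    ellipsoidal brain mask, constant baseline outside. Bit-reproducible for
    a fixed truth.rng_seed.
    """
    if t_points < 50:
        raise ValueError("t_points must be >= 50")
    grid_shape = tuple(int(g) for g in grid_shape)
    voxel_mm = tuple(float(v) for v in voxel_mm)
    affine = _centered_affine(grid_shape, voxel_mm)
    mask = _ellipsoid_mask(grid_shape, voxel_mm, affine)
    rng = substream(truth.rng_seed, "bold")

    k = truth.n_networks
    nvox = int(np.prod(grid_shape))
    idx = np.indices(grid_shape).reshape(3, -1)
    xyz = (affine @ np.vstack([idx, np.ones(nvox)]))[:3].T

    if truth.loadings is not None:
        loadings = np.asarray(truth.loadings, dtype=float).reshape(nvox, k)
    else:
        if network_centers_mm is None:
            # deterministic default: one bump per network, spread on a ring
            semi = 0.45 * np.asarray(grid_shape) * np.asarray(voxel_mm)
            angles = 2 * np.pi * np.arange(k) / max(k, 1)
            network_centers_mm = [
                [(0.5 * semi[0] * np.cos(a), 0.5 * semi[1] * np.sin(a), 0.0)]
                for a in angles
            ]
        peaks = bump_peak if isinstance(bump_peak, (list, tuple)) else [bump_peak] * k
        loadings = np.column_stack(
            [_gaussian_bump(network_centers_mm[j], xyz, bump_sigma_mm, peaks[j])
             for j in range(k)]
        )
    loadings = loadings * mask.reshape(-1, 1)
    total = loadings.sum(axis=1)
    over = total > 1.0
    if over.any():
        loadings[over] /= total[over, None]
    for j in range(k):
        if not (loadings[:, j] > 0.5).any():
            raise ValueError(f"network {j}: no voxel with loading > 0.5")

    latents = _bandlimited_latents(k, t_points, truth.tr_seconds, truth.band_hz, rng)
    data = np.full((nvox, t_points), float(baseline))
    signal_part = loadings @ latents
    noise = rng.standard_normal((int(mask.sum()), t_points)) / truth.snr
    flat_mask = mask.reshape(-1)
    data[flat_mask] += signal_part[flat_mask] + noise
    img = VolumeImage(
        data.reshape(*grid_shape, t_points), affine, mask, truth.tr_seconds
    )
    return img, replace(truth, loadings=loadings.reshape(*grid_shape, k))


@dataclass(frozen=True)
class DemoLayout:
    """A miniature two-arm study on synthetic data."""

    bold: VolumeImage
    truth: NetworkTruth
    seeds: list[SeedSpec]
    planted_seed_label: str
    masks: dict[str, np.ndarray]
    parcellation: Parcellation
    tracing_cases: list[CellCountTable]
    tracing_truths: dict[str, TracingTruth]
    enriched_group: str

    def seeds_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [s.label for s in self.seeds],
                "x_mm": [s.center_mm[0] for s in self.seeds],
                "y_mm": [s.center_mm[1] for s in self.seeds],
                "z_mm": [s.center_mm[2] for s in self.seeds],
                "radius_mm": [s.radius_mm for s in self.seeds],
            }
        )

    def counts_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.tracing_cases:
            row = {"case_id": c.case_id}
            row.update({g: int(v) for g, v in c.counts.items()})
            rows.append(row)
        return pd.DataFrame(rows)


#: geometry of the demo study (world mm on the default 20^3 x 2 mm grid)
_PLANTED_CENTER = (-8.0, -8.0, -4.0)
_DACC_CENTER = (8.0, 6.0, 4.0)
_AI_CENTER = (-6.0, 8.0, 6.0)
_DISTRACTOR_CENTER = (0.0, -12.0, 8.0)
#: off-network seed centres are kept >= ~12.5 mm from every planted loading
#: bump so that, at the default 3 mm seed radius, residual signal leakage into
#: the seed sphere is negligible against the noise floor
_OFF_NETWORK_SEEDS = {
    "rostral_47_12": (12.0, -6.0, -6.0),
    "mid_47_12": (-13.0, 4.0, -7.0),
    "area_45a": (2.0, 14.0, -6.0),
    "area_45b": (2.0, -2.0, -13.0),
    "area_6v": (6.0, -15.0, -2.0),
}


def make_demo_layout(
    grid_shape: tuple[int, int, int] = (20, 20, 20),
    voxel_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
    t_points: int = 300,
    snr: float = 1.0,
    seed_radius_mm: float = 3.0,
    mask_radius_mm: float = 4.0,
    enriched_group: str = "24",
    enrichment_factor: float = 3.0,
    total_cells: int = 2000,
    rng_seed: int = 0,
) -> DemoLayout:
    """Build the full miniature study design.

    One salience-like network spans the planted seed location and both target
    masks; a second distractor network lives elsewhere; the remaining seeds
    sit in unstructured noise or the distractor. The tracing arm provides two
    replicate cases with the same group enriched (to exercise the cross-case
    rank correlation) plus one unenriched control case.
    """
    truth = NetworkTruth(n_networks=2, snr=snr, rng_seed=rng_seed)
    centers = [
        [_PLANTED_CENTER, _DACC_CENTER, _AI_CENTER],  # salience-like network
        [_DISTRACTOR_CENTER],
    ]
    # The seed-site bump carries a strong loading; the mask sites sit in the
    # network's penumbra (moderate loading). Mask-mean statistics judged
    # against an exchangeability null are sensitive to map-wide coherent
    # shifts (chance correlation between a seed series and a latent), so a
    # realistic layout keeps mask purity moderate; the planted seed's true
    # effect remains an order of magnitude above the chance band.
    bold, truth = generate_synthetic_bold(
        grid_shape, voxel_mm, t_points, truth, network_centers_mm=centers,
        bump_peak=[[0.9, 0.3, 0.3], [0.9]],
    )

    seeds = [SeedSpec("caudal_47_12", _PLANTED_CENTER, seed_radius_mm)]
    seeds += [SeedSpec(lbl, c, seed_radius_mm) for lbl, c in _OFF_NETWORK_SEEDS.items()]
    seeds.append(SeedSpec("area_44", _DISTRACTOR_CENTER, seed_radius_mm))

    masks = {
        "dACC": build_spherical_seed(SeedSpec("dACC", _DACC_CENTER, mask_radius_mm), bold),
        "AI": build_spherical_seed(SeedSpec("AI", _AI_CENTER, mask_radius_mm), bold),
    }

    parc = default_parcellation(level="group")
    truths = {
        "caudal_47_12_case1": TracingTruth(
            {enriched_group: enrichment_factor}, total_cells, rng_seed
        ),
        "caudal_47_12_case2": TracingTruth(
            {enriched_group: enrichment_factor}, total_cells, rng_seed
        ),
        "control_case": TracingTruth({}, total_cells, rng_seed),
    }
    cases = [
        generate_tracing_case(parc, t, case_id)[0] for case_id, t in truths.items()
    ]
    return DemoLayout(
        bold=bold,
        truth=truth,
        seeds=seeds,
        planted_seed_label="caudal_47_12",
        masks=masks,
        parcellation=parc,
        tracing_cases=cases,
        tracing_truths=truths,
        enriched_group=enriched_group,
    )
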