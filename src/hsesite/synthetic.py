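"""Synthetic fixtures: geometric chains for HSE and datasets with planted signal.

Nothing here touches the network. Three generators cover the pipeline:

* ``make_helix_chain`` — an ideal α-helix-like Cα trace (1.5 Å rise, 100°
  twist, 2.3 Å radius) with Cβ placed radially outward, optionally jittered.
  Realistic enough that HSEα and HSEβ roughly agree, and simple enough that
  profiles can be checked against a naive reference.
* ``make_point_cloud_chain`` — uniformly packed random points with a minimum
  separation; an adversarial geometry for exercising the HSE neighbour and
  half-space logic.
* ``make_labeled_dataset`` — feature-level datasets emulating the
  statistical structure the classifier assumes: 124-dimensional vectors of
  baseline HSE counts plus Gaussian noise, where positive sites have the
  HSEα-up coordinates of the central five window positions shifted by
  ``effect_size`` noise standard deviations. Planting at the feature level
  isolates classifier and evaluation correctness from geometry.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import HALF_WIDTH, N_FEATURES, LabeledDataset
from .structio import ProteinChain, ResidueGeometry, SiteAnnotation


@dataclass(frozen=True)
class HelixParams:
    """Geometry of the ideal helix trace (Å and degrees); ``jitter_sd`` adds
    seeded Gaussian displacement to every atom."""

    n_residues: int
    rise: float = 1.5
    helix_radius: float = 2.3
    twist: float = 100.0
    cb_offset: float = 1.5
    seed: int = 0
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.rise <= 0 or self.helix_radius <= 0:
            raise ValueError("rise and helix_radius must be positive")


def make_helix_chain(p: HelixParams) -> ProteinChain:
    """An all-lysine chain on an ideal helical Cα trace with radial Cβ."""
    rng = np.random.default_rng(p.seed)
    theta = np.deg2rad(p.twist) * np.arange(p.n_residues)
    ca = np.column_stack(
        [
            p.helix_radius * np.cos(theta),
            p.helix_radius * np.sin(theta),
            p.rise * np.arange(p.n_residues),
        ]
    )
    cb = np.column_stack(
        [
            (p.helix_radius + p.cb_offset) * np.cos(theta),
            (p.helix_radius + p.cb_offset) * np.sin(theta),
            p.rise * np.arange(p.n_residues),
        ]
    )
    if p.jitter_sd > 0:
        ca = ca + rng.normal(0.0, p.jitter_sd, ca.shape)
        cb = cb + rng.normal(0.0, p.jitter_sd, cb.shape)
    geometry = [ResidueGeometry(ca=a, cb=b) for a, b in zip(ca, cb)]
    return ProteinChain(
        id=f"helix{p.n_residues}",
        sequence="K" * p.n_residues,
        geometry=geometry,
    )


def make_point_cloud_chain(
    n: int, box: float = 40.0, min_sep: float = 3.5, seed: int = 0
) -> ProteinChain:
    """Uniform random Cα points in a cube with rejection for minimum
    separation; Cβ sits 1.5 Å away in a random direction. Raises if the
    requested packing cannot be reached within a bounded number of draws."""
    rng = np.random.default_rng(seed)
    points: list[np.ndarray] = []
    attempts = 0
    max_attempts = 1000 * n
    while len(points) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not pack {n} points with min_sep={min_sep} in box={box}"
            )
        cand = rng.uniform(0.0, box, size=3)
        if all(np.linalg.norm(cand - q) >= min_sep for q in points):
            points.append(cand)
    geometry = []
    for pt in points:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        geometry.append(ResidueGeometry(ca=pt, cb=pt + 1.5 * direction))
    return ProteinChain(id=f"cloud{n}", sequence="K" * n, geometry=geometry)


@dataclass(frozen=True)
class PlantedSignalParams:
    """n_pos/n_neg: class sizes; effect_size: shift (in units of noise SD)
    added to the HSEα-up coordinates of the central 5 window positions of
    positive sites; base_counts: baseline values for the 4 HSE measures."""

    n_pos: int
    n_neg: int
    effect_size: float = 0.0
    noise_sd: float = 1.0
    base_counts: tuple[float, float, float, float] = (10.0, 10.0, 10.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class counts must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


#: feature indices of HSEα-up at window offsets -2..+2 (offset-major layout)
SIGNAL_INDICES = tuple(4 * (o + HALF_WIDTH) for o in range(-2, 3))


def make_labeled_dataset(p: PlantedSignalParams) -> LabeledDataset:
    """Feature-level dataset with a tunable planted class difference.

    Positives come first, then negatives; real-valued features are fine
    downstream (predicted HSE profiles are real-valued too).
    """
    rng = np.random.default_rng(p.seed)
    n = p.n_pos + p.n_neg
    base = np.tile(np.asarray(p.base_counts, dtype=float), N_FEATURES // 4)
    X = base + rng.normal(0.0, p.noise_sd, size=(n, N_FEATURES))
    X[: p.n_pos, list(SIGNAL_INDICES)] += p.effect_size * p.noise_sd
    y = np.concatenate([np.ones(p.n_pos, dtype=int), np.zeros(p.n_neg, dtype=int)])
    sites = [
        SiteAnnotation(f"synth{i:05d}", HALF_WIDTH + 1, int(lab))
        for i, lab in enumerate(y)
    ]
    return LabeledDataset(X=X, y=y, sites=sites)
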