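"""Half-sphere exposure (HSE) from Cα/Cβ coordinates.

HSE is a residue-level solvent-exposure measure: a sphere of radius R
(default 12 Å) centred on a residue's Cα is split into two half-spheres by a
plane through the Cα, and the Cα atoms of other residues falling in each half
are counted. Two variants differ only in the vector that orients the plane:

* **HSEβ** uses the Cα→Cβ vector; the half-sphere containing Cβ is "up".
* **HSEα** uses a pseudo-vector built from the two flanking Cα positions,
  u = -[(Cα_{i-1} - Cα_i) + (Cα_{i+1} - Cα_i)], so no Cβ is required. The
  negated sum points away from the backbone, approximating the Cβ direction;
  set ``alpha_points_outward=False`` to flip the convention.

For each variant ``up + down`` equals the total number of Cα neighbours
within R, so the two variants always agree on their sum where both are
defined.

Boundary conventions (sphere surface, dividing plane) are not part of the
mathematical definition and are exposed on :class:`HseConfig` rather than
hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .structio import ProteinChain

A_UP, A_DOWN, B_UP, B_DOWN = 0, 1, 2, 3
MEASURES = ("hse_a_up", "hse_a_down", "hse_b_up", "hse_b_down")


@dataclass(frozen=True)
class HseConfig:
    """Parameters of the HSE computation.

    radius: sphere radius in Å (the conventional value is 12).
    tie_rule: which half receives a neighbour lying exactly on the dividing
        plane (dot product zero); "down" or "up".
    inclusive_radius: whether a neighbour exactly at distance R counts.
    alpha_points_outward: sign of the HSEα pseudo-vector (see module docs).
    """

    radius: float = 12.0
    tie_rule: str = "down"
    inclusive_radius: bool = True
    alpha_points_outward: bool = True

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.tie_rule not in ("up", "down"):
            raise ValueError("tie_rule must be 'up' or 'down'")


@dataclass
class HseProfile:
    """Per-residue HSE counts for one chain.

    values: (L, 4) array ordered (HSEα-up, HSEα-down, HSEβ-up, HSEβ-down).
    positions: 1-based residue positions aligned with rows of ``values``.
    alpha_defined: False where no flanking Cα exists (single-residue chain).
    beta_fallback: True where Cβ was missing and the HSEα pseudo-vector was
        used to orient the HSEβ half-spheres (glycine, incomplete residues).
    degenerate: True where the orienting vector vanished (collinear flanks)
        and every neighbour was assigned by the tie rule.
    """

    positions: np.ndarray
    values: np.ndarray
    residues: str | None = None
    alpha_defined: np.ndarray | None = None
    beta_fallback: np.ndarray | None = None
    degenerate: np.ndarray | None = None
    _index: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.positions), 4):
            raise ValueError("values must be (len(positions), 4)")
        if (self.values < 0).any():
            raise ValueError("HSE counts must be non-negative")
        if self.alpha_defined is None:
            self.alpha_defined = np.ones(len(self.positions), dtype=bool)
        if self.beta_fallback is None:
            self.beta_fallback = np.zeros(len(self.positions), dtype=bool)
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.positions), dtype=bool)
        self._index = {int(p): i for i, p in enumerate(self.positions)}
        if len(self._index) != len(self.positions):
            raise ValueError("duplicate positions in profile")

    def __len__(self) -> int:
        return len(self.positions)

    def value_at(self, position: int) -> np.ndarray:
        """The 4 HSE values at a 1-based position; KeyError if absent."""
        try:
            return self.values[self._index[int(position)]]
        except KeyError:
            raise KeyError(f"no HSE values at position {position}") from None


def neighbor_set(
    chain: "ProteinChain", i: int, cfg: HseConfig = HseConfig()
) -> np.ndarray:
    """Displacements Cα_j − Cα_i for all j ≠ i within the sphere radius.

    The residue itself is excluded; sequence neighbours are not (no i±1
    exclusion). Boundary handling follows ``cfg.inclusive_radius``.
    """
    ca = chain.ca_coords()
    disp = ca - ca[i]
    dist = np.linalg.norm(disp, axis=1)
    if cfg.inclusive_radius:
        mask = dist <= cfg.radius
    else:
        mask = dist < cfg.radius
    mask[i] = False
    return disp[mask]


def _split(u: np.ndarray, disps: np.ndarray, cfg: HseConfig) -> tuple[int, int, bool]:
    """Partition neighbour displacements into (up, down) halves along ``u``.

    Returns (up, down, degenerate); degenerate means ``u`` had zero norm, in
    which case every dot product is zero and the tie rule decides everything.
    """
    degenerate = bool(np.linalg.norm(u) == 0.0)
    if len(disps) == 0:
        return 0, 0, degenerate
    dots = disps @ u
    if cfg.tie_rule == "up":
        up = dots >= 0.0
    else:
        up = dots > 0.0
    n_up = int(np.count_nonzero(up))
    return n_up, len(disps) - n_up, degenerate


def _alpha_up_vector(chain: "ProteinChain", i: int, cfg: HseConfig) -> np.ndarray | None:
    """HSEα pseudo-vector at residue i; None when no flanking Cα exists.

    At chain termini only the single available flank contributes.
    """
    ca = chain.ca_coords()
    s = np.zeros(3)
    have_flank = False
    if i > 0:
        s += ca[i - 1] - ca[i]
        have_flank = True
    if i < len(ca) - 1:
        s += ca[i + 1] - ca[i]
        have_flank = True
    if not have_flank:
        return None
    return -s if cfg.alpha_points_outward else s


def hse_alpha(
    chain: "ProteinChain", i: int, cfg: HseConfig = HseConfig()
) -> tuple[int, int]:
    """(up, down) counts for the HSEα variant at residue i.

    An isolated residue (no flanking Cα) has the variant undefined and
    returns (0, 0); :func:`compute_profile` records this in
    ``alpha_defined``.
    """
    u = _alpha_up_vector(chain, i, cfg)
    if u is None:
        return 0, 0
    up, down, _ = _split(u, neighbor_set(chain, i, cfg), cfg)
    return up, down


def hse_beta(
    chain: "ProteinChain", i: int, cfg: HseConfig = HseConfig()
) -> tuple[int, int]:
    """(up, down) counts for the HSEβ variant at residue i.

    When Cβ is missing (glycine) the HSEα pseudo-vector orients the
    half-spheres instead; :func:`compute_profile` flags the fallback.
    """
    if chain.geometry is None:
        raise ValueError("chain has no geometry")
    geo = chain.geometry[i]
    if geo.cb is not None:
        u = geo.cb - geo.ca
    else:
        u = _alpha_up_vector(chain, i, cfg)
        if u is None:
            return 0, 0
    up, down, _ = _split(u, neighbor_set(chain, i, cfg), cfg)
    return up, down


def compute_profile(
    chain: "ProteinChain", cfg: HseConfig = HseConfig()
) -> HseProfile:
    """All four HSE counts for every residue of a chain with geometry."""
    if chain.geometry is None:
        raise ValueError("chain has no geometry")
    n = len(chain)
    if n < 1:
        raise ValueError("chain must contain at least one residue")
    values = np.zeros((n, 4), dtype=float)
    alpha_defined = np.ones(n, dtype=bool)
    beta_fallback = np.zeros(n, dtype=bool)
    degenerate = np.zeros(n, dtype=bool)
    for i in range(n):
        disps = neighbor_set(chain, i, cfg)
        u_alpha = _alpha_up_vector(chain, i, cfg)
        if u_alpha is None:
            alpha_defined[i] = False
        else:
            up, down, degen = _split(u_alpha, disps, cfg)
            values[i, A_UP], values[i, A_DOWN] = up, down
            degenerate[i] |= degen
        geo = chain.geometry[i]
        if geo.cb is not None:
            u_beta = geo.cb - geo.ca
        else:
            beta_fallback[i] = True
            u_beta = u_alpha
        if u_beta is not None:
            up, down, degen = _split(u_beta, disps, cfg)
            values[i, B_UP], values[i, B_DOWN] = up, down
            degenerate[i] |= degen
    return HseProfile(
        positions=np.array(chain.residue_numbers, dtype=int),
        values=values,
        residues=chain.sequence,
        alpha_defined=alpha_defined,
        beta_fallback=beta_fallback,
        degenerate=degenerate,
    )
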