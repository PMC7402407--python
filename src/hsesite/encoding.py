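"""Windowed HSE encoding of annotated lysines.

Each site is described by a segment of 31 residues — the lysine plus 15
upstream and 15 downstream neighbours. Near a terminus the window is
completed by mirror padding: out-of-range positions are reflected about the
terminal residue (p → 2 − p below position 1, p → 2L − p above position L,
iterated until in range). With the 4 HSE measures per residue this yields a
124-dimensional feature vector per site.

Feature ordering is offset-major, measure-minor: measure m at window offset
o ∈ [−15, +15] lands at index 4·(o+15) + m, with measures ordered
(HSEα-up, HSEα-down, HSEβ-up, HSEβ-down). The trained model and the feature
matrix CSV both depend on this contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .hse import HseProfile
from .structio import ProteinChain, SiteAnnotation

logger = logging.getLogger(__name__)

HALF_WIDTH = 15
WINDOW = 2 * HALF_WIDTH + 1  # 31
N_FEATURES = WINDOW * 4  # 124


@dataclass(frozen=True)
class SiteSegment:
    """The 31 resolved sequence positions around one lysine."""

    protein_id: str
    center: int
    resolved_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        w = (len(self.resolved_positions) - 1) // 2
        if self.resolved_positions[w] != self.center:
            raise ValueError("middle of segment must be the site itself")


@dataclass(frozen=True)
class FeatureVector:
    """One encoded site: 4 HSE measures per window position (124 values for
    the default 31-residue window) plus its annotation."""

    values: np.ndarray
    site: SiteAnnotation | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(values) % 4 or len(values) == 0:
            raise ValueError("feature vector must be 4 values per window position")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature vector contains non-finite values")


@dataclass
class LabeledDataset:
    """Feature matrix + binary labels + per-row site provenance."""

    X: np.ndarray
    y: np.ndarray
    sites: list[SiteAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")
        if self.sites and len(self.sites) != len(self.y):
            raise ValueError("sites and y lengths differ")
        if not self.sites:
            self.sites = [
                SiteAnnotation(f"row{i}", 1, int(lab)) for i, lab in enumerate(self.y)
            ]
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be 0/1")

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, indices: np.ndarray) -> "LabeledDataset":
        indices = np.asarray(indices, dtype=int)
        return LabeledDataset(
            X=self.X[indices],
            y=self.y[indices],
            sites=[self.sites[i] for i in indices],
        )


def resolve_segment(
    length: int, center: int, half_width: int = HALF_WIDTH, protein_id: str = ""
) -> SiteSegment:
    """Resolve the window positions around ``center`` with mirror padding.

    Raw positions center−w … center+w; any position below 1 reflects to
    2 − p, any above L to 2L − p, applied iteratively. A length-1 sequence
    cannot be padded (the reflection never terminates inside the range).
    """
    if not 1 <= center <= length:
        raise ValueError(f"center {center} outside sequence of length {length}")
    if length == 1 and half_width > 0:
        raise ValueError("cannot mirror-pad a window on a length-1 sequence")
    positions = []
    for offset in range(-half_width, half_width + 1):
        p = center + offset
        while p < 1 or p > length:
            if p < 1:
                p = 2 - p
            if p > length:
                p = 2 * length - p
        positions.append(p)
    return SiteSegment(
        protein_id=protein_id, center=center, resolved_positions=tuple(positions)
    )


def encode_site(
    profile: HseProfile, segment: SiteSegment, site: SiteAnnotation | None = None
) -> FeatureVector:
    """Concatenate the 4 HSE measures over the 31 window positions.

    Pure: the same profile and segment always yield the identical vector.
    Raises KeyError naming protein and position when the profile does not
    cover a resolved position.
    """
    values = np.empty(4 * len(segment.resolved_positions), dtype=float)
    for slot, pos in enumerate(segment.resolved_positions):
        try:
            values[4 * slot : 4 * slot + 4] = profile.value_at(pos)
        except KeyError:
            raise KeyError(
                f"protein {segment.protein_id!r}: no HSE values at position {pos}"
            ) from None
    return FeatureVector(values=values, site=site)


def build_dataset(
    chains,
    profiles: dict[str, HseProfile],
    sites: list[SiteAnnotation],
    half_width: int = HALF_WIDTH,
    strict: bool = False,
) -> LabeledDataset:
    """Encode every annotated site into a labeled dataset.

    Sites are validated against the sequences: the protein must be known,
    the position in range, and the residue a lysine. Invalid sites are
    skipped with a warning (``strict=True`` makes them fatal); output order
    follows input site order.
    """
    if not isinstance(chains, dict):
        chains = {c.id: c for c in chains}
    vectors: list[np.ndarray] = []
    labels: list[int] = []
    kept: list[SiteAnnotation] = []
    skipped = 0
    for site in sites:
        try:
            chain = chains.get(site.protein_id)
            if chain is None:
                raise KeyError(f"unknown protein {site.protein_id!r}")
            if not 1 <= site.position <= len(chain):
                raise ValueError(
                    f"{site.protein_id}: position {site.position} outside sequence"
                )
            if chain.sequence[site.position - 1] != "K":
                raise ValueError(
                    f"{site.protein_id}: position {site.position} is "
                    f"{chain.sequence[site.position - 1]!r}, not lysine"
                )
            profile = profiles.get(site.protein_id)
            if profile is None:
                raise KeyError(f"no HSE profile for {site.protein_id!r}")
            segment = resolve_segment(
                len(chain), site.position, half_width, protein_id=site.protein_id
            )
            fv = encode_site(profile, segment, site)
        except (KeyError, ValueError) as exc:
            if strict:
                raise
            logger.warning("skipping site %s:%d: %s", site.protein_id, site.position, exc)
            skipped += 1
            continue
        vectors.append(fv.values)
        labels.append(site.label)
        kept.append(site)
    if skipped:
        logger.warning("skipped %d of %d sites", skipped, len(sites))
    if not vectors:
        raise ValueError("no valid sites to encode")
    return LabeledDataset(X=np.vstack(vectors), y=np.array(labels), sites=kept)
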