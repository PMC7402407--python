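"""Readers and writers for every on-disk format the pipeline touches.

Formats: PDB structures (read, via Biopython; write, minimal ATOM records for
synthetic chains), FASTA sequences, TSV site annotations, TSV per-residue HSE
profiles, and the CSV feature matrix produced by the encoder.

Positions throughout are 1-based indices into the *parsed* sequence, not
author PDB residue numbers; ``ProteinChain.author_ids`` keeps the original
numbering so a mapping table can be emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_3to1
from Bio.PDB import PDBParser

from .hse import HseProfile

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .encoding import LabeledDataset

logger = logging.getLogger(__name__)

VALID_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: one-letter codes for the 20 standard residues, anything else becomes 'X'
_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}


@dataclass(frozen=True)
class ResidueGeometry:
    """Cα coordinate (required) and Cβ coordinate (absent for glycine or
    when the atom is missing from the structure), both in Å."""

    ca: np.ndarray
    cb: np.ndarray | None = None

    def __post_init__(self) -> None:
        ca = np.asarray(self.ca, dtype=float)
        object.__setattr__(self, "ca", ca)
        if ca.shape != (3,) or not np.all(np.isfinite(ca)):
            raise ValueError("ca must be a finite 3-vector")
        if self.cb is not None:
            cb = np.asarray(self.cb, dtype=float)
            object.__setattr__(self, "cb", cb)
            if cb.shape != (3,) or not np.all(np.isfinite(cb)):
                raise ValueError("cb must be a finite 3-vector")


@dataclass
class ProteinChain:
    """A single protein chain: sequence plus optional per-residue geometry.

    ``residue_numbers`` are 1-based positions into ``sequence``;
    ``author_ids`` (when parsed from a PDB file) records the original
    residue identifiers ("<resseq><icode>") aligned with the sequence.
    """

    id: str
    sequence: str
    residue_numbers: list[int] = field(default_factory=list)
    geometry: list[ResidueGeometry] | None = None
    author_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.residue_numbers:
            self.residue_numbers = list(range(1, len(self.sequence) + 1))
        if len(self.residue_numbers) != len(self.sequence):
            raise ValueError("residue_numbers and sequence lengths differ")
        if any(b <= a for a, b in zip(self.residue_numbers, self.residue_numbers[1:])):
            raise ValueError("residue_numbers must be strictly increasing")
        bad = set(self.sequence) - VALID_LETTERS
        if bad:
            raise ValueError(f"invalid sequence letters: {sorted(bad)}")
        if self.geometry is not None and len(self.geometry) != len(self.sequence):
            raise ValueError("geometry and sequence lengths differ")
        if self.author_ids is not None and len(self.author_ids) != len(self.sequence):
            raise ValueError("author_ids and sequence lengths differ")

    def __len__(self) -> int:
        return len(self.sequence)

    def ca_coords(self) -> np.ndarray:
        """(L, 3) array of Cα coordinates; raises if geometry is absent."""
        if self.geometry is None:
            raise ValueError(f"chain {self.id!r} has no geometry")
        return np.array([g.ca for g in self.geometry], dtype=float)


@dataclass(frozen=True)
class SiteAnnotation:
    """One annotated lysine: 1-based sequence position and binary label
    (1 = sumoylated, 0 = non-sumoylated)."""

    protein_id: str
    position: int
    label: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


# ---------------------------------------------------------------------------
# PDB


def read_pdb(path: str | Path, chain_id: str | None = None) -> ProteinChain:
    """Parse one chain from a PDB file into a :class:`ProteinChain`.

    Dialect: first model only; for alternate locations the first-listed
    conformer is kept; HETATM records are ignored; residues without a Cα are
    skipped with a warning; nonstandard residues map to 'X'. Cβ is taken when
    present (glycine has none).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    try:
        model = next(iter(structure))
    except StopIteration:
        raise ValueError(f"{path}: no models found") from None
    if chain_id is None:
        try:
            chain = next(iter(model))
        except StopIteration:
            raise ValueError(f"{path}: no chains found") from None
    else:
        if not model.has_id(chain_id):
            raise KeyError(f"{path}: chain {chain_id!r} not found")
        chain = model[chain_id]

    letters: list[str] = []
    geometry: list[ResidueGeometry] = []
    author_ids: list[str] = []
    for residue in chain:
        hetflag, resseq, icode = residue.id
        if hetflag.strip():
            continue  # HETATM / water
        ca = _first_conformer(residue, "CA")
        if ca is None:
            logger.warning(
                "%s chain %s residue %s%s: no CA atom, skipped",
                path.name, chain.id, resseq, icode.strip(),
            )
            continue
        cb = _first_conformer(residue, "CB")
        letters.append(_THREE_TO_ONE.get(residue.resname.strip().upper(), "X"))
        geometry.append(ResidueGeometry(ca=ca, cb=cb))
        author_ids.append(f"{resseq}{icode.strip()}")
    if not letters:
        raise ValueError(f"{path}: chain {chain.id!r} has no residues with CA")
    return ProteinChain(
        id=chain.id if chain_id is not None else path.stem,
        sequence="".join(letters),
        residue_numbers=list(range(1, len(letters) + 1)),
        geometry=geometry,
        author_ids=author_ids,
    )


def _first_conformer(residue, name: str) -> np.ndarray | None:
    if not residue.has_id(name):
        return None
    atom = residue[name]
    if atom.is_disordered():
        atom = atom.disordered_get_list()[0]  # first-listed altloc
    return np.asarray(atom.coord, dtype=float)


def write_pdb(chain: ProteinChain, path: str | Path) -> None:
    """Write a chain's Cα/Cβ geometry as fixed-width ATOM records."""
    if chain.geometry is None:
        raise ValueError("chain has no geometry to write")
    three = {v: k.upper() for k, v in protein_letters_3to1.items()}
    lines = []
    serial = 1
    for pos, (letter, geo) in enumerate(zip(chain.sequence, chain.geometry), start=1):
        resname = three.get(letter, "UNK")
        for name, xyz in (("CA", geo.ca), ("CB", geo.cb)):
            if xyz is None:
                continue
            lines.append(
                f"ATOM  {serial:5d} {name:^4s} {resname:>3s} A{pos:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {name[0]:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_residue_mapping(chain: ProteinChain, path: str | Path) -> None:
    """TSV mapping of 1-based sequence positions to author PDB residue ids."""
    author = chain.author_ids or [str(n) for n in chain.residue_numbers]
    pd.DataFrame(
        {
            "position": chain.residue_numbers,
            "residue": list(chain.sequence),
            "author_id": author,
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinChain]:
    """Read FASTA records as geometry-free chains.

    Ids are the header up to the first whitespace; sequences are uppercased;
    duplicate ids and empty files are errors.
    """
    chains: list[ProteinChain] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate FASTA id {record.id!r}")
        seen.add(record.id)
        seq = str(record.seq).upper()
        seq = "".join(c if c in VALID_LETTERS else "X" for c in seq)
        chains.append(ProteinChain(id=record.id, sequence=seq))
    if not chains:
        raise ValueError(f"{path}: no FASTA records")
    return chains


# ---------------------------------------------------------------------------
# Site annotations


def read_sites(path: str | Path) -> list[SiteAnnotation]:
    """Read a TSV of site annotations (header: protein_id, position, label)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "position", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"site table must have columns {sorted(required)}")
    sites = []
    for row in df.itertuples(index=False):
        pos = int(row.position)
        if pos != row.position:
            raise ValueError(f"non-integer position {row.position!r}")
        sites.append(SiteAnnotation(str(row.protein_id), pos, int(row.label)))
    return sites


def write_sites(sites: Iterable[SiteAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(s.protein_id, s.position, s.label) for s in sites],
        columns=["protein_id", "position", "label"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# HSE profiles

_PROFILE_COLUMNS = [
    "protein_id", "position", "residue",
    "hse_a_up", "hse_a_down", "hse_b_up", "hse_b_down",
]


def read_hse_profile(path: str | Path) -> dict[str, HseProfile]:
    """Read per-residue HSE profiles keyed by protein id.

    Counts are usually non-negative integers but real values are accepted
    (sequence-predicted profiles are real-valued); negative values and
    duplicate (protein, position) pairs are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    if not set(_PROFILE_COLUMNS).issubset(df.columns):
        raise ValueError(f"profile table must have columns {_PROFILE_COLUMNS}")
    value_cols = _PROFILE_COLUMNS[3:]
    if (df[value_cols].to_numpy(dtype=float) < 0).any():
        raise ValueError("HSE counts must be non-negative")
    if df.duplicated(subset=["protein_id", "position"]).any():
        raise ValueError("duplicate (protein_id, position) in profile table")
    profiles: dict[str, HseProfile] = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        grp = grp.sort_values("position")
        profiles[str(pid)] = HseProfile(
            positions=grp["position"].to_numpy(dtype=int),
            values=grp[value_cols].to_numpy(dtype=float),
            residues="".join(grp["residue"].astype(str)),
        )
    return profiles


def write_hse_profile(
    profiles: Mapping[str, HseProfile], path: str | Path
) -> None:
    frames = []
    for pid, prof in profiles.items():
        residues = list(prof.residues) if prof.residues else ["X"] * len(prof.positions)
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": pid,
                    "position": prof.positions,
                    "residue": residues,
                    "hse_a_up": prof.values[:, 0],
                    "hse_a_down": prof.values[:, 1],
                    "hse_b_up": prof.values[:, 2],
                    "hse_b_down": prof.values[:, 3],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Feature matrix

N_FEATURES = 124  # 31 window positions x 4 HSE measures
FEATURE_COLUMNS = [f"f_{i:03d}" for i in range(N_FEATURES)]


def write_feature_matrix(dataset: "LabeledDataset", path: str | Path) -> None:
    """Write a labeled dataset as CSV: protein_id, position, label, f_000..f_123."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    meta = pd.DataFrame(
        {
            "protein_id": [s.protein_id for s in dataset.sites],
            "position": [s.position for s in dataset.sites],
            "label": dataset.y,
        }
    )
    feats = pd.DataFrame(dataset.X, columns=FEATURE_COLUMNS)
    pd.concat([meta, feats], axis=1).to_csv(path, index=False)


def read_feature_matrix(path: str | Path) -> "LabeledDataset":
    from .encoding import LabeledDataset

    df = pd.read_csv(path, dtype={"protein_id": str})
    missing = {"protein_id", "position", "label", *FEATURE_COLUMNS} - set(df.columns)
    if missing:
        raise ValueError(f"feature matrix missing columns: {sorted(missing)[:5]} ...")
    sites = [
        SiteAnnotation(str(p), int(pos), int(lab))
        for p, pos, lab in zip(df["protein_id"], df["position"], df["label"])
    ]
    return LabeledDataset(
        X=df[FEATURE_COLUMNS].to_numpy(dtype=float),
        y=df["label"].to_numpy(dtype=int),
        sites=sites,
    )
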