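"""Read and write protein structures in PDB format.

The in-memory model is deliberately backbone-centric: a :class:`Structure`
is an ordered map of chains to residues, each residue an ordered list of
atoms with coordinates and a B-factor.  For predicted models the B-factor
column carries the per-residue confidence score (pLDDT, 0-100), as in
AlphaFold Database files; for experimental structures it is the
crystallographic B-factor.  Structures are therefore tagged ``experimental``
or ``predicted`` and confidence-specific operations refuse the wrong tag.

Parsing is backed by gemmi; only polymer ATOM records of the first model
are kept, waters and HETATM records are dropped, and alternate conformers
are resolved to the highest-occupancy altloc (ties broken alphabetically).
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "StructureError",
    "EmptyStructureError",
    "ParseError",
    "SourceTagError",
    "read_structure",
    "write_structure",
    "plddt_profile",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")


class StructureError(Exception):
    """Base class for structure I/O and contract errors."""


class EmptyStructureError(StructureError):
    """File contained no usable polymer ATOM records."""


class ParseError(StructureError):
    """Malformed structure file."""


class SourceTagError(StructureError):
    """Operation applied to a structure with the wrong source tag."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    bfactor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name!r}: coords must be a finite 3-vector")


@dataclass
class Residue:
    aa: str                 # one-letter code, X for nonstandard
    seq_id: str             # author residue number + insertion code
    name: str               # three-letter residue name
    atoms: list[Atom] = field(default_factory=list)

    def get(self, atom_name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == atom_name:
                return a
        return None

    def coord(self, atom_name: str) -> np.ndarray | None:
        a = self.get(atom_name)
        return None if a is None else a.coords

    @property
    def is_complete(self) -> bool:
        """True when the N, CA, C backbone triplet is present."""
        return all(self.get(n) is not None for n in ("N", "CA", "C"))


@dataclass
class Structure:
    id: str
    source: str                                  # "experimental" | "predicted"
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)     # generator/provenance extras

    def __post_init__(self) -> None:
        if self.source not in ("experimental", "predicted"):
            raise StructureError(f"unknown source tag {self.source!r}")

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    @property
    def n_atoms(self) -> int:
        return sum(len(res.atoms) for res in self.iter_residues())

    def iter_residues(self):
        for residues in self.chains.values():
            yield from residues

    def sequence(self, chain: str) -> str:
        return "".join(r.aa for r in self.chains[chain])


_ONE_LETTER_CACHE: dict[str, str] = {}


def _one_letter(resname: str) -> str:
    code = _ONE_LETTER_CACHE.get(resname)
    if code is None:
        info = gemmi.find_tabulated_residue(resname)
        if info is not None and info.is_amino_acid():
            code = info.one_letter_code.upper()
            if code not in string.ascii_uppercase:
                code = "X"
        else:
            code = "X"
        _ONE_LETTER_CACHE[resname] = code
    return code


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """One atom per name: highest occupancy wins, ties to the first altloc."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for atom in res:
        by_name.setdefault(atom.name, []).append(atom)
    picked = []
    for name, group in by_name.items():
        group.sort(key=lambda a: (-a.occ, a.altloc or "~"))
        picked.append(group[0])
    return picked


def read_structure(path: str | Path, source_tag: str) -> Structure:
    """Parse a PDB (or mmCIF) file into a :class:`Structure`.

    Only polymer ATOM records of the first model are retained.  HETATM
    records and waters are excluded; duplicated altlocs keep the
    highest-occupancy conformer.  Nonstandard residues are mapped to ``X``
    and kept only if they carry N, CA, C backbone atoms.
    """
    path = Path(path)
    if source_tag not in ("experimental", "predicted"):
        raise SourceTagError(f"unknown source tag {source_tag!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports position in message
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]

    out = Structure(id=path.stem, source=source_tag)
    for chain in model:
        residues: list[Residue] = []
        seen_ids: set[str] = set()
        for res in chain:
            if res.is_water() or res.het_flag == "H":
                continue
            aa = _one_letter(res.name)
            atoms = _resolve_altlocs(res)
            names = {a.name for a in atoms}
            if aa == "X" and not {"N", "CA", "C"} <= names:
                continue  # ligand-like ATOM record without a backbone
            seq_id = f"{res.seqid.num}{res.seqid.icode.strip()}"
            if seq_id in seen_ids:
                continue  # duplicate (chain, seq_id): keep the first occurrence
            seen_ids.add(seq_id)
            residues.append(
                Residue(
                    aa=aa,
                    seq_id=seq_id,
                    name=res.name,
                    atoms=[
                        Atom(
                            name=a.name,
                            element=a.element.name,
                            coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                            bfactor=a.b_iso,
                            occupancy=a.occ,
                            altloc=(a.altloc or "").strip(),
                        )
                        for a in atoms
                    ],
                )
            )
        if residues:
            out.chains[chain.name] = residues
    if out.n_atoms == 0:
        raise EmptyStructureError(f"{path}: no polymer ATOM records")
    return out


def _split_seq_id(seq_id: str) -> tuple[int, str]:
    digits = seq_id
    icode = ""
    if seq_id and seq_id[-1].isalpha():
        digits, icode = seq_id[:-1], seq_id[-1]
    return int(digits), icode


def _format_atom_name(name: str) -> str:
    # Names up to 3 characters start in column 14 (PDB convention).
    return f" {name:<3s}" if len(name) < 4 else name[:4]


def write_structure(s: Structure, path: str | Path) -> None:
    """Write fixed-column PDB ATOM records, serial numbers renumbered from 1."""
    if s.n_atoms == 0:
        raise StructureError("refusing to write an empty structure")
    lines = []
    serial = 0
    for chain_id, residues in s.chains.items():
        for res in residues:
            num, icode = _split_seq_id(res.seq_id)
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:5d} {_format_atom_name(atom.name)}{atom.altloc[:1] or ' '}"
                    f"{res.name:>3s} {chain_id[:1]}{num:4d}{icode or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
                    f"          {atom.element:>2s}"
                )
        serial += 1
        lines.append(f"TER   {serial:5d}      {residues[-1].name:>3s} "
                     f"{chain_id[:1]}{_split_seq_id(residues[-1].seq_id)[0]:4d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def plddt_profile(s: Structure) -> list[tuple[Residue, float]]:
    """Per-residue mean-over-atoms confidence for a predicted structure.

    AlphaFold stores the per-residue pLDDT on every atom of the residue, so
    the mean over atoms recovers it; refuses experimental structures, whose
    B-factor column is a crystallographic B-factor, not a confidence.
    """
    if s.source != "predicted":
        raise SourceTagError("pLDDT profile requires a predicted-source structure "
                             "(experimental B-factors are not confidence scores)")
    profile = []
    for res in s.iter_residues():
        if not res.atoms:
            continue
        vals = np.array([a.bfactor for a in res.atoms])
        if np.any(vals > 100.0):
            warnings.warn(f"residue {res.seq_id}: B-factor above 100 in a predicted "
                          "structure; value does not look like a pLDDT", stacklevel=2)
        profile.append((res, float(vals.mean())))
    return profile
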