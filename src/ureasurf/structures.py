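"""Protein structure model and PDB input/output.

A deliberately small atom/residue/chain hierarchy tailored to surface-area
analysis: coordinates in Angstrom, author residue numbering preserved, and a
per-atom van der Waals radius assigned from a named, pinned radii table so
that surface counts are reproducible and attributable to an explicit
parameter choice.  Heavy lifting of the fixed-column PDB format is delegated
to gemmi; this module owns the domain model, the heteroatom/water stripping,
alternate-location resolution and radius assignment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "PdbParseError",
    "EmptyStructureError",
    "RADII_SETS",
    "DEFAULT_RADII_SET",
    "parse_pdb",
    "write_pdb",
    "strip_hetero",
    "assign_radii",
    "resolve_alt_locs",
    "three_to_one",
]


class PdbParseError(ValueError):
    """A malformed fixed-column record was encountered."""


class EmptyStructureError(ValueError):
    """The input contained no polymer ATOM records."""


#: Bondi-style van der Waals radii in Angstrom, the package default.
#: The radii set is a recorded parameter of every run because the surface
#: classification (rel. SASA > threshold) is sensitive to it.
RADII_SETS: dict[str, dict[str, float]] = {
    "bondi": {
        "C": 1.70,
        "N": 1.55,
        "O": 1.52,
        "S": 1.80,
        "H": 1.20,
        "P": 1.80,
        "SE": 1.90,
    },
}
DEFAULT_RADII_SET = "bondi"
#: Fallback radius (Angstrom) for elements missing from the chosen table.
DEFAULT_UNKNOWN_RADIUS = 1.80

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def three_to_one(resname: str) -> str:
    """Map a three-letter residue name to a one-letter code ('X' if unknown)."""
    return _THREE_TO_ONE.get(resname.strip().upper(), "X")


def one_to_three(aa: str) -> str:
    return _ONE_TO_THREE.get(aa.upper(), "UNK")


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    alt_loc: str = ""
    radius: float | None = None  # assigned, never parsed
    is_hetero: bool = False

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    insertion_code: str
    name: str  # three-letter PDB residue name
    atoms: list[Atom] = field(default_factory=list)

    @property
    def aa(self) -> str:
        return three_to_one(self.name)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.insertion_code)

    @property
    def is_water(self) -> bool:
        return self.name.strip().upper() in _WATER_NAMES

    def copy(self) -> "Residue":
        return replace(self, atoms=[a.copy() for a in self.atoms])


@dataclass
class Structure:
    """A (possibly multi-chain) structure, first model only.

    ``numbering_offset`` maps author residue numbers to pre-protein (HGVS)
    coordinates: ``pre_protein_position = seq_num + offset``.  It defaults to
    0 for every chain and must be supplied explicitly when the deposited
    numbering differs from the pre-protein numbering.
    """

    id: str = ""
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    state_label: str = "unspecified"  # apo | liganded | unspecified
    numbering_offset: dict[str, int] = field(default_factory=dict)

    def residues(self):
        for chain in self.chains.values():
            yield from chain

    def atoms(self):
        for res in self.residues():
            yield from res.atoms

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def offset_for(self, chain_id: str) -> int:
        return self.numbering_offset.get(chain_id, 0)

    def copy(self) -> "Structure":
        return Structure(
            id=self.id,
            chains={cid: [r.copy() for r in ch] for cid, ch in self.chains.items()},
            state_label=self.state_label,
            numbering_offset=dict(self.numbering_offset),
        )


def _validate_fixed_columns(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise PdbParseError(
                f"line {lineno}: {rec} record truncated before coordinate columns"
            )
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                value = float(line[lo:hi])
            except ValueError as exc:
                raise PdbParseError(
                    f"line {lineno}: unparseable {what} coordinate field "
                    f"{line[lo:hi]!r}"
                ) from exc
            if not math.isfinite(value):
                raise PdbParseError(f"line {lineno}: non-finite {what} coordinate")


def parse_pdb(
    text: str,
    structure_id: str = "",
    state_label: str = "unspecified",
    include_hydrogens: bool = False,
) -> Structure:
    """Parse PDB-format content into a :class:`Structure`.

    Only the first MODEL is read.  Hydrogens are dropped by default (the
    crystal structures this pipeline targets do not resolve them).  Author
    chain identifiers, residue numbers and insertion codes are preserved.
    """
    _validate_fixed_columns(text)
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise EmptyStructureError("no ATOM records in input")
    model = st[0]
    out = Structure(id=structure_id or st.name.strip(), state_label=state_label)
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            is_het = res.het_flag == "H"
            atoms: list[Atom] = []
            for at in res:
                element = at.element.name.upper()
                if not include_hydrogens and element in ("H", "D"):
                    continue
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=element,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z], dtype=float),
                        occupancy=at.occ,
                        alt_loc=at.altloc.strip() if at.altloc != "\x00" else "",
                        is_hetero=is_het,
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        chain_id=chain.name,
                        seq_num=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        name=res.name,
                        atoms=atoms,
                    )
                )
        if residues:
            out.chains[chain.name] = residues
    if not any(not r.is_water and not all(a.is_hetero for a in r.atoms)
               for r in out.residues()):
        raise EmptyStructureError("input contains no polymer ATOM records")
    return out


def write_pdb(structure: Structure) -> str:
    """Serialize to fixed-column PDB text (synthetic fixtures and round trips)."""
    lines = []
    serial = 0
    for chain_id, residues in structure.chains.items():
        for res in residues:
            for atom in res.atoms:
                serial += 1
                record = "HETATM" if atom.is_hetero else "ATOM"
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                x, y, z = atom.coords
                lines.append(
                    f"{record:<6s}{serial:>5d} {name:<4s}{atom.alt_loc or ' ':1s}"
                    f"{res.name:>3s} {chain_id[:1]:1s}{res.seq_num:>4d}"
                    f"{res.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
        lines.append(f"TER   {serial + 1:>5d}      {residues[-1].name:>3s} "
                     f"{chain_id[:1]:1s}{residues[-1].seq_num:>4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def strip_hetero(structure: Structure) -> Structure:
    """Remove HETATM-derived atoms and water residues; idempotent."""
    out = Structure(
        id=structure.id,
        state_label=structure.state_label,
        numbering_offset=dict(structure.numbering_offset),
    )
    for chain_id, residues in structure.chains.items():
        kept: list[Residue] = []
        for res in residues:
            if res.is_water:
                continue
            atoms = [a.copy() for a in res.atoms if not a.is_hetero]
            if atoms:
                kept.append(replace(res, atoms=atoms))
        if kept:
            out.chains[chain_id] = kept
    return out


def assign_radii(
    structure: Structure,
    radii_set: str = DEFAULT_RADII_SET,
    unknown_radius: float = DEFAULT_UNKNOWN_RADIUS,
) -> Structure:
    """Assign per-atom van der Waals radii from a named table, in place-copy.

    Elements are resolved from the element column with a fallback to the
    leading letters of the atom name.  Unknown elements receive
    ``unknown_radius`` and a logged warning so that runs remain auditable.
    """
    table = RADII_SETS[radii_set]
    out = structure.copy()
    warned: set[str] = set()
    for atom in out.atoms():
        element = atom.element.strip().upper()
        if not element:
            element = "".join(c for c in atom.name if c.isalpha())[:1].upper()
            atom.element = element
        if element in table:
            atom.radius = table[element]
        else:
            if element not in warned:
                logger.warning(
                    "element %r not in radii set %r; using default %.2f A",
                    element, radii_set, unknown_radius,
                )
                warned.add(element)
            atom.radius = unknown_radius
    return out


def resolve_alt_locs(structure: Structure) -> Structure:
    """Keep one alternate location per (residue, atom name).

    The conformer with the highest occupancy wins; ties go to the
    alphabetically first alt_loc identifier.
    """
    out = structure.copy()
    for res in out.residues():
        groups: dict[str, list[Atom]] = {}
        for atom in res.atoms:
            groups.setdefault(atom.name, []).append(atom)
        winners = {
            name: min(atoms, key=lambda a: (-a.occupancy, a.alt_loc))
            for name, atoms in groups.items()
        }
        res.atoms = [a for a in res.atoms if winners[a.name] is a]
    return out
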