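"""Shrake-Rupley solvent-accessible surface area and surface classification.

The engine places a deterministic quasi-uniform lattice of points on each
probe-expanded atom sphere (a golden-section spiral, so there is no random
number generator anywhere in the surface calculation) and counts the points
not occluded by any neighbouring expanded sphere.  Per-residue SASA is the
sum over member atoms.  Relative SASA normalises each residue by its maximal
SASA, computed with the same engine on a Gly-flanked reference polypeptide
modeled as an extended beta-strand, and residues with relative SASA strictly
above the threshold (default 25%) are classified as surface residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .peptide import AA20, build_peptide
from .structures import DEFAULT_RADII_SET, Structure, assign_radii

logger = logging.getLogger(__name__)

__all__ = [
    "SasaParams",
    "ResidueAccessibility",
    "MaxSasaTable",
    "sphere_points",
    "atom_sasa",
    "residue_sasa",
    "build_reference_peptide",
    "max_sasa_table",
    "classify_surface",
    "surface_count",
    "accessibility_table",
]


@dataclass(frozen=True)
class SasaParams:
    """Parameters of a SASA run; every field is recorded in run provenance.

    probe_radius: solvent probe radius in Angstrom (water: 1.4).
    n_points: dots per atom sphere (mesh density).
    threshold_pct: relative-SASA cutoff in percent; residues strictly above
        it count as surface.
    """

    probe_radius: float = 1.4
    n_points: int = 9600
    threshold_pct: float = 25.0

    def __post_init__(self):
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.n_points < 12:
            raise ValueError("n_points must be >= 12")
        if not 0 < self.threshold_pct < 100:
            raise ValueError("threshold_pct must be in (0, 100)")


@dataclass
class ResidueAccessibility:
    chain_id: str
    seq_num: int
    insertion_code: str
    aa: str
    sasa: float  # Angstrom^2
    max_sasa: float | None = None
    rel_sasa: float | None = None  # percent; may exceed 100, never clamped
    is_surface: bool | None = None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.insertion_code)


@dataclass
class MaxSasaTable:
    """Maximal per-residue SASA (Angstrom^2) in a fully exposed context."""

    values: dict[str, float]
    provenance: str

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]

    def __contains__(self, aa: str) -> bool:
        return aa in self.values


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform points on the unit sphere (golden-section spiral).

    Deterministic for fixed ``n``; no randomness.
    """
    if n < 12:
        raise ValueError("at least 12 sphere points are required")
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (1.0 + 5.0**0.5) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def atom_sasa(
    structure: Structure, params: SasaParams = SasaParams()
) -> dict[tuple[str, int, str, str], float]:
    """Per-atom SASA in Angstrom^2, keyed by (chain, seq_num, icode, atom name).

    For each atom the area is 4*pi*(r + probe)^2 times the fraction of its
    sphere points lying outside every neighbour's expanded sphere.  The
    neighbour search uses a KD-tree with cutoff r_i + probe + max_j(r_j + probe),
    which cannot miss an occluder.
    """
    atoms = []
    keys = []
    for res in structure.residues():
        for atom in res.atoms:
            if atom.radius is None or atom.radius <= 0:
                raise ValueError(
                    f"atom {res.key}/{atom.name} has no radius; run assign_radii first"
                )
            atoms.append(atom)
            keys.append((res.chain_id, res.seq_num, res.insertion_code, atom.name))
    if not atoms:
        return {}

    coords = np.array([a.coords for a in atoms], dtype=float)
    expanded = np.array([a.radius for a in atoms], dtype=float) + params.probe_radius
    unit = sphere_points(params.n_points)
    tree = cKDTree(coords)
    r_max = expanded.max()

    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        neighbors = tree.query_ball_point(coords[i], expanded[i] + r_max)
        neighbors = [
            j for j in neighbors
            if j != i
            and np.linalg.norm(coords[j] - coords[i]) < expanded[i] + expanded[j]
        ]
        dots = coords[i] + expanded[i] * unit
        exposed = np.ones(params.n_points, dtype=bool)
        for j in neighbors:
            if not exposed.any():
                break
            d2 = np.einsum("ij,ij->i", dots - coords[j], dots - coords[j])
            exposed &= d2 >= expanded[j] ** 2
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * exposed.sum() / params.n_points
    return dict(zip(keys, areas))


def residue_sasa(
    structure: Structure,
    atom_areas: dict[tuple[str, int, str, str], float],
) -> list[ResidueAccessibility]:
    """Per-residue SASA as the sum over member atoms."""
    out = []
    for res in structure.residues():
        total = sum(
            atom_areas[(res.chain_id, res.seq_num, res.insertion_code, a.name)]
            for a in res.atoms
        )
        out.append(
            ResidueAccessibility(
                chain_id=res.chain_id,
                seq_num=res.seq_num,
                insertion_code=res.insertion_code,
                aa=res.aa,
                sasa=total,
            )
        )
    return out


def build_reference_peptide() -> Structure:
    """The 41-residue maximal-SASA reference peptide.

    Each of the 20 standard amino acids, in alphabetical one-letter order, is
    flanked by glycines (G-X1-G-X2-...-X20-G) and the chain is modeled as an
    extended beta-strand (phi=-135, psi=+135, omega=180).  Deterministic.
    """
    sequence = "G" + "".join(aa + "G" for aa in AA20)
    return build_peptide(sequence, structure_id="max_sasa_reference")


_MAX_TABLE_CACHE: dict[tuple, MaxSasaTable] = {}


def max_sasa_table(
    params: SasaParams = SasaParams(), radii_set: str = DEFAULT_RADII_SET
) -> MaxSasaTable:
    """Maximal SASA per amino acid, from the Gly-flanked reference strand.

    Each amino acid's maximum is its residue SASA inside the reference
    peptide under the same engine parameters, so relative SASA is a
    like-for-like ratio.  Results are cached per (params, radii set).
    """
    cache_key = (params, radii_set)
    if cache_key in _MAX_TABLE_CACHE:
        return _MAX_TABLE_CACHE[cache_key]
    ref = assign_radii(build_reference_peptide(), radii_set=radii_set)
    accs = residue_sasa(ref, atom_sasa(ref, params))
    values = {}
    for idx, aa in enumerate(AA20):
        # guest residues sit at positions 2, 4, ..., 40 in alphabetical order
        values[aa] = accs[2 * idx + 1].sasa
    table = MaxSasaTable(
        values=values,
        provenance=(
            "Gly-flanked 41-mer beta-strand (phi=-135, psi=+135, omega=180), "
            f"radii_set={radii_set}, probe={params.probe_radius}, "
            f"n_points={params.n_points}"
        ),
    )
    _MAX_TABLE_CACHE[cache_key] = table
    return table


def classify_surface(
    residues: list[ResidueAccessibility],
    table: MaxSasaTable,
    params: SasaParams = SasaParams(),
) -> list[ResidueAccessibility]:
    """Fill relative SASA and the surface flag (strictly greater than cutoff).

    Relative SASA above 100% (fully isolated residues exceed their in-chain
    maximum) is reported as-is, never clamped.  Residues whose amino acid is
    not in the table (non-standard, 'X') are skipped with a warning.
    """
    out = []
    for acc in residues:
        if acc.aa not in table:
            logger.warning(
                "residue %s%s %s not in max-SASA table; skipped",
                acc.chain_id, acc.seq_num, acc.aa,
            )
            continue
        acc.max_sasa = float(table[acc.aa])
        acc.rel_sasa = float(100.0 * acc.sasa / acc.max_sasa)
        acc.is_surface = bool(acc.rel_sasa > params.threshold_pct)
        if acc.rel_sasa > 100.0:
            logger.info(
                "residue %s%s %s relative SASA %.1f%% exceeds 100%%",
                acc.chain_id, acc.seq_num, acc.aa, acc.rel_sasa,
            )
        out.append(acc)
    return out


def accessibility_table(
    structure: Structure,
    params: SasaParams = SasaParams(),
    radii_set: str = DEFAULT_RADII_SET,
) -> list[ResidueAccessibility]:
    """Full per-residue pipeline: radii -> atom SASA -> residue SASA -> class."""
    prepared = assign_radii(structure, radii_set=radii_set)
    accs = residue_sasa(prepared, atom_sasa(prepared, params))
    return classify_surface(accs, max_sasa_table(params, radii_set), params)


def surface_count(
    structure: Structure,
    params: SasaParams = SasaParams(),
    radii_set: str = DEFAULT_RADII_SET,
) -> dict[str, int]:
    """Number of surface residues per chain plus 'total'."""
    accs = accessibility_table(structure, params, radii_set)
    counts: dict[str, int] = {cid: 0 for cid in structure.chains}
    for acc in accs:
        if acc.is_surface:
            counts[acc.chain_id] += 1
    counts["total"] = sum(v for k, v in counts.items() if k != "total")
    return counts
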