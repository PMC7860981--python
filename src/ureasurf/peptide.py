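"""Deterministic peptide construction in ideal geometry.

Builds extended polypeptides residue by residue from internal coordinates
(bond lengths, bond angles, backbone dihedrals) and grafts heavy side-chain
atoms from ideal chemical-component-dictionary conformers (frozen into the
package, see ``_residue_templates``).  Used for the Gly-flanked maximal-SASA
reference peptide and for synthetic test structures; no energy minimisation,
no randomness.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from ._residue_templates import IDEAL_RESIDUES
from .structures import Atom, Residue, Structure, one_to_three

__all__ = ["build_peptide", "AA20"]

#: The 20 standard amino acids in alphabetical one-letter order.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Engh-Huber-style ideal backbone internal coordinates (Angstrom, degrees).
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.8

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom D from A-B-C."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-np.cos(theta), np.sin(theta) * np.cos(chi),
                  np.sin(theta) * np.sin(chi)])
    return c + length * (bc * d[0] + m * d[1] + n * d[2])


def _ccd_template(resname: str):
    """Heavy atoms of the ideal conformer: (names, elements, coords)."""
    entries = IDEAL_RESIDUES[resname]
    names = [e[0] for e in entries]
    elements = [e[1] for e in entries]
    coords = np.array([e[2:] for e in entries], dtype=float)
    return names, elements, coords


def _fit_side_chain(resname: str, n: np.ndarray, ca: np.ndarray, c: np.ndarray):
    """Rigid-fit the ideal conformer's N/CA/C onto the built backbone triad and
    return the transformed side-chain atoms as (name, element, xyz) tuples."""
    names, elements, coords = _ccd_template(resname)
    idx = {nm: i for i, nm in enumerate(names)}
    src = coords[[idx["N"], idx["CA"], idx["C"]]]
    dst = np.stack([n, ca, c])
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    rot, _ = Rotation.align_vectors(dst_c, src_c)
    out = []
    for nm, el, xyz in zip(names, elements, coords):
        if nm in _BACKBONE_NAMES:
            continue
        out.append((nm, el.upper(),
                    rot.apply(xyz - src.mean(axis=0)) + dst.mean(axis=0)))
    return out


def build_peptide(
    sequence: str,
    phi: float = -135.0,
    psi: float = 135.0,
    omega: float = 180.0,
    chain_id: str = "A",
    structure_id: str = "peptide",
) -> Structure:
    """Build a single-chain peptide in a repeating (phi, psi, omega) state.

    The default dihedrals give an extended beta-strand.  Side chains adopt the
    ideal conformer of the chemical component dictionary, rigid-body fitted to
    the backbone; the construction is fully deterministic.
    """
    sequence = sequence.upper()
    if not sequence or any(aa not in AA20 for aa in sequence):
        raise ValueError("sequence must be non-empty standard one-letter codes")

    n_pos = np.zeros((len(sequence), 3))
    ca_pos = np.zeros_like(n_pos)
    c_pos = np.zeros_like(n_pos)
    o_pos = np.zeros_like(n_pos)

    # first residue seeds the chain in the xy-plane
    n_pos[0] = np.array([0.0, 0.0, 0.0])
    ca_pos[0] = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - _A_N_CA_C)
    c_pos[0] = ca_pos[0] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, len(sequence)):
        n_pos[i] = _place(n_pos[i - 1], ca_pos[i - 1], c_pos[i - 1],
                          _B_C_N, _A_CA_C_N, psi)
        ca_pos[i] = _place(ca_pos[i - 1], c_pos[i - 1], n_pos[i],
                           _B_N_CA, _A_C_N_CA, omega)
        c_pos[i] = _place(c_pos[i - 1], n_pos[i], ca_pos[i],
                          _B_CA_C, _A_N_CA_C, phi)
    for i in range(len(sequence)):
        o_pos[i] = _place(n_pos[i], ca_pos[i], c_pos[i],
                          _B_C_O, _A_CA_C_O, psi + 180.0)

    residues: list[Residue] = []
    serial = 0
    for i, aa in enumerate(sequence):
        resname = one_to_three(aa)
        atoms: list[Atom] = []
        for name, element, xyz in (
            ("N", "N", n_pos[i]),
            ("CA", "C", ca_pos[i]),
            ("C", "C", c_pos[i]),
            ("O", "O", o_pos[i]),
        ):
            serial += 1
            atoms.append(Atom(serial=serial, name=name, element=element,
                              coords=np.asarray(xyz, dtype=float)))
        for name, element, xyz in _fit_side_chain(resname, n_pos[i], ca_pos[i],
                                                  c_pos[i]):
            serial += 1
            atoms.append(Atom(serial=serial, name=name, element=element,
                              coords=np.asarray(xyz, dtype=float)))
        residues.append(Residue(chain_id=chain_id, seq_num=i + 1,
                                insertion_code="", name=resname, atoms=atoms))
    return Structure(id=structure_id, chains={chain_id: residues})
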