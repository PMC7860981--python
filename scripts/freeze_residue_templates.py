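"""Regenerate src/ureasurf/_residue_templates.py from the CCD via biotite.

The package ships the ideal-conformer heavy-atom coordinates of the 20
standard amino acids as a frozen table because parsing the full chemical
component dictionary costs over a minute per process; run this script to
refresh the table after a biotite/CCD upgrade.
"""

import pathlib

import biotite.structure.info as info

NAMES3 = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

HEADER = '''"""Ideal-geometry heavy-atom coordinates of the 20 standard amino acids.

Reference conformers from the PDB chemical component dictionary (CCD) ideal
coordinate sets; heavy atoms only, Angstrom.  Each entry maps a three-letter
residue name to a list of (atom_name, element, x, y, z).  Used to graft side
chains onto ideal backbones; regenerate with scripts/freeze_residue_templates.py.
"""

IDEAL_RESIDUES = {
'''


def main() -> None:
    lines = [HEADER.rstrip("\n")]
    for res3 in sorted(NAMES3):
        arr = info.residue(res3)
        mask = arr.element != "H"
        lines.append(f'    "{res3}": [')
        for nm, el, xyz in zip(arr.atom_name[mask], arr.element[mask], arr.coord[mask]):
            lines.append(
                f'        ("{nm}", "{el.upper()}", '
                f"{xyz[0]:.3f}, {xyz[1]:.3f}, {xyz[2]:.3f}),"
            )
        lines.append("    ],")
    lines.append("}")
    out = pathlib.Path(__file__).resolve().parents[1] / "src/ureasurf/_residue_templates.py"
    out.write_text("\n".join(lines) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
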