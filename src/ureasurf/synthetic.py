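"""Synthetic fixtures with built-in ground truth for every pipeline stage.

All fixtures are generated programmatically from a (spec, seed) pair — sphere
systems with closed-form or Monte-Carlo reference areas, toy peptides and
homotrimers with surface/buried labels, simulated alignments with prescribed
per-column conservation, variant tables with a hand-derivable candidate set,
and NAGS-like sequence sets with known variable-segment spans.  Defaults of
the sequence generators mirror the study conditions of the comparative
analyses they emulate (233-homolog alignments; 90 mammalian and 61
non-mammalian records; mammalian VS length 37-64 at 17.4-32.3% proline,
non-mammalian 31-40 at 2.3-11.1%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .conservation import Alignment
from .peptide import build_peptide
from .sasa import SasaParams, max_sasa_table
from .structures import Atom, Residue, Structure, one_to_three, write_pdb
from .variants import MissenseVariant, stability_class, StabilityClass
from .vs import NagsRecord

__all__ = [
    "FixtureSpec",
    "DegenerateGeometryError",
    "two_sphere_exposed_areas",
    "mc_sasa",
    "make_sphere_system",
    "make_toy_peptide",
    "make_homotrimer",
    "simulate_msa",
    "make_variant_table",
    "make_nags_set",
    "generate_fixture",
]

#: Sequence alphabet of the synthetic sequence generators.  Tryptophan is
#: reserved as the first residue of the conserved-domain reference so the
#: domain start is an unambiguous alignment anchor (see docs/methods.md).
_SEQ_ALPHABET = "ACDEFGHIKLMNQRSTVY"
_SEQ_ALPHABET_NOP = _SEQ_ALPHABET  # no proline either; prolines are placed by count


class DegenerateGeometryError(ValueError):
    """Two spheres share a center; the system has no defined surface split."""


@dataclass
class FixtureSpec:
    """A reproducible fixture request: kind, per-kind parameters, seed."""

    kind: str  # sphere_system | toy_peptide | homotrimer | msa | variant_table | nags_set
    params: dict = field(default_factory=dict)
    seed: int = 0


# ---------------------------------------------------------------------------
# sphere systems and the Monte-Carlo oracle


def two_sphere_exposed_areas(
    r1: float, r2: float, d: float, probe: float = 0.0
) -> tuple[float, float]:
    """Closed-form exposed areas of two intersecting spheres.

    Expanded radii R_i = r_i + probe; for center distance d the buried part
    of sphere i is the spherical cap of height h_i = R_i - (d^2 + R_i^2 -
    R_j^2) / (2 d), so the exposed area is 4*pi*R_i^2 - 2*pi*R_i*h_i.
    """
    R1, R2 = r1 + probe, r2 + probe
    if d <= 0:
        raise DegenerateGeometryError("sphere centers coincide")
    if d >= R1 + R2:  # no overlap
        return 4 * np.pi * R1**2, 4 * np.pi * R2**2
    if d + min(R1, R2) <= max(R1, R2):  # one sphere engulfed
        big_is_1 = R1 >= R2
        return (4 * np.pi * R1**2, 0.0) if big_is_1 else (0.0, 4 * np.pi * R2**2)
    h1 = R1 - (d**2 + R1**2 - R2**2) / (2 * d)
    h2 = R2 - (d**2 + R2**2 - R1**2) / (2 * d)
    return (4 * np.pi * R1**2 - 2 * np.pi * R1 * h1,
            4 * np.pi * R2**2 - 2 * np.pi * R2 * h2)


def mc_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo surface integration oracle.

    Samples ``n_samples`` uniform points on each atom's probe-expanded sphere
    and scores the unoccluded fraction.  Returns per-atom areas and their
    binomial standard errors.  Independent of the dot-lattice engine: random
    directions instead of a deterministic spiral.
    """
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, dtype=float)
    expanded = np.asarray(radii, dtype=float) + probe
    n_atoms = len(coords)
    areas = np.empty(n_atoms)
    ses = np.empty(n_atoms)
    for i in range(n_atoms):
        dirs = rng.normal(size=(n_samples, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = coords[i] + expanded[i] * dirs
        exposed = np.ones(n_samples, dtype=bool)
        for j in range(n_atoms):
            if j == i:
                continue
            if np.linalg.norm(coords[j] - coords[i]) >= expanded[i] + expanded[j]:
                continue
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            exposed &= d2 >= expanded[j] ** 2
        frac = exposed.mean()
        full = 4 * np.pi * expanded[i] ** 2
        areas[i] = full * frac
        ses[i] = full * np.sqrt(frac * (1 - frac) / n_samples)
    return areas, ses


def _spheres_to_structure(coords: np.ndarray, radii: np.ndarray) -> Structure:
    """One-carbon-atom-per-residue structure carrying explicit radii."""
    residues = [
        Residue(
            chain_id="A", seq_num=i + 1, insertion_code="", name="ALA",
            atoms=[Atom(serial=i + 1, name="CA", element="C",
                        coords=np.asarray(c, dtype=float), radius=float(r))],
        )
        for i, (c, r) in enumerate(zip(coords, radii))
    ]
    return Structure(id="spheres", chains={"A": residues})


def make_sphere_system(
    radii: list[float],
    positions: list[list[float]] | np.ndarray,
    probe: float = 1.4,
    mc_samples: int = 1_000_000,
    seed: int = 0,
) -> tuple[Structure, np.ndarray, np.ndarray | None]:
    """Atom system plus reference per-atom SASA.

    One or two spheres use the analytic closed form (standard error None);
    larger systems use the Monte-Carlo oracle with reported standard errors.
    """
    coords = np.asarray(positions, dtype=float)
    radii_arr = np.asarray(radii, dtype=float)
    if len(coords) != len(radii_arr):
        raise ValueError("radii and positions length mismatch")
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            if np.allclose(coords[i], coords[j]):
                raise DegenerateGeometryError(f"spheres {i} and {j} coincide")
    structure = _spheres_to_structure(coords, radii_arr)
    if len(coords) == 1:
        truth = np.array([4 * np.pi * (radii_arr[0] + probe) ** 2])
        return structure, truth, None
    if len(coords) == 2:
        d = float(np.linalg.norm(coords[1] - coords[0]))
        truth = np.array(two_sphere_exposed_areas(radii_arr[0], radii_arr[1],
                                                  d, probe))
        return structure, truth, None
    areas, ses = mc_sasa(coords, radii_arr, probe, mc_samples, seed)
    return structure, areas, ses


# ---------------------------------------------------------------------------
# toy peptides, labelled surface/buried ground truth


def make_toy_peptide(
    sequence: str,
    conformation: str = "extended",
    seed: int = 0,
    params: SasaParams = SasaParams(),
    mc_samples: int = 20_000,
    label_margin_pct: float = 3.0,
) -> tuple[Structure, dict[int, bool]]:
    """A labelled toy structure for the surface classifier.

    ``extended``: a beta-strand; every residue is fully exposed and labelled
    surface.  ``collapsed``: ideal residues packed into a compact cluster;
    labels come from Monte-Carlo relative SASA, and the placement is
    re-jittered (deterministically, from the seed) until every residue's
    relative SASA clears the classification threshold by ``label_margin_pct``
    so labels are verified truths, not intentions.
    """
    if len(sequence) > 50:
        raise ValueError("toy peptides are limited to 50 residues")
    if conformation == "extended":
        structure = build_peptide(sequence, structure_id="toy_extended")
        return structure, {i + 1: True for i in range(len(sequence))}
    if conformation != "collapsed":
        raise ValueError(f"unknown conformation {conformation!r}")

    table = max_sasa_table(params)
    rng = np.random.default_rng(seed)
    for _attempt in range(50):
        structure = _collapsed_cluster(sequence, rng)
        labels, ok = _mc_labels(structure, table, params, mc_samples,
                                seed, label_margin_pct)
        if ok:
            structure.id = "toy_collapsed"
            return structure, labels
    raise RuntimeError("could not place a margin-clean collapsed cluster")


def _collapsed_cluster(sequence: str, rng: np.random.Generator) -> Structure:
    """Residues on a jittered compact cubic grid (not a bonded chain)."""
    from .peptide import _ccd_template  # ideal conformers

    n = len(sequence)
    side = int(np.ceil(n ** (1 / 3)))
    spacing = 5.4
    order = []  # center-out order so early residues sit inside
    cells = [(x, y, z) for x in range(side) for y in range(side) for z in range(side)]
    center = (np.array([side - 1] * 3)) / 2
    cells.sort(key=lambda c: np.linalg.norm(np.array(c) - center))
    order = cells[:n]
    residues = []
    serial = 0
    for i, aa in enumerate(sequence):
        names, elements, coords = _ccd_template(one_to_three(aa))
        coords = coords - coords.mean(axis=0)
        # random proper rotation
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        from scipy.spatial.transform import Rotation
        coords = Rotation.from_quat(q).apply(coords)
        origin = np.array(order[i], dtype=float) * spacing
        origin += rng.uniform(-0.6, 0.6, size=3)
        atoms = []
        for nm, el, xyz in zip(names, elements, coords):
            serial += 1
            atoms.append(Atom(serial=serial, name=nm, element=el,
                              coords=xyz + origin))
        residues.append(Residue(chain_id="A", seq_num=i + 1, insertion_code="",
                                name=one_to_three(aa), atoms=atoms))
    return Structure(id="toy_collapsed", chains={"A": residues})


def _mc_labels(structure, table, params, mc_samples, seed, margin):
    from .structures import assign_radii

    prepared = assign_radii(structure)
    atoms = list(prepared.atoms())
    coords = np.array([a.coords for a in atoms])
    radii = np.array([a.radius for a in atoms])
    areas, _ = mc_sasa(coords, radii, params.probe_radius, mc_samples, seed)
    labels = {}
    idx = 0
    for res in prepared.residues():
        res_area = areas[idx:idx + len(res.atoms)].sum()
        idx += len(res.atoms)
        rel = 100.0 * res_area / table[res.aa]
        if abs(rel - params.threshold_pct) < margin:
            return {}, False
        labels[res.seq_num] = rel > params.threshold_pct
    return labels, True


def make_homotrimer(
    sequence: str = "ADKLF", radius_offset: float = 4.0, seed: int = 0
) -> Structure:
    """A C3-symmetric homotrimer of extended peptides (chains A, B, C).

    Each chain is an extended peptide displaced ``radius_offset`` Angstrom
    from the threefold axis and rotated by 0/120/240 degrees; per-chain
    surface counts are equal by construction.
    """
    from scipy.spatial.transform import Rotation

    base = build_peptide(sequence, structure_id="trimer")
    chain = base.chains["A"]
    for res in chain:
        for atom in res.atoms:
            atom.coords = atom.coords + np.array([radius_offset, 0.0, 0.0])
    out = Structure(id="homotrimer", chains={})
    for k, cid in enumerate("ABC"):
        rot = Rotation.from_euler("z", 120.0 * k, degrees=True)
        residues = []
        for res in chain:
            atoms = [
                Atom(serial=a.serial, name=a.name, element=a.element,
                     coords=rot.apply(a.coords), occupancy=a.occupancy)
                for a in res.atoms
            ]
            residues.append(Residue(chain_id=cid, seq_num=res.seq_num,
                                    insertion_code="", name=res.name,
                                    atoms=atoms))
        out.chains[cid] = residues
    return out


# ---------------------------------------------------------------------------
# simulated alignments


def simulate_msa(
    n_seqs: int = 233,
    length: int = 60,
    conservation: float | np.ndarray = 0.85,
    groups: list[str] | None = None,
    seed: int = 0,
    query_id: str = "query",
) -> tuple[Alignment, np.ndarray]:
    """Alignment with a prescribed per-column conservation level.

    The query is a random sequence; each of ``n_seqs`` homologs matches the
    query at column j with probability c_j and otherwise draws uniformly
    from the other 19 residues.  Group labels are assigned round-robin.
    Returns the alignment and the truth vector c (fractions in [0, 1]).
    """
    rng = np.random.default_rng(seed)
    c = np.broadcast_to(np.asarray(conservation, dtype=float), (length,)).copy()
    if ((c < 0) | (c > 1)).any():
        raise ValueError("conservation values must lie in [0, 1]")
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    query = rng.choice(alphabet, size=length)
    records = [(query_id, "".join(query))]
    taxonomy = {}
    groups = groups or ["group1"]
    for i in range(n_seqs):
        match = rng.random(length) < c
        seq = query.copy()
        mismatch_idx = np.flatnonzero(~match)
        for j in mismatch_idx:
            others = alphabet[alphabet != query[j]]
            seq[j] = rng.choice(others)
        rid = f"hom{i + 1:04d}"
        records.append((rid, "".join(seq)))
        taxonomy[rid] = groups[i % len(groups)]
    return Alignment(records=records, query_id=query_id, taxonomy=taxonomy), c


# ---------------------------------------------------------------------------
# variant tables


def make_variant_table(
    residue_labels: dict[int, tuple[str, bool]],
    n_variants: int = 20,
    fraction_surface: float = 0.5,
    ddg_spec: float | tuple[str, float, float] | None = ("normal", 1.0, 2.0),
    annotated_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, set[str]]:
    """A variant table with a hand-derivable expected candidate set.

    ``residue_labels`` maps pre-protein position -> (ref aa, is_surface).
    ddg_spec: a constant, ("normal", mu, sigma), or None for missing ddG.
    Returns (table, expected candidate tokens), where the expectation applies
    the ledger filter rule directly to the generated ground truth: surface,
    ddG <= 2 kcal/mol (or more stable), and unannotated.
    """
    rng = np.random.default_rng(seed)
    surface_pool = [p for p, (_, s) in residue_labels.items() if s]
    buried_pool = [p for p, (_, s) in residue_labels.items() if not s]
    n_surface = round(n_variants * fraction_surface)
    n_buried = n_variants - n_surface
    if n_surface > len(surface_pool) or n_buried > len(buried_pool):
        raise ValueError(
            f"cannot draw {n_surface} surface + {n_buried} buried variants "
            f"from pools of {len(surface_pool)}/{len(buried_pool)}"
        )
    positions = list(rng.choice(surface_pool, n_surface, replace=False)) + \
        list(rng.choice(buried_pool, n_buried, replace=False))
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    rows = []
    expected: set[str] = set()
    for pos in positions:
        ref, is_surface = residue_labels[int(pos)]
        alt = rng.choice([a for a in alphabet if a != ref])
        if ddg_spec is None:
            ddg = None
        elif isinstance(ddg_spec, tuple):
            _, mu, sigma = ddg_spec
            ddg = float(rng.normal(mu, sigma))
        else:
            ddg = float(ddg_spec)
        annotated = bool(is_surface and rng.random() < annotated_fraction)
        token = f"p.{ref}{int(pos)}{alt}"
        rows.append({
            "variant": token,
            "source": "synthetic",
            "ddg_kcal_mol": ddg,
            "annotation": "characterized elsewhere" if annotated else "",
        })
        stab = stability_class(ddg)
        if (is_surface and not annotated
                and stab in (StabilityClass.SIMILAR, StabilityClass.MORE_STABLE)):
            expected.add(token)
    return pd.DataFrame(rows), expected


# ---------------------------------------------------------------------------
# NAGS-like sequence sets


def _random_seq(rng: np.random.Generator, length: int,
                proline_fraction: float | None = None) -> str:
    letters = rng.choice(list(_SEQ_ALPHABET_NOP), size=length)
    if proline_fraction is not None:
        n_p = int(round(proline_fraction * length))
        pos = rng.choice(length, size=n_p, replace=False)
        letters[pos] = "P"
    return "".join(letters)


def make_nags_set(
    n_mammal: int = 90,
    n_other: int = 61,
    mammal_len: tuple[int, int] = (37, 64),
    other_len: tuple[int, int] = (31, 40),
    mammal_proline: tuple[float, float] = (0.174, 0.323),
    other_proline: tuple[float, float] = (0.023, 0.111),
    mts_len: tuple[int, int] = (15, 50),
    reference_length: int = 120,
    seed: int = 0,
) -> tuple[list[NagsRecord], str, dict[str, tuple[int, int]]]:
    """NAGS-like pre-proteins = MTS + VS + shared conserved domain.

    VS lengths and proline fractions are drawn uniformly from the group
    ranges (defaults mirror the mammalian and fish/amphibian/reptile study
    populations).  The conserved-domain reference starts with W, a residue
    excluded from the synthetic MTS/VS alphabet, so the domain start is an
    unambiguous anchor and the truth spans are exactly recoverable.
    Returns (records, reference sequence, {id: (vs_start, vs_end)}).
    """
    rng = np.random.default_rng(seed)
    reference = "W" + _random_seq(rng, reference_length - 1)
    records: list[NagsRecord] = []
    truth: dict[str, tuple[int, int]] = {}
    specs = [("mammal", n_mammal, mammal_len, mammal_proline),
             ("non_mammal", n_other, other_len, other_proline)]
    for group, n, len_range, pro_range in specs:
        for i in range(n):
            mts = _random_seq(rng, int(rng.integers(mts_len[0], mts_len[1] + 1)))
            vs_len = int(rng.integers(len_range[0], len_range[1] + 1))
            pro = float(rng.uniform(*pro_range))
            vs_seq = _random_seq(rng, vs_len, proline_fraction=pro)
            rid = f"{group}{i + 1:03d}"
            seq = mts + vs_seq + reference
            mpp = len(mts) + 1
            records.append(NagsRecord(id=rid, group=group, sequence=seq,
                                      mpp_site=mpp))
            truth[rid] = (mpp, mpp + vs_len - 1)
    return records, reference, truth


# ---------------------------------------------------------------------------
# file-writing dispatcher (CLI `fixtures` subcommand)


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> list[Path]:
    """Materialise a fixture (and its truth files) under ``out_dir``.

    Every file starts with a header recording the spec and seed, so a fixture
    is reproducible from its own header.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = f"# fixture kind={spec.kind} seed={spec.seed} params={json.dumps(spec.params, sort_keys=True)}\n"
    written: list[Path] = []

    def _write(name: str, text: str, with_header: bool = True) -> None:
        path = out_dir / name
        path.write_text((header if with_header else "") + text)
        written.append(path)

    if spec.kind == "sphere_system":
        structure, truth, ses = make_sphere_system(seed=spec.seed, **spec.params)
        _write("spheres.pdb", write_pdb(structure), with_header=False)
        lines = ["atom_index\tarea_A2\tse_A2"]
        for i, a in enumerate(truth):
            se = "" if ses is None else f"{ses[i]:.4f}"
            lines.append(f"{i}\t{a:.4f}\t{se}")
        _write("spheres_truth.tsv", "\n".join(lines) + "\n")
    elif spec.kind == "toy_peptide":
        structure, labels = make_toy_peptide(seed=spec.seed, **spec.params)
        _write("peptide.pdb", write_pdb(structure), with_header=False)
        lines = ["seq_num\tis_surface"]
        lines += [f"{k}\t{int(v)}" for k, v in sorted(labels.items())]
        _write("peptide_labels.tsv", "\n".join(lines) + "\n")
    elif spec.kind == "homotrimer":
        structure = make_homotrimer(seed=spec.seed, **spec.params)
        _write("trimer.pdb", write_pdb(structure), with_header=False)
    elif spec.kind == "msa":
        alignment, truth = simulate_msa(seed=spec.seed, **spec.params)
        fasta = "".join(f">{rid}\n{seq}\n" for rid, seq in alignment.records)
        _write("alignment.fasta", fasta, with_header=False)
        tax = "".join(f"{rid}\t{g}\n" for rid, g in alignment.taxonomy.items())
        _write("taxonomy.tsv", tax)
        _write("conservation_truth.tsv",
               "column\tconservation\n" +
               "".join(f"{j + 1}\t{c:.4f}\n" for j, c in enumerate(truth)))
    elif spec.kind == "variant_table":
        table, expected = make_variant_table(seed=spec.seed, **spec.params)
        _write("variants.tsv", table.to_csv(sep="\t", index=False))
        _write("expected_candidates.tsv", "".join(f"{t}\n" for t in sorted(expected)))
    elif spec.kind == "nags_set":
        records, reference, truth = make_nags_set(seed=spec.seed, **spec.params)
        fasta = "".join(f">{r.id}\n{r.sequence}\n" for r in records)
        _write("nags.fasta", fasta, with_header=False)
        _write("reference.fasta", f">conserved_reference\n{reference}\n",
               with_header=False)
        _write("annotations.tsv",
               "id\tgroup\tmpp_site\n" +
               "".join(f"{r.id}\t{r.group}\t{r.mpp_site}\n" for r in records))
        _write("vs_truth.tsv",
               "id\tvs_start\tvs_end\n" +
               "".join(f"{rid}\t{s}\t{e}\n" for rid, (s, e) in truth.items()))
    else:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    return written
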