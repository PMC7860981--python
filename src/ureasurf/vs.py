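"""NAGS variable-segment (VS) delimitation and comparative statistics.

The N-terminus of vertebrate N-acetylglutamate synthase consists of a
mitochondrial targeting signal (MTS, removed by the mitochondrial processing
peptidase), a variable segment, and the conserved catalytic domain.  The VS
is delimited between the MPP cleavage site (an annotation input) and the
start of homology with a reference conserved-domain sequence that itself
lacks MTS and VS (the bacterial vertebrate-like NAGS-kinase), found by
global pairwise alignment.  Group statistics — VS length, proline content
and within-group pairwise identity — contrast the long proline-rich
mammalian VS with the shorter proline-poor VS of fish, amphibians and
reptiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.SeqUtils import molecular_weight

from .peptide import AA20

logger = logging.getLogger(__name__)

__all__ = [
    "NagsRecord",
    "VariableSegment",
    "align_global",
    "find_vs",
    "proline_content",
    "pairwise_identity",
    "group_stats",
    "peptide_mass",
]

#: Affine gap penalties: a gap of length L costs GAP_OPEN + (L-1)*GAP_EXTEND.
GAP_OPEN = -11.0
GAP_EXTEND = -1.0
DEFAULT_MATRIX = "BLOSUM62"


@dataclass(frozen=True)
class NagsRecord:
    """A NAGS pre-protein with its annotated MPP cleavage site.

    ``mpp_site`` is the 1-based position of the first residue of the mature
    protein (the first residue after MPP cleavage).
    """

    id: str
    group: str  # e.g. "mammal" | "non_mammal"
    sequence: str
    mpp_site: int

    def __post_init__(self):
        if not 1 <= self.mpp_site <= len(self.sequence):
            raise ValueError(
                f"{self.id}: mpp_site {self.mpp_site} outside sequence "
                f"(length {len(self.sequence)})"
            )


@dataclass(frozen=True)
class VariableSegment:
    parent_id: str
    start: int  # 1-based inclusive, pre-protein coordinates; == mpp_site
    end: int  # 1-based inclusive; end < start for an empty VS
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def proline_pct(self) -> float:
        return proline_content(self.sequence)


def _aligner(matrix: str = DEFAULT_MATRIX) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def align_global(
    seq_a: str,
    seq_b: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> tuple[str, str, float]:
    """Optimal global alignment under affine gap penalties.

    Returns the two gapped strings and the optimal score.  Ties are broken
    deterministically (the aligner's canonical first traceback).
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    return str(aln[0]), str(aln[1]), float(aln.score)


def find_vs(record: NagsRecord, reference_conserved: str) -> VariableSegment:
    """Delimit the variable segment of a NAGS pre-protein.

    The post-MPP sequence is globally aligned against the conserved-domain
    reference (which has neither MTS nor VS); the VS runs from the MPP site
    up to the residue preceding the first record position aligned to the
    reference's first residue.  An empty VS (post-MPP sequence starting at
    the conserved domain) yields ``end < start`` and a warning.
    """
    if not reference_conserved:
        raise ValueError("reference sequence must be non-empty")
    post = record.sequence[record.mpp_site - 1:]
    gapped_rec, gapped_ref, _ = align_global(post, reference_conserved)
    n_before = 0
    for rec_ch, ref_ch in zip(gapped_rec, gapped_ref):
        if ref_ch != "-":
            break
        if rec_ch != "-":
            n_before += 1
    start = record.mpp_site
    end = record.mpp_site + n_before - 1
    if n_before == 0:
        logger.warning("%s: conserved domain starts at the MPP site; empty VS",
                       record.id)
    return VariableSegment(
        parent_id=record.id,
        start=start,
        end=end,
        sequence=record.sequence[start - 1:end],
    )


def proline_content(sequence: str) -> float:
    """Percent prolines in a sequence (undefined for an empty sequence)."""
    if not sequence:
        raise ValueError("proline content of an empty sequence is undefined")
    return 100.0 * sequence.upper().count("P") / len(sequence)


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity over gap-free aligned columns (pairwise deletion).

    The two sequences are globally aligned; identity is matches divided by
    the number of columns where neither sequence has a gap, times 100 (the
    complement of the p-distance under pairwise deletion).
    """
    a, b, _ = align_global(seq_a, seq_b)
    matched = 0
    compared = 0
    for ca, cb in zip(a, b):
        if ca == "-" or cb == "-":
            continue
        compared += 1
        if ca == cb:
            matched += 1
    return 100.0 * matched / compared if compared else 0.0


def group_stats(
    records: list[NagsRecord], reference_conserved: str
) -> pd.DataFrame:
    """Per-group (min, max) of VS length, proline % and pairwise identity %.

    Groups with fewer than two records have their identity range omitted
    (NaN) with a warning.  Output rows: vs_length, vs_proline_pct,
    vs_identity_pct; one (min, max) column pair per group.
    """
    segments: dict[str, list[VariableSegment]] = {}
    for rec in records:
        vs = find_vs(rec, reference_conserved)
        if vs.length == 0:
            logger.warning("%s: empty VS excluded from group statistics", rec.id)
            continue
        segments.setdefault(rec.group, []).append(vs)
    rows = []
    for group in sorted(segments):
        group_vs = segments[group]
        lengths = [vs.length for vs in group_vs]
        prolines = [vs.proline_pct for vs in group_vs]
        if len(group_vs) >= 2:
            idents = [
                pairwise_identity(a.sequence, b.sequence)
                for i, a in enumerate(group_vs)
                for b in group_vs[i + 1:]
            ]
            ident_min, ident_max = min(idents), max(idents)
        else:
            logger.warning("group %r has <2 records; identity range omitted", group)
            ident_min = ident_max = float("nan")
        rows.append({
            "group": group,
            "n": len(group_vs),
            "length_min": min(lengths),
            "length_max": max(lengths),
            "proline_min_pct": min(prolines),
            "proline_max_pct": max(prolines),
            "identity_min_pct": ident_min,
            "identity_max_pct": ident_max,
        })
    return pd.DataFrame(rows)


def peptide_mass(sequence: str, tag: str = "") -> float:
    """Average-isotopic peptide mass in kDa (3 decimals).

    ``tag`` is an optional N-terminal tag sequence fused to the peptide
    (a single peptide bond, i.e. one water is lost at the junction).
    """
    full = (tag + sequence).upper()
    if not full:
        raise ValueError("empty sequence")
    bad = set(full) - set(AA20)
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    dalton = molecular_weight(full, seq_type="protein", monoisotopic=False)
    return round(dalton / 1000.0, 3)
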