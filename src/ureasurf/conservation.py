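"""Per-position conservation scoring from a multiple sequence alignment.

Conservation of a query residue is the percentage of homologs carrying the
identical amino acid at the aligned column — the statistic used to rank
candidate interaction residues of CPS1 and OTC against their 233 and 270
animal homologs.  The query itself is excluded from the denominator by
default; gaps and ambiguous residues count as non-matching.  Per-taxon
residue sets summarise which amino acids each group of species tolerates at
a position.
"""

from __future__ import annotations

import io
import logging
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from Bio import AlignIO

logger = logging.getLogger(__name__)

__all__ = [
    "Alignment",
    "ConservationProfile",
    "read_alignment",
    "read_taxonomy",
    "column_map",
    "conservation_score",
    "group_residue_sets",
    "profile_table",
    "n_fully_conserved",
]

GAP = "-"
_AMBIGUOUS = set("XBZJUO*.")


@dataclass
class Alignment:
    """Equal-length aligned records with a designated query sequence."""

    records: list[tuple[str, str]]  # (sequence id, aligned sequence)
    query_id: str
    taxonomy: dict[str, str] = field(default_factory=dict)  # id -> group label

    def __post_init__(self):
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) > 1:
            raise ValueError("aligned sequences have unequal lengths")
        ids = [rid for rid, _ in self.records]
        if self.query_id not in ids:
            raise KeyError(f"query id {self.query_id!r} not in alignment")

    @property
    def query(self) -> str:
        return dict(self.records)[self.query_id]

    @property
    def homologs(self) -> list[tuple[str, str]]:
        return [(rid, seq) for rid, seq in self.records if rid != self.query_id]

    @property
    def length(self) -> int:
        return len(self.records[0][1])


@dataclass
class ConservationProfile:
    """Per-query-position conservation with per-group residue sets."""

    rows: pd.DataFrame  # columns: position, aa, score, score_exact, one per group


def read_alignment(
    source: str,
    query_id: str,
    taxonomy: dict[str, str] | None = None,
    fmt: str | None = None,
) -> Alignment:
    """Read a FASTA or Clustal alignment (path or literal text).

    The format is auto-detected from the content when not given.  Sequences
    are upper-cased; '.' gaps are normalised to '-'.
    """
    if "\n" in source:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    if fmt is None:
        head = text.lstrip()[:30].upper()
        fmt = "clustal" if head.startswith("CLUSTAL") else "fasta"
    msa = AlignIO.read(io.StringIO(text), fmt)
    if len(msa) < 2:
        raise ValueError("alignment must contain at least 2 sequences")
    records = [(rec.id, str(rec.seq).upper().replace(".", GAP)) for rec in msa]
    return Alignment(records=records, query_id=query_id,
                     taxonomy=dict(taxonomy or {}))


def read_taxonomy(source: str) -> dict[str, str]:
    """Two-column tab-separated (sequence id, group) sidecar file or text."""
    text = source if "\n" in source else open(source).read()
    out: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rid, group = line.split("\t")[:2]
        out[rid] = group
    return out


def column_map(alignment: Alignment) -> dict[int, int]:
    """1-based query residue position -> 1-based alignment column."""
    mapping = {}
    pos = 0
    for col, ch in enumerate(alignment.query, start=1):
        if ch != GAP:
            pos += 1
            mapping[pos] = col
    return mapping


def conservation_score(
    alignment: Alignment, query_position: int, include_query: bool = False
) -> float:
    """Percent of homologs identical to the query at ``query_position``.

    Full precision; gaps and ambiguous residues never match.  Set
    ``include_query`` to count the query sequence in the denominator
    (sensitivity check; off by default).
    """
    cmap = column_map(alignment)
    if query_position not in cmap:
        raise IndexError(f"position {query_position} outside ungapped query")
    col = cmap[query_position] - 1
    query_aa = alignment.query[col]
    seqs = [seq for _, seq in alignment.homologs]
    if include_query:
        seqs.append(alignment.query)
    if not seqs:
        return 0.0
    matches = sum(
        1 for seq in seqs
        if seq[col] == query_aa and seq[col] != GAP and seq[col] not in _AMBIGUOUS
    )
    return 100.0 * matches / len(seqs)


def group_residue_sets(
    alignment: Alignment,
    query_position: int,
    taxonomy: dict[str, str] | None = None,
    ambiguous_min_fraction: float = 0.05,
) -> dict[str, str]:
    """Distinct residues per taxonomic group at a position.

    Rendered as a '/'-joined string ordered by within-group frequency
    (ties alphabetical).  Ambiguity codes collapse to 'X' and are shown only
    when they reach ``ambiguous_min_fraction`` of the group.  Sequences with
    no taxonomy entry are excluded (with a warning) from group sets but still
    count in conservation scores.
    """
    taxonomy = taxonomy if taxonomy is not None else alignment.taxonomy
    col = column_map(alignment)[query_position] - 1
    counts: dict[str, Counter] = {}
    totals: Counter = Counter()
    for rid, seq in alignment.homologs:
        group = taxonomy.get(rid)
        if group is None:
            logger.warning("sequence %r has no taxonomy group; excluded from sets", rid)
            continue
        ch = seq[col]
        if ch == GAP:
            continue
        totals[group] += 1
        counts.setdefault(group, Counter())[
            "X" if ch in _AMBIGUOUS else ch
        ] += 1
    out = {}
    for group, counter in counts.items():
        kept = [
            (aa, n) for aa, n in counter.items()
            if aa != "X" or n >= ambiguous_min_fraction * totals[group]
        ]
        kept.sort(key=lambda t: (-t[1], t[0]))
        out[group] = "/".join(aa for aa, _ in kept)
    return out


def _round_half_up(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def profile_table(
    alignment: Alignment,
    positions: list[int],
    taxonomy: dict[str, str] | None = None,
    include_query: bool = False,
) -> ConservationProfile:
    """One row per requested query position: score plus group residue sets.

    Duplicate positions are dropped (first occurrence wins, order preserved);
    out-of-range positions raise.  Reported scores are integers rounded
    half-up; the exact value is kept in ``score_exact``.
    """
    cmap = column_map(alignment)
    seen, ordered = set(), []
    for pos in positions:
        if pos not in cmap:
            raise IndexError(f"position {pos} outside ungapped query (1..{len(cmap)})")
        if pos not in seen:
            seen.add(pos)
            ordered.append(pos)
    taxonomy = taxonomy if taxonomy is not None else alignment.taxonomy
    groups = sorted(set(taxonomy.values()))
    rows = []
    for pos in ordered:
        exact = conservation_score(alignment, pos, include_query=include_query)
        sets = group_residue_sets(alignment, pos, taxonomy)
        aa = alignment.query[cmap[pos] - 1]
        row = {
            "position": pos,
            "aa": aa,
            "residue_id": f"{aa}{pos}",
            "score": _round_half_up(exact),
            "score_exact": exact,
        }
        for g in groups:
            row[g] = sets.get(g, "")
        rows.append(row)
    return ConservationProfile(rows=pd.DataFrame(rows))


def n_fully_conserved(profile: ConservationProfile) -> int:
    """How many profiled positions have a reported score of 100."""
    return int((profile.rows["score"] == 100).sum())
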