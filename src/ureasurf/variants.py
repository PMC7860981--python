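"""Missense-variant mapping, stability classification and the candidate ledger.

Disease-causing missense variants (HGVS protein notation, numbered on the
pre-protein) are located on the apo and liganded structures via per-residue
accessibility tables, classified by predicted stability change (ddG,
kcal/mol, positive = destabilising), and filtered to the candidate
interaction residues: surface-exposed in at least one structural state, not
destabilising, not already explained by experimental characterisation, and —
when a functional-site list is supplied — distant from catalytic and
substrate-binding residues.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .sasa import ResidueAccessibility
from .structures import Structure, _THREE_TO_ONE

logger = logging.getLogger(__name__)

__all__ = [
    "MissenseVariant",
    "StabilityClass",
    "LedgerRow",
    "UnsupportedVariantError",
    "parse_variant",
    "stability_class",
    "accessibility_index",
    "locate_variant",
    "site_distance_map",
    "build_ledger",
    "summarize_counts",
]

#: ddG (kcal/mol) bounds of the "similar stability" class; destabilising above,
#: more stable below zero.
DDG_SIMILAR_RANGE = (0.0, 2.0)
#: Default minimum distance (Angstrom) from a candidate residue to the nearest
#: annotated functional-site atom.
DEFAULT_SITE_DISTANCE_CUTOFF = 8.0


class UnsupportedVariantError(ValueError):
    """Token is not a simple missense substitution (nonsense, frameshift...)."""


class StabilityClass(str, Enum):
    MORE_STABLE = "more_stable"
    SIMILAR = "similar"
    DESTABILIZING = "destabilizing"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class MissenseVariant:
    ref_aa: str
    position: int  # 1-based pre-protein coordinate
    alt_aa: str
    source_label: str = ""
    ddg: float | None = None  # kcal/mol

    def __post_init__(self):
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"reference and alternate residues equal: {self}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1: {self}")

    @property
    def token(self) -> str:
        return f"p.{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass
class LedgerRow:
    variant: MissenseVariant
    surface: dict[str, bool | None] = field(default_factory=dict)  # state -> flag
    discordant: dict[str, str] = field(default_factory=dict)  # state -> found aa
    stability: StabilityClass = StabilityClass.UNKNOWN
    conservation: float | None = None
    annotation: str = ""
    site_distance: float | None = None
    candidate: bool = False

    @property
    def surface_any(self) -> bool:
        return any(v is True for v in self.surface.values())


_ONE = set(_THREE_TO_ONE.values())
_THREE_LOWER = {k.capitalize(): v for k, v in _THREE_TO_ONE.items()}
_UNSUPPORTED = re.compile(
    r"(fs|del|dup|ins|ext|\*|Ter|^=$)", re.IGNORECASE
)
_TOKEN = re.compile(r"^(?:p\.)?\(?([A-Za-z]{1,3})(\d+)([A-Za-z]{1,3})\)?$")


def _normalise_aa(code: str) -> str:
    if len(code) == 1 and code.upper() in _ONE:
        return code.upper()
    if len(code) == 3 and code.capitalize() in _THREE_LOWER:
        return _THREE_LOWER[code.capitalize()]
    raise UnsupportedVariantError(f"unrecognised amino-acid code {code!r}")


def parse_variant(token: str, source_label: str = "",
                  ddg: float | None = None) -> MissenseVariant:
    """Parse an HGVS-style protein token such as 'p.R40H' or 'p.Arg721Gln'.

    Only simple missense substitutions are supported; nonsense, frameshift
    and indel tokens raise :class:`UnsupportedVariantError`.
    """
    token = token.strip()
    if _UNSUPPORTED.search(token.removeprefix("p.")):
        raise UnsupportedVariantError(f"not a missense substitution: {token!r}")
    m = _TOKEN.match(token)
    if not m:
        raise UnsupportedVariantError(f"cannot parse variant token {token!r}")
    ref, pos, alt = m.groups()
    return MissenseVariant(
        ref_aa=_normalise_aa(ref),
        position=int(pos),
        alt_aa=_normalise_aa(alt),
        source_label=source_label,
        ddg=ddg,
    )


def stability_class(ddg: float | None) -> StabilityClass:
    """Classify a predicted stability change.

    ddG in [0, 2] kcal/mol: similar stability to wild type (both bounds
    inclusive); ddG < 0: more stable; ddG > 2: destabilising; absent: unknown.
    """
    if ddg is None:
        return StabilityClass.UNKNOWN
    lo, hi = DDG_SIMILAR_RANGE
    if ddg < lo:
        return StabilityClass.MORE_STABLE
    if ddg <= hi:
        return StabilityClass.SIMILAR
    return StabilityClass.DESTABILIZING


def accessibility_index(
    accessibilities: list[ResidueAccessibility],
    structure: Structure | None = None,
    numbering_offset: int | dict[str, int] = 0,
) -> dict[int, ResidueAccessibility]:
    """Index residue accessibilities by pre-protein position.

    ``numbering_offset`` maps author numbering to pre-protein coordinates
    (pre-protein = seq_num + offset); per-chain offsets may be given as a
    dict.  When several chains resolve the same pre-protein position (a
    homotrimer), the most exposed copy is kept — a residue is reported as
    surface if it is on the surface of any subunit.
    """
    index: dict[int, ResidueAccessibility] = {}
    for acc in accessibilities:
        if isinstance(numbering_offset, dict):
            offset = numbering_offset.get(acc.chain_id, 0)
        else:
            offset = numbering_offset
        pos = acc.seq_num + offset
        prev = index.get(pos)
        if prev is None or (acc.rel_sasa or 0.0) > (prev.rel_sasa or 0.0):
            index[pos] = acc
    return index


def locate_variant(
    variant: MissenseVariant,
    state_indexes: dict[str, dict[int, ResidueAccessibility]],
) -> LedgerRow:
    """Surface flags per structural state plus data-quality discordances.

    For each state: ``True``/``False`` if the residue is resolved there,
    ``None`` if absent.  If the structure's residue identity disagrees with
    the variant's reference residue the row is still emitted, with the
    observed amino acid recorded in ``discordant``.
    """
    row = LedgerRow(variant=variant, stability=stability_class(variant.ddg))
    for state, index in state_indexes.items():
        acc = index.get(variant.position)
        if acc is None:
            row.surface[state] = None
            continue
        row.surface[state] = bool(acc.is_surface)
        if acc.aa != variant.ref_aa:
            row.discordant[state] = acc.aa
    return row


def site_distance_map(
    structure: Structure,
    functional_sites: list[tuple[str, int]],
    numbering_offset: int | dict[str, int] = 0,
) -> dict[int, float]:
    """Minimum heavy-atom distance from every residue to the functional sites.

    ``functional_sites`` lists (chain_id, author seq_num) of catalytic and
    substrate-binding residues.  Returns pre-protein position -> distance (A).
    """
    site_coords = []
    wanted = set(functional_sites)
    for res in structure.residues():
        if (res.chain_id, res.seq_num) in wanted:
            site_coords.extend(a.coords for a in res.atoms)
    if not site_coords:
        raise ValueError("no functional-site residues found in structure")
    sites = np.array(site_coords)
    out: dict[int, float] = {}
    for res in structure.residues():
        offset = (
            numbering_offset.get(res.chain_id, 0)
            if isinstance(numbering_offset, dict) else numbering_offset
        )
        pos = res.seq_num + offset
        coords = np.array([a.coords for a in res.atoms])
        d = float(np.sqrt(
            ((coords[:, None, :] - sites[None, :, :]) ** 2).sum(-1)
        ).min())
        prev = out.get(pos)
        if prev is None or d < prev:
            out[pos] = d
    return out


def build_ledger(
    variants: list[MissenseVariant],
    state_indexes: dict[str, dict[int, ResidueAccessibility]],
    annotations: dict[str, str] | None = None,
    conservation: dict[int, float] | None = None,
    site_distances: dict[int, float] | None = None,
    site_distance_cutoff: float = DEFAULT_SITE_DISTANCE_CUTOFF,
    allow_unknown_ddg: bool = False,
) -> list[LedgerRow]:
    """Assemble the candidate-interaction-residue ledger.

    A variant is a candidate iff it is on the surface in at least one state,
    its stability class is similar/more stable (unknown passes only with
    ``allow_unknown_ddg``), it carries no experimental annotation explaining
    the disease mechanism, and — when distances are provided — it lies
    farther than ``site_distance_cutoff`` from every functional-site atom.
    Duplicate variant tokens are dropped with a warning.
    """
    annotations = annotations or {}
    seen: set[str] = set()
    rows: list[LedgerRow] = []
    for variant in variants:
        if variant.token in seen:
            logger.warning("duplicate variant %s dropped", variant.token)
            continue
        seen.add(variant.token)
        row = locate_variant(variant, state_indexes)
        row.annotation = annotations.get(variant.token, "")
        if conservation is not None:
            row.conservation = conservation.get(variant.position)
        if site_distances is not None:
            row.site_distance = site_distances.get(variant.position)
        stability_ok = row.stability in (
            StabilityClass.SIMILAR, StabilityClass.MORE_STABLE
        ) or (allow_unknown_ddg and row.stability is StabilityClass.UNKNOWN)
        distance_ok = (
            site_distances is None
            or (row.site_distance is not None
                and row.site_distance > site_distance_cutoff)
        )
        row.candidate = (
            row.surface_any and stability_ok and not row.annotation and distance_ok
        )
        rows.append(row)
    return rows


def summarize_counts(ledger: list[LedgerRow]) -> dict[str, int]:
    """Category counts over variants and over distinct affected residues."""
    states = sorted({s for row in ledger for s in row.surface})
    two_state = len(states) == 2

    def _residues(rows):
        return len({r.variant.position for r in rows})

    surface_rows = [r for r in ledger if r.surface_any]
    candidates = [r for r in ledger if r.candidate]
    unmapped = [
        r for r in ledger if all(v is None for v in r.surface.values())
    ]
    out = {
        "total_missense": len(ledger),
        "surface_variants": len(surface_rows),
        "surface_residues": _residues(surface_rows),
        "candidate_variants": len(candidates),
        "candidate_residues": _residues(candidates),
        "unmapped_variants": len(unmapped),
    }
    if two_state:
        a, b = states
        both = [r for r in ledger
                if r.surface.get(a) is True and r.surface.get(b) is True]
        only_a = [r for r in ledger
                  if r.surface.get(a) is True and r.surface.get(b) is not True]
        only_b = [r for r in ledger
                  if r.surface.get(b) is True and r.surface.get(a) is not True]
        out[f"surface_in_both"] = len(both)
        out[f"surface_{a}_only"] = len(only_a)
        out[f"surface_{b}_only"] = len(only_b)
    return out
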