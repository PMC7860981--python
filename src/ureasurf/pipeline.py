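"""End-to-end orchestration: structures -> SASA -> variants -> ledger, and
sequences -> variable-segment statistics.

Every run is driven by a :class:`RunConfig` whose canonical JSON is hashed;
the hash is embedded in every output file so that two runs with equal
configs and inputs produce byte-identical tables and any numeric discrepancy
is attributable to a pinned parameter.  Stages log record counts in and out.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import conservation as cons
from . import sasa as sasa_mod
from . import variants as var_mod
from . import vs as vs_mod
from .structures import (DEFAULT_RADII_SET, parse_pdb, resolve_alt_locs,
                         strip_hetero)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_surface_pipeline", "run_vs_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All pinned parameters of a run; serialisable, hashable.

    Numbering offsets map author residue numbers to pre-protein (HGVS)
    coordinates per structural state, e.g. ``{"apo": 0, "liganded": 0}``.
    """

    structure_apo: str | None = None
    structure_liganded: str | None = None
    variants: str | None = None
    ddg: str | None = None
    msa: str | None = None
    taxonomy: str | None = None
    functional_sites: str | None = None
    fasta: str | None = None
    annotations: str | None = None
    reference: str | None = None
    out_dir: str = "."
    probe_radius: float = 1.4
    n_points: int = 9600
    threshold_pct: float = 25.0
    radii_set: str = DEFAULT_RADII_SET
    numbering_offset: dict[str, int] = field(default_factory=dict)
    site_distance_cutoff: float = var_mod.DEFAULT_SITE_DISTANCE_CUTOFF
    allow_unknown_ddg: bool = False
    query_id: str | None = None
    seed: int = 0

    @property
    def sasa_params(self) -> sasa_mod.SasaParams:
        return sasa_mod.SasaParams(
            probe_radius=self.probe_radius,
            n_points=self.n_points,
            threshold_pct=self.threshold_pct,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    _PATH_FIELDS = ("structure_apo", "structure_liganded", "variants", "ddg",
                    "msa", "taxonomy", "functional_sites", "fasta",
                    "annotations", "reference")

    @property
    def config_hash(self) -> str:
        """Hash of parameters and input *contents* (not paths or out_dir), so
        equal configs + equal inputs give byte-identical outputs anywhere."""
        d = self.to_dict()
        d.pop("out_dir", None)
        for key in self._PATH_FIELDS:
            value = d.get(key)
            if value and Path(value).exists():
                d[key] = _sha256(value)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _sha256(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


class _OutputWriter:
    """Writes outputs atomically per run: on failure, removes what it wrote."""

    def __init__(self, out_dir: Path, config_hash: str):
        self.out_dir = out_dir
        self.hash = config_hash
        self.written: list[Path] = []
        out_dir.mkdir(parents=True, exist_ok=True)

    def table(self, name: str, frame: pd.DataFrame, float_formats=None) -> Path:
        path = self.out_dir / name
        frame = frame.copy()
        for col, fmt in (float_formats or {}).items():
            if col in frame:
                frame[col] = frame[col].map(
                    lambda v: "" if pd.isna(v) else format(v, fmt)
                )
        body = frame.to_csv(sep="\t", index=False)
        path.write_text(f"# config_hash={self.hash}\n{body}")
        self.written.append(path)
        return path

    def json(self, name: str, payload: dict) -> Path:
        path = self.out_dir / name
        payload = {"config_hash": self.hash, **payload}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        self.written.append(path)
        return path

    def rollback(self) -> None:
        for path in self.written:
            path.unlink(missing_ok=True)


def _load_structure(path: str, state: str, config: RunConfig):
    text = Path(path).read_text()
    st = parse_pdb(text, structure_id=Path(path).stem, state_label=state)
    st = strip_hetero(resolve_alt_locs(st))
    logger.info("stage=load_structure state=%s residues=%d atoms=%d",
                state, st.n_residues, st.n_atoms)
    return st


def _accessibility_frame(accs) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "chain": a.chain_id,
            "seq_num": a.seq_num,
            "aa": a.aa,
            "sasa_A2": a.sasa,
            "max_sasa_A2": a.max_sasa,
            "rel_sasa_pct": a.rel_sasa,
            "is_surface": int(bool(a.is_surface)),
        }
        for a in accs
    ])


def _read_variant_table(config: RunConfig):
    frame = pd.read_csv(config.variants, sep="\t", comment="#",
                        dtype={"variant": str}).fillna("")
    ddg_map: dict[str, float] = {}
    if config.ddg:
        ddg_frame = pd.read_csv(config.ddg, sep="\t", comment="#")
        ddg_map = dict(zip(ddg_frame["variant"], ddg_frame["ddg_kcal_mol"]))
    variants, annotations, failures = [], {}, []
    for _, row in frame.iterrows():
        token = row["variant"]
        ddg = row.get("ddg_kcal_mol", "")
        ddg = float(ddg) if ddg != "" else ddg_map.get(token)
        try:
            v = var_mod.parse_variant(token, source_label=str(row.get("source", "")),
                                      ddg=ddg)
        except ValueError as exc:
            failures.append({"variant": token, "error": str(exc)})
            continue
        variants.append(v)
        annotation = str(row.get("annotation", "") or "")
        if annotation:
            annotations[v.token] = annotation
    logger.info("stage=read_variants in=%d parsed=%d failed=%d",
                len(frame), len(variants), len(failures))
    return variants, annotations, failures


def run_surface_pipeline(config: RunConfig) -> dict:
    """Structure(s) + variants (+ ddG, MSA, sites) -> reports.

    Writes per-state accessibility tables, the variant ledger, summary
    counts, the conservation profile (if an alignment is given), a
    discordance report and a JSON provenance block.  Returns the summary.
    """
    out = _OutputWriter(Path(config.out_dir), config.config_hash)
    try:
        return _run_surface(config, out)
    except PipelineError:
        out.rollback()
        raise
    except Exception as exc:  # noqa: BLE001 - stage attribution
        out.rollback()
        raise PipelineError("surface_pipeline", str(exc)) from exc


def _run_surface(config: RunConfig, out: _OutputWriter) -> dict:
    if not config.structure_apo and not config.structure_liganded:
        raise PipelineError("load_structure", "at least one structure is required")
    params = config.sasa_params

    states: dict[str, object] = {}
    if config.structure_apo:
        states["apo"] = _load_structure(config.structure_apo, "apo", config)
    if config.structure_liganded:
        states["liganded"] = _load_structure(
            config.structure_liganded, "liganded", config)

    indexes = {}
    resolved_counts = {}
    for state, structure in states.items():
        accs = sasa_mod.accessibility_table(structure, params, config.radii_set)
        resolved_counts[state] = len(accs)
        out.table(
            f"sasa_{state}.tsv", _accessibility_frame(accs),
            float_formats={"sasa_A2": ".2f", "max_sasa_A2": ".2f",
                           "rel_sasa_pct": ".1f"},
        )
        offset = config.numbering_offset.get(state, 0)
        indexes[state] = var_mod.accessibility_index(accs, numbering_offset=offset)
        n_surface = sum(1 for a in accs if a.is_surface)
        logger.info("stage=sasa state=%s residues=%d surface=%d",
                    state, len(accs), n_surface)

    summary: dict = {
        "resolved_residues": resolved_counts,
        "surface_counts": {
            state: sum(1 for a in idx.values() if a.is_surface)
            for state, idx in indexes.items()
        },
    }

    ledger_rows = []
    failures = []
    if config.variants:
        variants, annotations, failures = _read_variant_table(config)

        conservation_map = None
        if config.msa:
            if not config.query_id:
                raise PipelineError("conservation", "msa given without query_id")
            taxonomy = (cons.read_taxonomy(config.taxonomy)
                        if config.taxonomy else {})
            alignment = cons.read_alignment(config.msa, config.query_id, taxonomy)
            cmap = cons.column_map(alignment)
            positions = sorted({
                v.position for v in variants if v.position in cmap
            })
            profile = cons.profile_table(alignment, positions)
            out.table("conservation_profile.tsv", profile.rows.drop(
                columns=["score_exact"]))
            conservation_map = dict(zip(profile.rows["position"],
                                        profile.rows["score_exact"]))
            logger.info("stage=conservation positions=%d", len(positions))

        site_distances = None
        if config.functional_sites:
            sites_frame = pd.read_csv(config.functional_sites, sep="\t",
                                      comment="#")
            sites = list(zip(sites_frame["chain"], sites_frame["seq_num"]))
            state, structure = next(iter(states.items()))
            site_distances = var_mod.site_distance_map(
                structure, sites, config.numbering_offset.get(state, 0))

        ledger_rows = var_mod.build_ledger(
            variants, indexes,
            annotations=annotations,
            conservation=conservation_map,
            site_distances=site_distances,
            site_distance_cutoff=config.site_distance_cutoff,
            allow_unknown_ddg=config.allow_unknown_ddg,
        )
        state_names = list(indexes)
        frame = pd.DataFrame([
            {
                "variant": r.variant.token,
                "position": r.variant.position,
                **{
                    f"surface_{s}": ("" if r.surface.get(s) is None
                                     else int(bool(r.surface[s])))
                    for s in state_names
                },
                "stability": r.stability.value,
                "ddg_kcal_mol": r.variant.ddg,
                "conservation": r.conservation,
                "site_distance_A": r.site_distance,
                "annotation": r.annotation,
                "candidate": int(r.candidate),
            }
            for r in ledger_rows
        ])
        out.table("ledger.tsv", frame,
                  float_formats={"ddg_kcal_mol": ".2f", "conservation": ".0f",
                                 "site_distance_A": ".1f"})
        discord = pd.DataFrame([
            {"variant": r.variant.token, "state": s, "structure_aa": aa,
             "variant_ref_aa": r.variant.ref_aa}
            for r in ledger_rows for s, aa in r.discordant.items()
        ])
        if failures:
            discord = pd.concat(
                [discord, pd.DataFrame(failures)], ignore_index=True)
        out.table("discordance.tsv", discord if len(discord) else
                  pd.DataFrame(columns=["variant", "state", "structure_aa",
                                        "variant_ref_aa"]))
        summary.update(var_mod.summarize_counts(ledger_rows))
        logger.info("stage=ledger variants=%d candidates=%d",
                    len(ledger_rows), summary.get("candidate_variants", 0))

    out.json("summary.json", summary)
    out.json("provenance.json", {
        "config": config.to_dict(),
        "input_checksums": {
            k: _sha256(v) for k, v in {
                "structure_apo": config.structure_apo,
                "structure_liganded": config.structure_liganded,
                "variants": config.variants,
                "ddg": config.ddg,
                "msa": config.msa,
            }.items() if v
        },
        "max_sasa_provenance": sasa_mod.max_sasa_table(
            params, config.radii_set).provenance,
    })
    return summary


def run_vs_pipeline(config: RunConfig) -> pd.DataFrame:
    """FASTA + annotations + reference -> per-record VS table + group summary."""
    out = _OutputWriter(Path(config.out_dir), config.config_hash)
    try:
        return _run_vs(config, out)
    except PipelineError:
        out.rollback()
        raise
    except Exception as exc:  # noqa: BLE001
        out.rollback()
        raise PipelineError("vs_pipeline", str(exc)) from exc


def _run_vs(config: RunConfig, out: _OutputWriter) -> pd.DataFrame:
    if not (config.fasta and config.annotations and config.reference):
        raise PipelineError("vs_input", "fasta, annotations and reference required")
    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(config.fasta, "fasta")}
    if not seqs:
        raise PipelineError("vs_input", "no sequences in FASTA input")
    reference = str(next(SeqIO.parse(config.reference, "fasta")).seq).upper()
    annot = pd.read_csv(config.annotations, sep="\t", comment="#")
    annotated = {row["id"]: row for _, row in annot.iterrows()}

    records, skipped = [], []
    for rid, seq in seqs.items():
        if rid not in annotated:
            logger.warning("stage=vs record %r unannotated; skipped", rid)
            skipped.append(rid)
            continue
        row = annotated[rid]
        records.append(vs_mod.NagsRecord(
            id=rid, group=str(row["group"]), sequence=seq,
            mpp_site=int(row["mpp_site"])))
    logger.info("stage=vs in=%d annotated=%d skipped=%d",
                len(seqs), len(records), len(skipped))

    rows = []
    segments = []
    for rec in records:
        vseg = vs_mod.find_vs(rec, reference)
        segments.append(vseg)
        rows.append({
            "id": rec.id,
            "group": rec.group,
            "vs_start": vseg.start,
            "vs_end": vseg.end,
            "vs_length": vseg.length,
            "proline_pct": vseg.proline_pct if vseg.length else float("nan"),
        })
    table = pd.DataFrame(rows)
    out.table("vs_table.tsv", table, float_formats={"proline_pct": ".1f"})

    summary = vs_mod.group_stats(records, reference)
    out.table("vs_group_summary.tsv", summary, float_formats={
        "proline_min_pct": ".1f", "proline_max_pct": ".1f",
        "identity_min_pct": ".1f", "identity_max_pct": ".1f"})

    # LOGO-ready export: VS sequences right-padded to a common length
    width = max((s.length for s in segments), default=0)
    fasta = "".join(
        f">{s.parent_id}\n{s.sequence.ljust(width, '-')}\n" for s in segments
    )
    path = out.out_dir / "vs_aligned.fasta"
    path.write_text(fasta)
    out.written.append(path)

    out.json("vs_report.json", {
        "n_input": len(seqs),
        "n_analyzed": len(records),
        "skipped_unannotated": skipped,
    })
    return summary
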