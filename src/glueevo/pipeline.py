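"""End-to-end orchestration: validate a config, run the stages whose inputs
are present, and assemble a provenance-carrying :class:`AnalysisReport`.

Stages run in the order of the comparative argument: expression screen ->
repeat architecture -> domain properties -> selection -> pull-test mechanics.
A stage whose inputs are absent from the config is skipped and marked as such;
a failing stage aborts the run naming the stage and offending record. The
report is deterministic for a fixed config and seed except for its timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__, expression, properties, pulltest, repeats, selection
from .formats import (
    AnalysisReport,
    ConfigurationError,
    read_codon_alignment,
    read_expression_table,
    read_fasta,
)

log = logging.getLogger("glueevo")


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


_SECTION_KEYS = {
    "expression": {"table", "roles", "focal", "pseudocount", "genes"},
    "architecture": {
        "fasta", "glyco_track", "domains", "signal",
        "min_period", "max_period", "min_copies", "min_identity",
    },
    "properties": {"fasta", "spans", "disorder", "secstruct", "threshold"},
    "selection": {"alignment", "tree", "site_classes", "threshold"},
    "pulltest": {"records", "compare", "n_perm"},
}
_TOP_KEYS = set(_SECTION_KEYS) | {"seed", "out_dir"}
_FILE_KEYS = {
    "table", "roles", "fasta", "glyco_track", "domains", "spans",
    "alignment", "tree", "site_classes", "records", "disorder", "secstruct",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (flat per-stage key/value sections)."""

    seed: int = 0
    out_dir: str | None = None
    sections: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "PipelineConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        sections: dict[str, dict] = {}
        for name, allowed in _SECTION_KEYS.items():
            if name not in raw:
                continue
            sec = dict(raw[name] or {})
            bad = set(sec) - allowed
            if bad:
                raise ConfigurationError(f"section {name!r}: unknown keys {sorted(bad)}")
            for key in _FILE_KEYS & set(sec):
                if sec[key] is None:
                    continue
                p = Path(sec[key])
                if base is not None and not p.is_absolute():
                    p = base / p
                if not p.exists():
                    raise ConfigurationError(f"section {name!r}: file not found: {p}")
                sec[key] = str(p)
            sections[name] = sec
        return cls(seed=int(raw.get("seed", 0)), out_dir=raw.get("out_dir"), sections=sections)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=path.parent)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _region_dict(r: repeats.RepeatRegion) -> dict:
    return {
        "start": r.start,
        "end": r.end,
        "unit_length": r.unit_length,
        "copy_number": round(r.copy_number, 3),
        "consensus": r.consensus,
        "mean_identity": round(r.mean_identity, 4),
        "unit_pg_counts": list(r.unit_pg_counts),
        "unit_st_counts": list(r.unit_st_counts),
    }


def _run_expression(sec: dict) -> dict:
    table = read_expression_table(sec["table"], sec["roles"])
    focal = sec["focal"]
    pseudo = float(sec.get("pseudocount", expression.DEFAULT_PSEUDOCOUNT))
    genes = sec.get("genes")
    results = expression.screen_genes(table, focal, genes=genes, pseudocount=pseudo)
    return {
        "focal_species": focal,
        "pseudocount": pseudo,
        "null_size": results[0].null_size if results else len(table.reference_genes),
        "ratios": [
            {"gene": r.gene, "ratio": r.ratio, "p": r.p} for r in results
        ],
    }


def _run_architecture(sec: dict) -> dict:
    from .formats import read_residue_track, read_spans_tsv

    seqs = read_fasta(sec["fasta"])
    domains = read_spans_tsv(sec["domains"]) if sec.get("domains") else {}
    signals = read_spans_tsv(sec["signal"]) if sec.get("signal") else {}
    track = (
        read_residue_track(sec["glyco_track"], kind="glyco")
        if sec.get("glyco_track")
        else None
    )
    det_kwargs = {
        k: sec[k]
        for k in ("min_period", "max_period", "min_copies", "min_identity")
        if k in sec
    }
    out = {}
    for seq in seqs:
        regions = repeats.detect_tandem_repeats(seq, **det_kwargs)
        sig = signals.get(seq.id)
        annotation = repeats.annotate_architecture(
            seq,
            domain_hits=domains.get(seq.id, []),
            repeats=regions,
            signal_peptide=(sig[0][0], sig[0][1]) if sig else None,
        )
        entry = {
            "repeats": [_region_dict(r) for r in regions],
            "segments": [dataclasses.asdict(s) for s in annotation.segments],
        }
        if track is not None and track.sequence_id == seq.id:
            entry["glyco_candidates_per_region"] = [
                repeats.count_glyco_candidates((r.start, r.end), seq, track)
                for r in regions
            ]
        out[seq.id] = entry
    return out


def _run_properties(sec: dict) -> dict:
    from .formats import read_residue_track, read_spans_tsv

    seqs = {s.id: s for s in read_fasta(sec["fasta"])}
    spans = read_spans_tsv(sec["spans"])
    threshold = float(sec.get("threshold", 0.5))

    def load_tracks(key: str, kind: str) -> dict:
        paths = sec.get(key)
        if not paths:
            return {}
        if isinstance(paths, str):
            paths = [paths]
        tracks = [read_residue_track(p, kind=kind) for p in paths]
        return {t.sequence_id: t for t in tracks}

    disorder = load_tracks("disorder", "disorder")
    secstruct = load_tracks("secstruct", "secstruct")
    out = {}
    for seq_id, span_list in spans.items():
        if seq_id not in seqs:
            raise StageError("properties", f"span references unknown sequence {seq_id!r}")
        profiles = []
        for start, end, label in span_list:
            p = properties.profile_domain(
                seqs[seq_id],
                (start, end),
                disorder_track=disorder.get(seq_id),
                secstruct_track=secstruct.get(seq_id),
                threshold=threshold,
            )
            d = dataclasses.asdict(p)
            d["label"] = label
            profiles.append(d)
        out[seq_id] = profiles
    return out


def _run_selection(sec: dict) -> dict:
    out: dict = {}
    if sec.get("site_classes"):
        table = selection.parse_site_class_tsv(sec["site_classes"])
        threshold = float(sec.get("threshold", 0.5))
        summary = selection.positive_site_proportion(table, threshold)
        out["positive_sites"] = {
            "label": summary.label,
            "n_sites": summary.n_sites,
            "n_positive": summary.n_positive,
            "percent_positive": round(summary.percent_positive, 1),
            "posterior_threshold": threshold,
        }
    if sec.get("alignment"):
        aln = read_codon_alignment(sec["alignment"], sec.get("tree"))
        pairs = []
        for i in range(len(aln.records)):
            for j in range(i + 1, len(aln.records)):
                r = selection.ng86_pairwise(aln.records[i], aln.records[j])
                pairs.append(
                    {
                        "a": aln.records[i].id,
                        "b": aln.records[j].id,
                        "dN": r.dN,
                        "dS": r.dS,
                        "omega": r.omega,
                        "n_skipped": r.n_skipped,
                    }
                )
        defined = [p["omega"] for p in pairs if p["omega"] is not None]
        out["ng86"] = {
            "pairs": pairs,
            "mean_omega": sum(defined) / len(defined) if defined else None,
        }
    return out


def _run_pulltest(sec: dict, seed: int) -> dict:
    records = pulltest.read_pulltest_tsv(sec["records"])
    summary = pulltest.group_summary(records)
    out: dict = {"groups": summary.to_dict(orient="records")}
    if sec.get("compare"):
        a, b = sec["compare"]
        out["comparison"] = {
            "treatment_a": a,
            "treatment_b": b,
            "p": pulltest.permutation_test(
                records, a, b, n_perm=int(sec.get("n_perm", 10000)), seed=seed
            ),
        }
    return out


_STAGES = ("expression", "architecture", "properties", "selection", "pulltest")


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute all configured stages and return the assembled report."""
    report = AnalysisReport()
    inputs = {}
    for sec in config.sections.values():
        for key in _FILE_KEYS & set(sec):
            if sec[key]:
                inputs[sec[key]] = _sha256(sec[key])
    report.content.update(
        {
            "tool": {"name": "glue-evo", "version": __version__},
            "seed": config.seed,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "inputs": inputs,
            "stages": {},
        }
    )
    runners = {
        "expression": lambda sec: _run_expression(sec),
        "architecture": lambda sec: _run_architecture(sec),
        "properties": lambda sec: _run_properties(sec),
        "selection": lambda sec: _run_selection(sec),
        "pulltest": lambda sec: _run_pulltest(sec, config.seed),
    }
    for stage in _STAGES:
        if stage not in config.sections:
            report.content["stages"][stage] = {"status": "skipped"}
            log.info("stage %s: skipped (no inputs configured)", stage)
            continue
        log.info("stage %s: running", stage)
        try:
            result = runners[stage](config.sections[stage])
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        report.content["stages"][stage] = {
            "status": "run",
            "params": {
                k: v for k, v in config.sections[stage].items() if k not in _FILE_KEYS
            },
            "results": result,
        }
    return report
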