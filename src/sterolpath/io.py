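"""Format readers/writers and the two workflow drivers.

FASTA handling goes through Biopython with strict validation (duplicate
ids and illegal residues are rejected with positions); the drivers
:func:`run_annotate` and :func:`run_quant` bind the library stages into
the two halves of the study workflow and write TSV/JSON reports plus a
machine-readable run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

import sterolpath
from sterolpath.align import AlignmentParams, TierThresholds, _ALPHABET
from sterolpath.annotate import (
    EvidenceFloor,
    assign_orthologs,
    classify_osc,
    detect_altsqe,
    load_default_motif,
    load_default_rule,
)
from sterolpath.catalog import load_default_catalog
from sterolpath.pathway import assemble_routes, infer_backbone
from sterolpath.quant import (
    DEFAULT_LOD,
    ddct_expression,
    dose_response_table,
    log2fc_matrix,
    quantify_frame,
    read_measurements,
    read_qpcr,
)
from sterolpath.synth import load_reference_library

log = logging.getLogger(__name__)


class IOError_(ValueError):
    pass


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read protein FASTA as (id, sequence) pairs with strict validation."""
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with open(path) as fh:
        parsed = list(SeqIO.parse(fh, "fasta"))
    if not parsed:
        raise IOError_(f"{path}: empty FASTA file")
    for rec in parsed:
        if rec.id in seen:
            raise IOError_(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        for i, ch in enumerate(seq, start=1):
            if ch not in _ALPHABET:
                raise IOError_(
                    f"{path}: illegal residue {ch!r} at position {i} of {rec.id}"
                )
        records.append((rec.id, seq))
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs wrapped at 60 columns."""
    seq_records = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seq_records)


@dataclass
class RunConfig:
    """Configuration shared by the workflow drivers."""

    proteome_path: Path | None = None
    measurements_path: Path | None = None
    qpcr_path: Path | None = None
    out_dir: Path = Path("results")
    params: AlignmentParams = field(default_factory=AlignmentParams)
    tiers: TierThresholds = field(default_factory=TierThresholds)
    floor: EvidenceFloor = field(default_factory=EvidenceFloor)
    lod: float = DEFAULT_LOD
    seed: int = 0

    def validate(self, need: tuple[str, ...]) -> None:
        for attr in need:
            p = getattr(self, attr)
            if p is None or not Path(p).exists():
                raise IOError_(f"config: {attr} missing or does not exist: {p}")


def _manifest(config: RunConfig, inputs: list[Path]) -> dict:
    h = hashlib.sha256()
    for p in sorted(str(p) for p in inputs):
        h.update(Path(p).read_bytes())
    cfg = {
        "seed": config.seed,
        "lod": config.lod,
        "params": dataclasses.asdict(config.params),
        "tiers": dataclasses.asdict(config.tiers),
        "floor": dataclasses.asdict(config.floor),
    }
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()
    return {
        "version": sterolpath.__version__,
        "config": cfg,
        "config_sha256": cfg_hash,
        "inputs_sha256": h.hexdigest(),
    }


def run_annotate(config: RunConfig) -> dict:
    """Annotate a proteome: ortholog calls, classifier calls, pathway report.

    Writes ortholog_calls.tsv, annotation_report.json and a run manifest
    into ``config.out_dir``; returns the report as a dict.
    """
    config.validate(("proteome_path",))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    proteome = read_fasta(config.proteome_path)
    catalog = load_default_catalog()
    references = load_reference_library()
    rule = load_default_rule()
    motif = load_default_motif()

    calls = assign_orthologs(
        proteome, catalog, references, params=config.params, tiers=config.tiers
    )
    call_rows = []
    for c in calls:
        h = c.best_hit
        call_rows.append(
            {
                "activity": c.activity_symbol,
                "status": c.status,
                "gene": h.query_id if h else "",
                "score": h.raw_score if h else "",
                "evalue": h.evalue if h else "",
                "identity_pct": h.identity_pct if h else "",
                "tier": h.tier if h else "",
            }
        )
    pd.DataFrame(call_rows).to_csv(out / "ortholog_calls.tsv", sep="\t", index=False)

    seq_by_id = dict(proteome)
    osc_call = altsqe_call = None
    osc_gene = next(
        (c.best_hit.query_id for c in calls
         if c.activity_symbol in ("LAS", "CAS") and c.best_hit),
        None,
    )
    if osc_gene:
        osc_call = classify_osc(
            seq_by_id[osc_gene], rule, references[rule.reference_id],
            params=config.params, floor=config.floor, query_id=osc_gene,
        )
    altsqe_gene = next(
        (c.best_hit.query_id for c in calls
         if c.activity_symbol == "AltSQE" and c.best_hit),
        None,
    )
    if altsqe_gene:
        altsqe_call = detect_altsqe(
            seq_by_id[altsqe_gene], motif, references[motif.reference_id],
            params=config.params, floor=config.floor, query_id=altsqe_gene,
        )

    backbone = infer_backbone(calls, catalog)
    routes = assemble_routes(
        calls, catalog,
        altsqe_present=bool(altsqe_call and altsqe_call.verdict == "present"),
    )
    report = {
        "backbone": dataclasses.asdict(backbone),
        "osc": dataclasses.asdict(osc_call) if osc_call else None,
        "altsqe": dataclasses.asdict(altsqe_call) if altsqe_call else None,
        "routes": {
            "reachable": routes.reachable,
            "paths": routes.paths,
            "blocking": routes.blocking,
            "terminal_metabolites": routes.terminal_metabolites,
        },
        "manifest": _manifest(config, [Path(config.proteome_path)]),
    }
    (out / "annotation_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def run_quant(config: RunConfig) -> dict:
    """Quantification workflow over measurement and/or qPCR tables."""
    if config.measurements_path is None and config.qpcr_path is None:
        raise IOError_("config: need a measurement and/or qPCR table")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    inputs: list[Path] = []

    if config.measurements_path is not None:
        config.validate(("measurements_path",))
        inputs.append(Path(config.measurements_path))
        df = read_measurements(config.measurements_path)
        quantified = quantify_frame(df, lod=config.lod)
        quantified.to_csv(out / "quant_values.tsv", sep="\t", index=False)
        if (quantified["conc_uM"] > 0).any():
            effects = dose_response_table(quantified)
            effects.to_csv(out / "effects.tsv", sep="\t", index=False)
            report["n_effects"] = len(effects)
        report["n_quant"] = len(quantified)

    if config.qpcr_path is not None:
        config.validate(("qpcr_path",))
        inputs.append(Path(config.qpcr_path))
        results = ddct_expression(read_qpcr(config.qpcr_path))
        pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
            out / "expression.tsv", sep="\t", index=False
        )
        log2fc_matrix(results).to_csv(out / "log2fc_matrix.tsv", sep="\t")
        report["n_expression"] = len(results)

    report["manifest"] = _manifest(config, inputs)
    (out / "quant_manifest.json").write_text(
        json.dumps(report["manifest"], indent=2)
    )
    return report
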