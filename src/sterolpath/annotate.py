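"""Ortholog assignment and active-site residue-rule classifiers.

Three evidence layers turn a proteome into pathway calls:

* :func:`assign_orthologs` — best-hit search of the proteome against each
  catalog activity's reference ortholog ("the best-matching allele is the
  representative"); an activity is ``not_found`` when no hit clears a
  permissive E-value ceiling with minimal reference coverage.
* :func:`classify_osc` — oxidosqualene cyclase product specificity read
  from the residues aligned to reference positions 381/449/453 (human-OSC
  numbering): Y/H/I → cycloartenol synthase, T/{C,Q}/V → lanosterol
  synthase; mixed signatures are ambiguous, unmapped sites indeterminate.
* :func:`detect_altsqe` — alternative squalene epoxidase detection via the
  nine conserved histidines that coordinate the bimetal active-site center
  of the fatty acid hydroxylase superfamily; present only at 9/9.

Both classifiers apply an evidence floor (local E ≤ 1e-5 and ≥ 40% of the
reference covered); below it the verdict is ``indeterminate`` rather than
negative, distinguishing "no homolog" from "homolog lacking the signature".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from sterolpath.align import (
    AlignmentParams,
    PairwiseAlignment,
    SearchHit,
    TierThresholds,
    AlignmentError,
    map_ref_position,
    pairwise_align,
    search_best_hit,
)
from sterolpath.catalog import PathwayCatalog

log = logging.getLogger(__name__)

CYCLOARTENOL = "cycloartenol_synthase"
LANOSTEROL = "lanosterol_synthase"
AMBIGUOUS = "ambiguous"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class EvidenceFloor:
    max_evalue: float = 1e-5
    min_ref_coverage_pct: float = 40.0

    def met(self, evalue: float, ref_coverage_pct: float) -> bool:
        return evalue <= self.max_evalue and ref_coverage_pct >= self.min_ref_coverage_pct


@dataclass(frozen=True)
class DiagnosticRule:
    """Reference-anchored residue rule for OSC product specificity."""

    reference_id: str
    sites: tuple[int, ...] = (381, 449, 453)
    class_residues: dict[str, tuple[frozenset, ...]] = None  # type: ignore[assignment]

    def __post_init__(self):
        if list(self.sites) != sorted(set(self.sites)):
            raise ValueError("rule sites must be strictly increasing")
        if self.class_residues is None:
            object.__setattr__(
                self,
                "class_residues",
                {
                    CYCLOARTENOL: (frozenset("Y"), frozenset("H"), frozenset("I")),
                    LANOSTEROL: (frozenset("T"), frozenset("CQ"), frozenset("V")),
                },
            )
        for cls, sets in self.class_residues.items():
            if len(sets) != len(self.sites):
                raise ValueError(f"class {cls}: one residue set per site required")


@dataclass(frozen=True)
class MotifSpec:
    """Nine conserved-histidine positions in reference coordinates."""

    reference_id: str
    his_positions: tuple[int, ...]
    required_residue: str = "H"

    def __post_init__(self):
        if len(self.his_positions) != 9:
            raise ValueError("exactly nine histidine positions required")
        if list(self.his_positions) != sorted(set(self.his_positions)):
            raise ValueError("positions must be strictly increasing")


def load_diagnostic_rule(path: str | Path) -> DiagnosticRule:
    doc = yaml.safe_load(Path(path).read_text())
    return DiagnosticRule(
        reference_id=doc["reference_id"],
        sites=tuple(doc["sites"]),
        class_residues={
            cls: tuple(frozenset(res) for res in sets)
            for cls, sets in doc["classes"].items()
        },
    )


def load_motif_spec(path: str | Path) -> MotifSpec:
    doc = yaml.safe_load(Path(path).read_text())
    return MotifSpec(
        reference_id=doc["reference_id"],
        his_positions=tuple(doc["positions"]),
        required_residue=doc.get("required_residue", "H"),
    )


@dataclass
class OscCall:
    query_id: str
    mapped_sites: list[tuple[int | None, str | None]]
    verdict: str
    raw_score: int = 0
    evalue: float = float("inf")
    identity_pct: float = 0.0


@dataclass
class AltSqeCall:
    query_id: str
    conserved_count: int
    observations: list[tuple[int, int | None, str | None]]  # (ref_pos, query_pos, residue)
    verdict: str  # present | absent | indeterminate
    raw_score: int = 0
    evalue: float = float("inf")
    identity_pct: float = 0.0


@dataclass
class OrthologCall:
    activity_symbol: str
    status: str  # found | not_found
    best_hit: SearchHit | None = None
    runner_up_margin: float | None = None  # raw-score margin over rank 2
    verified: bool = True  # unambiguous-assignment check outcome
    all_hits: list[SearchHit] = field(default_factory=list)


def _evidence_alignment(
    query: str, reference: str, params: AlignmentParams, query_id: str, ref_id: str
) -> tuple[PairwiseAlignment, float]:
    aln = pairwise_align(query, reference, params, query_id=query_id, ref_id=ref_id)
    rspan = aln.ref_span
    rcov = 100.0 * (rspan[1] - rspan[0] + 1) / len(reference) if rspan else 0.0
    return aln, rcov


def classify_osc(
    query: str,
    rule: DiagnosticRule,
    reference: str,
    params: AlignmentParams | None = None,
    floor: EvidenceFloor | None = None,
    query_id: str = "query",
) -> OscCall:
    """Classify an OSC query by its residues at the diagnostic sites."""
    params = params or AlignmentParams()
    floor = floor or EvidenceFloor()
    if max(rule.sites) > len(reference):
        raise AlignmentError(
            f"rule site {max(rule.sites)} beyond reference length {len(reference)}"
        )
    aln, rcov = _evidence_alignment(query, reference, params, query_id, rule.reference_id)

    mapped: list[tuple[int | None, str | None]] = []
    for site in rule.sites:
        qpos = map_ref_position(aln, site, ref_len=len(reference)) if not aln.is_empty else None
        mapped.append((qpos, query[qpos - 1] if qpos is not None else None))

    if not floor.met(aln.evalue, rcov) or any(q is None for q, _ in mapped):
        verdict = INDETERMINATE
    else:
        observed = [res for _, res in mapped]
        matches = [
            cls
            for cls, sets in rule.class_residues.items()
            if all(res in allowed for res, allowed in zip(observed, sets))
        ]
        verdict = matches[0] if len(matches) == 1 else AMBIGUOUS
    return OscCall(
        query_id=query_id,
        mapped_sites=mapped,
        verdict=verdict,
        raw_score=aln.raw_score,
        evalue=aln.evalue,
        identity_pct=aln.identity_pct,
    )


def detect_altsqe(
    query: str,
    motif: MotifSpec,
    reference: str,
    params: AlignmentParams | None = None,
    floor: EvidenceFloor | None = None,
    query_id: str = "query",
) -> AltSqeCall:
    """Count conserved motif histidines in the query; present only at 9/9."""
    params = params or AlignmentParams()
    floor = floor or EvidenceFloor()
    if max(motif.his_positions) > len(reference):
        raise AlignmentError(
            f"motif position {max(motif.his_positions)} beyond reference "
            f"length {len(reference)}"
        )
    aln, rcov = _evidence_alignment(query, reference, params, query_id, motif.reference_id)

    observations = []
    conserved = 0
    for pos in motif.his_positions:
        qpos = map_ref_position(aln, pos, ref_len=len(reference)) if not aln.is_empty else None
        residue = query[qpos - 1] if qpos is not None else None
        if residue == motif.required_residue:
            conserved += 1
        observations.append((pos, qpos, residue))

    if not floor.met(aln.evalue, rcov):
        verdict = INDETERMINATE
    elif conserved == 9:
        verdict = "present"
    else:
        verdict = "absent"
    return AltSqeCall(
        query_id=query_id,
        conserved_count=conserved,
        observations=observations,
        verdict=verdict,
        raw_score=aln.raw_score,
        evalue=aln.evalue,
        identity_pct=aln.identity_pct,
    )


def assign_orthologs(
    proteome: list[tuple[str, str]],
    catalog: PathwayCatalog,
    references: dict[str, str],
    params: AlignmentParams | None = None,
    tiers: TierThresholds | None = None,
    not_found_ceiling: float = 10.0,
    min_ref_coverage_pct: float = 25.0,
    ambiguity_factor: float = 1.5,
) -> list[OrthologCall]:
    """One :class:`OrthologCall` per catalog activity.

    ``references`` maps ref_id → protein sequence; for each activity the
    first reference ortholog with a bundled sequence anchors the search.
    Activities with no available reference sequence are skipped with a
    logged warning. ``not_found`` when no hit has E ≤ ``not_found_ceiling``
    with at least ``min_ref_coverage_pct`` of the reference covered.

    Passing hits are additionally verified by an unambiguous-assignment
    check — the computational stand-in for the study design's secondary
    domain verification of selected candidates. A proteome sequence is a
    credible representative of an activity only if its score against that
    activity's reference family (families group references whose
    activities share one locus) is at least ``ambiguity_factor`` times its
    best score against any other family; chance-level alignments have flat
    score profiles across references and fail this, while even distant
    true orthologs dominate their own family.
    """
    if not proteome:
        raise AlignmentError("empty proteome")
    params = params or AlignmentParams()
    tiers = tiers or TierThresholds()

    searched: list[tuple] = []  # (activity, ref_id, family, hits)
    for activity in catalog.activities:
        ref_pair = next(
            (
                (r.ref_id, references[r.ref_id])
                for r in activity.reference_orthologs
                if r.ref_id in references
            ),
            None,
        )
        if ref_pair is None:
            log.warning(
                "activity %s: no reference sequence available, skipped",
                activity.symbol,
            )
            continue
        family = activity.assigned_gene if activity.present else activity.symbol
        hits = search_best_hit(
            proteome, ref_pair, activity_symbol=activity.symbol,
            params=params, tiers=tiers,
        )
        searched.append((activity, ref_pair[0], family, hits))

    # per-query best raw score into each reference family
    family_scores: dict[str, dict[str, int]] = {}
    for _, _, family, hits in searched:
        for h in hits:
            by_fam = family_scores.setdefault(h.query_id, {})
            by_fam[family] = max(by_fam.get(family, 0), h.raw_score)

    calls: list[OrthologCall] = []
    for activity, _, family, hits in searched:
        best = hits[0]
        margin = float(best.raw_score - hits[1].raw_score) if len(hits) > 1 else None
        by_fam = family_scores[best.query_id]
        rival = max(
            (s for f, s in by_fam.items() if f != family), default=0
        )
        verified = by_fam[family] >= ambiguity_factor * rival
        accepted = (
            best.evalue <= not_found_ceiling
            and best.ref_coverage_pct >= min_ref_coverage_pct
            and verified
        )
        calls.append(
            OrthologCall(
                activity_symbol=activity.symbol,
                status="found" if accepted else "not_found",
                best_hit=best if accepted else None,
                runner_up_margin=margin,
                verified=verified,
                all_hits=hits,
            )
        )
    return calls


def load_default_rule() -> DiagnosticRule:
    from sterolpath import data_path

    return load_diagnostic_rule(data_path("osc_rule.yaml"))


def load_default_motif() -> MotifSpec:
    from sterolpath import data_path

    return load_motif_spec(data_path("altsqe_motif.yaml"))
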