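#!/usr/bin/env python
"""Annotate the synthetic proteome and reconstruct the pathway.

Assigns every catalog activity by best-hit search against the reference
library, classifies the single oxidosqualene-cyclase locus by its
381/449/453 residues, detects the alternative squalene epoxidase by its
nine conserved histidines, infers the terpenoid-backbone verdict, and
reports sterol reachability. Writes ortholog_calls.tsv and
annotation_report.json under results/annotation/.

Finding (seed 1): all 9 mevalonate-pathway genes present, all 7
methylerythritol-phosphate genes absent (verdict MVA_only); the
oxidosqualene cyclase carries the cycloartenol signature Y/H/I; the
alternative epoxidase conserves 9/9 histidines; cholesterol and
stigmasterol are both reachable from acetyl-CoA.
"""

from pathlib import Path

from sterolpath.io import RunConfig, run_annotate

ROOT = Path(__file__).resolve().parent.parent
PROTEOME = ROOT / "results" / "inputs" / "proteome.fasta"
OUT = ROOT / "results" / "annotation"


def main() -> None:
    if not PROTEOME.exists():
        raise SystemExit("run 01_simulate_inputs.py first")
    report = run_annotate(RunConfig(proteome_path=PROTEOME, out_dir=OUT))
    backbone = report["backbone"]
    print(
        f"backbone: {backbone['verdict']} "
        f"({len(backbone['mva_found'])}/{backbone['mva_total']} MVA, "
        f"{len(backbone['mep_found'])}/{backbone['mep_total']} MEP)"
    )
    print(f"OSC verdict: {report['osc']['verdict']}")
    print(
        f"AltSQE: {report['altsqe']['verdict']} "
        f"({report['altsqe']['conserved_count']}/9 histidines)"
    )
    print(f"reachable sterols: {report['routes']['reachable']}")


if __name__ == "__main__":
    main()
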