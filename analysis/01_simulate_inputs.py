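#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes the seed-1 proteome (diverged orthologs for every catalog locus,
with the cycloartenol-type oxidosqualene-cyclase signature and the nine
epoxidase histidines planted, plus shuffled decoys) and the five
experiment scenarios (growth timecourse + four inhibitors) in both
noise-free and realistic-noise (CV 5%, triplicate) form, each paired
with its truth table, under results/inputs/.
"""

from pathlib import Path

from sterolpath.io import write_fasta
from sterolpath.synth import (
    BUNDLED_SCENARIOS,
    ProteomeScenario,
    generate_experiment,
    generate_proteome,
    load_scenario,
)

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    records, truth = generate_proteome(ProteomeScenario(seed=SEED))
    write_fasta(records, OUT / "proteome.fasta")
    truth.to_csv(OUT / "proteome_truth.tsv", sep="\t", index=False)
    n_orth = int((truth.kind == "ortholog").sum())
    print(
        f"proteome: {len(records)} sequences "
        f"({n_orth} planted orthologs, {len(records) - n_orth} decoys)"
    )

    for name in BUNDLED_SCENARIOS:
        for label, cv in (("noisefree", 0.0), ("noisy", 0.05)):
            scenario = load_scenario(name, seed=SEED, noise_cv=cv)
            meas, qpcr, truth_df = generate_experiment(scenario)
            meas.to_csv(OUT / f"{name}_{label}_measurements.tsv", sep="\t", index=False)
            if not qpcr.empty:
                qpcr.to_csv(OUT / f"{name}_{label}_qpcr.tsv", sep="\t", index=False)
            truth_df.to_csv(OUT / f"{name}_{label}_truth.tsv", sep="\t", index=False)
        print(f"scenario {name}: {len(meas)} measurement rows, {len(qpcr)} Ct rows")


if __name__ == "__main__":
    main()
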