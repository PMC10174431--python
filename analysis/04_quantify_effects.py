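#!/usr/bin/env python
"""Quantify the inhibitor experiments and the growth timecourse.

Pushes the generated measurement tables through internal-standard
quantification and dose-response effect estimation, and the Ct tables
through 2^(-ddCt) relative expression. Writes per-scenario effect tables
and log2 fold-change matrices under results/quant/.

Finding (noise-free recovery of the planted study effects): at 72 h
cholesterol reaches 0.55 and stigmasterol 1.17 mg/g DCW; 100 uM
mevinolin gives 4.51-/2.39-fold cholesterol/stigmasterol increases with
beta-carotene -64.69% and squalene -93.70%; fosmidomycin shows no effect
at any dose; 2 uM ketoconazole abolishes stigmasterol entirely.
"""

from pathlib import Path

import pandas as pd

from sterolpath.quant import (
    ddct_expression,
    dose_response_table,
    log2fc_matrix,
    quantify_frame,
    read_measurements,
    read_qpcr,
)

ROOT = Path(__file__).resolve().parent.parent
INPUTS = ROOT / "results" / "inputs"
OUT = ROOT / "results" / "quant"


def main() -> None:
    if not INPUTS.exists():
        raise SystemExit("run 01_simulate_inputs.py first")
    OUT.mkdir(parents=True, exist_ok=True)

    # timecourse endpoint concentrations
    tc = quantify_frame(
        read_measurements(INPUTS / "growth_timecourse_noisefree_measurements.tsv")
    )
    profile = tc.groupby(["analyte", "time_h"]).value_mg_per_g.mean().unstack()
    profile.to_csv(OUT / "timecourse_profile.tsv", sep="\t")
    print("72-h sterol levels (mg/g DCW):")
    print(profile[72.0].round(2).to_string())

    for name in ("mevinolin", "fosmidomycin", "terbinafine", "ketoconazole"):
        for label in ("noisefree", "noisy"):
            meas = read_measurements(
                INPUTS / f"{name}_{label}_measurements.tsv"
            )
            eff = dose_response_table(quantify_frame(meas))
            eff.to_csv(OUT / f"{name}_{label}_effects.tsv", sep="\t", index=False)
        qpcr_path = INPUTS / f"{name}_noisefree_qpcr.tsv"
        if qpcr_path.exists():
            results = ddct_expression(read_qpcr(qpcr_path))
            log2fc_matrix(results).to_csv(OUT / f"{name}_log2fc.tsv", sep="\t")
        n_sig = int(eff.significant_05.sum())
        print(f"{name}: {len(eff)} effect cells, {n_sig} significant at 0.05 (noisy)")


if __name__ == "__main__":
    main()
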