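"""Measurement-layer computations for the chemical-biology experiments.

* single-point internal-standard quantification to mg per g dry cell
  weight (DCW): value = (peak_signal / is_signal) × is_amount_mg / dcw_g;
* treated-vs-control effect estimates as fold change (treated/control) and
  signed percent change, with paired two-sided Student's t-tests on
  replicate-matched values;
* dose–response tables across inhibitor concentrations, with monotonicity
  annotations;
* classic ΔΔCt relative expression: rel_expr = 2^(−ΔΔCt), log2 fold change
  = −ΔΔCt (amplification efficiency fixed at 2).

Fold convention: "X-fold increase over the control" is the plain ratio
treated/control = X, so percent_change = (fold − 1) × 100 throughout (a
4.51-fold increase is +351%); a "decrease of Y%" is percent_change = −Y.
Values below the limit of detection (default 0.01 mg/g) are reported as
detected=False with value 0 and excluded from fold denominators with an
explicit flag rather than propagated as 0/0.

No multiple-testing correction is applied; each contrast is tested on its
own, which is documented as a limitation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_LOD = 0.01  # mg/g DCW
NOT_APPLICABLE = "NOT_APPLICABLE"

MEASUREMENT_COLUMNS = [
    "sample_id", "inhibitor", "conc_uM", "time_h", "analyte",
    "peak_signal", "is_signal", "is_amount_mg", "dcw_g", "replicate",
]
QPCR_COLUMNS = [
    "gene", "ref_gene", "inhibitor", "conc_uM", "time_h",
    "ct_target", "ct_ref", "replicate",
]


class QuantError(ValueError):
    pass


@dataclass(frozen=True)
class MeasurementRecord:
    sample_id: str
    inhibitor: str  # "none" for untreated
    conc_uM: float
    time_h: float
    analyte: str
    peak_signal: float
    is_signal: float
    is_amount_mg: float
    dcw_g: float
    replicate: int

    def __post_init__(self):
        if self.peak_signal < 0:
            raise QuantError(f"{self.sample_id}: negative peak signal")
        if self.is_signal <= 0:
            raise QuantError(f"{self.sample_id}: internal-standard signal must be > 0")
        if self.dcw_g <= 0:
            raise QuantError(f"{self.sample_id}: dry cell weight must be > 0")


@dataclass
class QuantValue:
    analyte: str
    inhibitor: str
    conc_uM: float
    time_h: float
    value_mg_per_g: float
    detected: bool
    n: int = 1
    mean: float | None = None
    sd: float | None = None


@dataclass
class EffectEstimate:
    analyte: str
    treated: tuple[str, float]  # (inhibitor, conc_uM)
    control: tuple[str, float]
    fold_change: float | None
    percent_change: float | str  # signed % or NOT_APPLICABLE
    t_stat: float | None = None
    df: int | None = None
    p_value: float | None = None
    significant_05: bool = False
    significant_01: bool = False
    degenerate: bool = False
    control_below_lod: bool = False


@dataclass
class ExpressionResult:
    gene: str
    inhibitor: str
    conc_uM: float
    time_h: float
    ddct: float
    rel_expr: float
    log2_fc: float
    n: int
    t_stat: float | None = None
    p_value: float | None = None


def quantify(record: MeasurementRecord, lod: float = DEFAULT_LOD) -> QuantValue:
    """Internal-standard ratio quantification of one measurement."""
    value = (record.peak_signal / record.is_signal) * record.is_amount_mg / record.dcw_g
    detected = value >= lod
    return QuantValue(
        analyte=record.analyte,
        inhibitor=record.inhibitor,
        conc_uM=record.conc_uM,
        time_h=record.time_h,
        value_mg_per_g=value if detected else 0.0,
        detected=detected,
    )


def paired_t(x: Sequence[float], y: Sequence[float]):
    """Two-sided paired Student's t-test.

    Returns (t, df, p, degenerate). With zero variance of the differences
    the test statistic is undefined: p = 1 when all differences are 0,
    otherwise the 0-limit (p = 0) is returned, both flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise QuantError("paired vectors must have equal length")
    n = len(x)
    if n < 2:
        raise QuantError("paired t-test requires n >= 2")
    d = x - y
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0):
            return 0.0, df, 1.0, True
        return math.copysign(math.inf, d.mean()), df, 0.0, True
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p, False


def effect_estimate(
    treated: Sequence[QuantValue],
    control: Sequence[QuantValue],
    paired: bool = True,
) -> EffectEstimate:
    """Fold / percent change of treated over control replicate sets."""
    if not treated or not control:
        raise QuantError("need at least one replicate per arm")
    tv = np.array([q.value_mg_per_g for q in treated])
    cv = np.array([q.value_mg_per_g for q in control])
    t_mean, c_mean = tv.mean(), cv.mean()
    control_below_lod = not any(q.detected for q in control)

    if control_below_lod or c_mean == 0:
        fold: float | None = None
        percent: float | str = NOT_APPLICABLE
    else:
        fold = t_mean / c_mean
        percent = (fold - 1.0) * 100.0

    t_stat = df = p = None
    sig05 = sig01 = False
    degenerate = False
    if len(tv) >= 2 and len(cv) == len(tv) and paired:
        t_stat, df, p, degenerate = paired_t(tv, cv)
        sig05 = (p is not None) and p < 0.05 and not degenerate
        sig01 = (p is not None) and p < 0.01 and not degenerate

    first = treated[0]
    ctrl = control[0]
    return EffectEstimate(
        analyte=first.analyte,
        treated=(first.inhibitor, first.conc_uM),
        control=(ctrl.inhibitor, ctrl.conc_uM),
        fold_change=fold,
        percent_change=percent,
        t_stat=t_stat,
        df=df,
        p_value=p,
        significant_05=sig05,
        significant_01=sig01,
        degenerate=degenerate,
        control_below_lod=control_below_lod,
    )


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a measurement TSV (schema in MEASUREMENT_COLUMNS)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise QuantError(f"{path}: missing columns {missing}")
    for i, row in df.iterrows():
        if row["dcw_g"] <= 0:
            raise QuantError(f"{path} row {i + 2}: dry cell weight must be > 0")
        if row["is_signal"] <= 0:
            raise QuantError(f"{path} row {i + 2}: internal-standard signal must be > 0")
        if row["peak_signal"] < 0:
            raise QuantError(f"{path} row {i + 2}: negative peak signal")
    return df


def quantify_frame(df: pd.DataFrame, lod: float = DEFAULT_LOD) -> pd.DataFrame:
    """Vectorised :func:`quantify` over a measurement table."""
    out = df.copy()
    value = (out["peak_signal"] / out["is_signal"]) * out["is_amount_mg"] / out["dcw_g"]
    out["value_mg_per_g"] = np.where(value >= lod, value, 0.0)
    out["detected"] = value >= lod
    return out


def _quant_values(group: pd.DataFrame) -> list[QuantValue]:
    return [
        QuantValue(
            analyte=r["analyte"],
            inhibitor=r["inhibitor"],
            conc_uM=r["conc_uM"],
            time_h=r["time_h"],
            value_mg_per_g=r["value_mg_per_g"],
            detected=bool(r["detected"]),
        )
        for _, r in group.sort_values("replicate").iterrows()
    ]


def _monotonicity(values: list[float]) -> str:
    if len(values) < 2:
        return "single"
    diffs = np.diff(values)
    if np.all(diffs <= 0) and np.any(diffs < 0):
        return "decreasing"
    if np.all(diffs >= 0) and np.any(diffs > 0):
        return "increasing"
    if np.all(diffs == 0):
        return "flat"
    return "non-monotone"


def dose_response_table(
    quantified: pd.DataFrame,
    analytes: Sequence[str] | None = None,
    time_h: float | None = None,
) -> pd.DataFrame:
    """Per-(analyte, concentration) effect estimates against the 0 µM arm.

    ``quantified`` is the output of :func:`quantify_frame` for a single
    inhibitor series. Adds a ``trend`` column annotating monotonicity of
    the mean response across the nonzero concentrations.
    """
    df = quantified
    if time_h is not None:
        df = df[df["time_h"] == time_h]
    if analytes is not None:
        df = df[df["analyte"].isin(analytes)]
    if not (df["conc_uM"] == 0).any():
        raise QuantError("missing 0 uM control arm")

    rows = []
    for analyte, sub in df.groupby("analyte", sort=False):
        control = _quant_values(sub[sub["conc_uM"] == 0])
        concs = sorted(c for c in sub["conc_uM"].unique() if c > 0)
        means = []
        for conc in concs:
            treated = _quant_values(sub[sub["conc_uM"] == conc])
            est = effect_estimate(treated, control)
            means.append(np.mean([q.value_mg_per_g for q in treated]))
            rows.append(
                {
                    "analyte": analyte,
                    "conc_uM": conc,
                    "fold_change": est.fold_change,
                    "percent_change": est.percent_change,
                    "t_stat": est.t_stat,
                    "p_value": est.p_value,
                    "significant_05": est.significant_05,
                    "significant_01": est.significant_01,
                    "control_below_lod": est.control_below_lod,
                    "treated_detected": any(q.detected for q in treated),
                }
            )
        trend = _monotonicity(means)
        for r in rows[-len(concs):]:
            r["trend"] = trend
    return pd.DataFrame(rows)


def read_qpcr(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise QuantError(f"{path}: missing columns {missing}")
    if df["ct_ref"].isna().any():
        bad = int(df.index[df["ct_ref"].isna()][0]) + 2
        raise QuantError(f"{path} row {bad}: missing reference-gene Ct")
    return df


def ddct_expression(
    records: pd.DataFrame,
    control: tuple[str, float] = ("none", 0.0),
) -> list[ExpressionResult]:
    """Livak 2^(−ΔΔCt) relative expression per (gene, condition, time).

    ΔCt = ct_target − ct_ref per replicate; ΔΔCt contrasts the treated
    condition's mean ΔCt with the control condition's at the same time
    point. A paired t-test on replicate ΔCt values accompanies each result
    when replicate counts match.
    """
    df = records.copy()
    df["dct"] = df["ct_target"] - df["ct_ref"]
    ctrl_inh, ctrl_conc = control
    results: list[ExpressionResult] = []
    treated_df = df[(df["inhibitor"] != ctrl_inh) | (df["conc_uM"] != ctrl_conc)]
    for (gene, inhibitor, conc, time_h), sub in treated_df.groupby(
        ["gene", "inhibitor", "conc_uM", "time_h"], sort=False
    ):
        ctrl = df[
            (df["gene"] == gene)
            & (df["inhibitor"] == ctrl_inh)
            & (df["conc_uM"] == ctrl_conc)
            & (df["time_h"] == time_h)
        ]
        if ctrl.empty:
            raise QuantError(
                f"gene {gene}: no control condition at time {time_h} h"
            )
        dct_t = sub.sort_values("replicate")["dct"].to_numpy()
        dct_c = ctrl.sort_values("replicate")["dct"].to_numpy()
        ddct = float(dct_t.mean() - dct_c.mean())
        t_stat = p = None
        if len(dct_t) >= 2 and len(dct_t) == len(dct_c):
            t_stat, _, p, _ = paired_t(dct_t, dct_c)
        results.append(
            ExpressionResult(
                gene=gene,
                inhibitor=inhibitor,
                conc_uM=conc,
                time_h=time_h,
                ddct=ddct,
                rel_expr=2.0 ** (-ddct),
                log2_fc=-ddct,
                n=len(dct_t),
                t_stat=t_stat,
                p_value=p,
            )
        )
    return results


def log2fc_matrix(results: Sequence[ExpressionResult]) -> pd.DataFrame:
    """Genes × timepoints matrix of log2 fold changes (heatmap-ready)."""
    rows = [
        {"gene": r.gene, "time_h": r.time_h, "log2_fc": r.log2_fc}
        for r in results
    ]
    return (
        pd.DataFrame(rows)
        .pivot_table(index="gene", columns="time_h", values="log2_fc")
        .sort_index()
    )
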