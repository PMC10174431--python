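"""Synthetic test-data generators with planted ground truth.

Two generators emulate the two data layers of the study design:

* **proteomes** — one diverged ortholog per catalog locus (substitution
  matrix-biased divergence from a synthetic reference library, with the
  diagnostic oxidosqualene-cyclase residues and the nine motif histidines
  planted as configured), plus decoy sequences carrying no signatures;
* **experiment tables** — triplicate internal-standard measurement rows
  and qPCR Ct rows for a growth timecourse and four inhibitor scenarios,
  with per-(analyte, concentration) effect multipliers planted as ground
  truth and multiplicative Gaussian noise (coefficient-of-variation
  parameter, truncated at zero; zero CV is exact).

Every generated record has exactly one truth row; recovery of the planted
truths through the annotation and quantification layers is what the test
suite measures. All randomness flows through a single integer seed via
:class:`numpy.random.Generator`, so identical scenarios give identical
outputs across platforms.

The bundled reference FASTA is a synthetic stand-in library: sequence
content is simulated (realistic amino-acid composition; homologous
families for activities sharing a locus), not downloaded; only the
coordinate conventions of the real references are reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from sterolpath.align import AMINO_ACIDS, _matrix
from sterolpath.catalog import PathwayCatalog, load_default_catalog

# approximate database amino-acid background frequencies
_AA_FREQ = {
    "A": 0.078, "C": 0.019, "D": 0.054, "E": 0.063, "F": 0.039,
    "G": 0.072, "H": 0.022, "I": 0.052, "K": 0.057, "L": 0.090,
    "M": 0.022, "N": 0.045, "P": 0.052, "Q": 0.043, "R": 0.051,
    "S": 0.071, "T": 0.058, "V": 0.064, "W": 0.013, "Y": 0.032,
}
_AA = np.array(list(_AA_FREQ))
_AA_P = np.array(list(_AA_FREQ.values()))
_AA_P = _AA_P / _AA_P.sum()

#: Diagnostic residues planted at reference positions 381/449/453.
OSC_CLASS_RESIDUES = {
    "cycloartenol": ("Y", "H", "I"),
    "lanosterol": ("T", "C", "V"),
}
OSC_SITES = (381, 449, 453)
ALTSQE_HIS_POSITIONS = (88, 92, 105, 109, 110, 201, 205, 294, 298)

#: Designated reference id per (symbol, ec); the first member of each
#: locus family is the family base.
DESIGNATED_REF = {
    ("ACAT", "2.3.1.9"): "YPL028W",
    ("HMGS", "2.3.3.10"): "YML126C",
    ("HMGR", "1.1.1.34"): "YLR450W",
    ("MK", "2.7.1.36"): "YMR208W",
    ("PMK", "2.7.4.2"): "YMR220W",
    ("MPDC", "4.1.1.33"): "YNR043W",
    ("IPI", "5.3.3.2"): "YPL117C",
    ("GPS", "2.5.1.1"): "YPL069C",
    ("FPS", "2.5.1.1/2.5.1.10"): "YJL167W",
    ("DXS", "2.2.1.7"): "AT3G21500",
    ("DXR", "1.1.1.267"): "AT5G62790",
    ("ISPD", "2.7.7.60"): "AT2G02500",
    ("CDPMEK", "2.7.1.148"): "AT2G26930",
    ("ISPF", "4.6.1.12"): "AT1G63970",
    ("HDS", "1.17.7.1/1.17.7.3"): "AT5G60600",
    ("HDR", "1.17.7.4"): "AT4G34350",
    ("SQS", "2.5.1.21"): "YHR190W",
    ("SQE", "1.14.14.17"): "YGR175C",
    ("LAS", "5.4.99.7"): "hsa:4047",
    ("CAS", "5.4.99.8"): "AT2G07050",
    ("CYP51G1", "1.14.14.154/1.14.15.36"): "YHR007C",
    ("FK", "1.3.1.70"): "YNL280C",
    ("SMO", "1.14.18.9"): "YGR060W",
    ("NSDHL", "1.1.1.170"): "YGL001C",
    ("HSD17B7", "1.1.1.270"): "YLR100W",
    ("SMT", "2.1.1.41"): "YML008C",
    ("STE1", "1.14.19.20"): "YLR056W",
    ("CYP710A", "1.14.19.41"): "YMR015C",
    ("ERG4", "1.3.1.71"): "YGL012W",
    ("DWF1", "1.3.1.72"): "AT3G19820",
    ("HYD1", "5.3.3.5"): "AT1G20050",
    ("DWF5", "1.3.1.21"): "AT1G50430",
    ("SMO", "1.14.18.10"): "AT4G12110",
    ("SMO", "1.14.18.11"): "AT1G07420",
    ("CPI1", "5.5.1.9"): "AT5G50375",
    ("AltSQE", "1.14.19.-"): "PtAltSQE",
}

#: ref_ids forming one homologous family (activities sharing a locus);
#: the first entry is the base, others are derived at ~78% identity.
_REF_FAMILIES = [
    ["hsa:4047", "AT2G07050"],  # the two oxidosqualene cyclases
    ["YNL280C", "YGL012W"],  # the two sterol reductases on one locus
    ["YGR060W", "AT4G12110", "AT1G07420"],  # methylsterol monooxygenases
]
_REF_LENGTHS = {"hsa:4047": 520, "AT2G07050": 520, "PtAltSQE": 430}
_DEFAULT_REF_LEN = 360
_LIBRARY_SEED = 902_059  # fixed: the library is data, not an experiment


class ScenarioError(ValueError):
    pass


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length, p=_AA_P))


def mutate_to_identity(
    ref: str,
    target_identity: float,
    preserved: set[int] | frozenset[int] = frozenset(),
    seed: int | np.random.Generator = 0,
    matrix_name: str = "BLOSUM62",
    uniform: bool = False,
) -> str:
    """Substitute residues until the sequence matches ``target_identity``.

    Substitutions only (no indels), so the result shares the reference's
    coordinate system and the realized identity is exact to rounding:
    (L − k)/L where k = round((1 − target/100)·L). ``preserved`` positions
    (1-based) are never touched. By default replacement residues are drawn
    preferring high off-diagonal substitution-matrix scores, mimicking
    homolog divergence; ``uniform=True`` falls back to uniform draws.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(ref)
    if not (20.0 < target_identity <= 100.0):
        raise ScenarioError(f"target identity {target_identity} outside (20, 100]")
    bad = [p for p in preserved if not (1 <= p <= L)]
    if bad:
        raise ScenarioError(f"preserved positions outside reference: {bad}")
    k = round((1.0 - target_identity / 100.0) * L)
    free = [i for i in range(L) if (i + 1) not in preserved]
    if k > len(free):
        raise ScenarioError(
            f"target identity {target_identity}% unreachable with "
            f"{len(preserved)} preserved positions in length {L}"
        )
    if k == 0:
        return ref
    matrix = _matrix(matrix_name)
    positions = rng.choice(len(free), size=k, replace=False)
    seq = list(ref)
    for idx in positions:
        i = free[idx]
        old = seq[i]
        candidates = [a for a in AMINO_ACIDS if a != old]
        if uniform or old not in AMINO_ACIDS:
            probs = None
        else:
            scores = np.array([matrix[old, a] for a in candidates], dtype=float)
            w = np.exp(scores)  # conservative substitutions preferred
            probs = w / w.sum()
        seq[i] = rng.choice(candidates, p=probs)
    return "".join(seq)


def build_reference_library(seed: int = _LIBRARY_SEED) -> dict[str, str]:
    """Deterministically build the synthetic reference protein library."""
    rng = np.random.default_rng(seed)
    library: dict[str, str] = {}
    family_member = {
        rid: fam[0] for fam in _REF_FAMILIES for rid in fam[1:]
    }
    # generate in a fixed order for determinism
    for ref_id in sorted(set(DESIGNATED_REF.values())):
        if ref_id in family_member:
            continue  # derived below from its family base
        length = _REF_LENGTHS.get(ref_id, _DEFAULT_REF_LEN)
        seq = list(_random_protein(rng, length))
        if ref_id == "hsa:4047":
            # the rule's numbering anchor carries the lanosterol signature
            for pos, res in zip(OSC_SITES, OSC_CLASS_RESIDUES["lanosterol"]):
                seq[pos - 1] = res
        if ref_id == "PtAltSQE":
            for pos in ALTSQE_HIS_POSITIONS:
                seq[pos - 1] = "H"
        library[ref_id] = "".join(seq)
    for fam in _REF_FAMILIES:
        base = library[fam[0]]
        for ref_id in fam[1:]:
            preserved = set(OSC_SITES) if ref_id == "AT2G07050" else set()
            derived = list(
                mutate_to_identity(base, 78.0, preserved=preserved, seed=rng)
            )
            if ref_id == "AT2G07050":
                for pos, res in zip(OSC_SITES, OSC_CLASS_RESIDUES["cycloartenol"]):
                    derived[pos - 1] = res
            library[ref_id] = "".join(derived)
    return library


def load_reference_library() -> dict[str, str]:
    """Load the bundled synthetic reference FASTA."""
    from Bio import SeqIO

    from sterolpath import data_path

    with data_path("reference_proteins.synthetic.fasta").open() as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


# ---------------------------------------------------------------------------
# proteome scenarios


@dataclass
class ProteomeScenario:
    seed: int = 0
    target_identity: float = 65.0  # % identity of each planted ortholog
    per_activity_identity: dict[str, float] = field(default_factory=dict)
    n_decoys: int = 10
    decoy_model: str = "shuffled"  # shuffled | random
    planted_osc_class: str = "cycloartenol"  # cycloartenol | lanosterol
    plant_altsqe: bool = True
    plant_mva: bool = True
    plant_mep: bool = False
    plant_sterol: bool = True

    def __post_init__(self):
        idents = [self.target_identity, *self.per_activity_identity.values()]
        for t in idents:
            if not (20.0 < t <= 100.0):
                raise ScenarioError(f"target identity {t} outside (20, 100]")
        if self.decoy_model not in ("shuffled", "random"):
            raise ScenarioError(f"unknown decoy model {self.decoy_model!r}")
        if self.planted_osc_class not in OSC_CLASS_RESIDUES:
            raise ScenarioError(f"unknown OSC class {self.planted_osc_class!r}")


def _locus_plan(catalog: PathwayCatalog, scenario: ProteomeScenario):
    """(locus, designated ref_id, symbols) for every locus to plant."""
    plan: dict[str, tuple[str, list[str]]] = {}
    for act in catalog.activities:
        if not act.present:
            continue
        section_on = {
            "terpenoid_backbone_MVA": scenario.plant_mva,
            "terpenoid_backbone_MEP": scenario.plant_mep,
            "sterol": scenario.plant_sterol,
        }[act.section]
        if not section_on:
            continue
        if act.symbol == "AltSQE" and not scenario.plant_altsqe:
            continue
        ref_id = DESIGNATED_REF[(act.symbol, act.ec)]
        if act.assigned_gene not in plan:
            plan[act.assigned_gene] = (ref_id, [act.symbol])
        else:
            symbols = plan[act.assigned_gene][1]
            if act.symbol not in symbols:
                symbols.append(act.symbol)
    return plan


def generate_proteome(
    scenario: ProteomeScenario,
    catalog: PathwayCatalog | None = None,
    references: dict[str, str] | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate (FASTA records, truth table) for a proteome scenario.

    One diverged ortholog is planted per catalog locus of the enabled
    sections; the oxidosqualene-cyclase locus carries the configured class
    residues and the alternative squalene epoxidase carries (or not) the
    nine motif histidines. Decoys are per-sequence shuffles of references
    (or fresh random-composition sequences) and carry no signatures.
    """
    catalog = catalog or load_default_catalog()
    references = references or load_reference_library()
    rng = np.random.default_rng(scenario.seed)
    records: list[tuple[str, str]] = []
    truth_rows = []

    for locus, (ref_id, symbols) in sorted(_locus_plan(catalog, scenario).items()):
        ref = references[ref_id]
        preserved: set[int] = set()
        planted_class = ""
        altsqe_state = ""
        base = list(ref)
        if ref_id in ("hsa:4047", "AT2G07050"):
            planted_class = scenario.planted_osc_class
            for pos, res in zip(OSC_SITES, OSC_CLASS_RESIDUES[planted_class]):
                base[pos - 1] = res
            preserved |= set(OSC_SITES)
        if ref_id == "PtAltSQE":
            altsqe_state = "present"
            preserved |= set(ALTSQE_HIS_POSITIONS)
        target = scenario.per_activity_identity.get(
            symbols[0], scenario.target_identity
        )
        seq = mutate_to_identity("".join(base), target, preserved, seed=rng)
        realized = 100.0 * sum(a == b for a, b in zip(seq, ref)) / len(ref)
        records.append((locus, seq))
        truth_rows.append(
            {
                "sequence_id": locus,
                "kind": "ortholog",
                "activity_symbols": ";".join(symbols),
                "reference_id": ref_id,
                "target_identity": target,
                "realized_identity": round(realized, 2),
                "planted_osc_class": planted_class,
                "planted_altsqe": altsqe_state,
            }
        )

    ref_ids = sorted(set(DESIGNATED_REF.values()))
    for i in range(scenario.n_decoys):
        if scenario.decoy_model == "shuffled":
            src = references[ref_ids[int(rng.integers(len(ref_ids)))]]
            seq = "".join(rng.permutation(list(src)))
        else:
            seq = _random_protein(rng, int(rng.integers(250, 450)))
        decoy_id = f"decoy_{i + 1:03d}"
        records.append((decoy_id, seq))
        truth_rows.append(
            {
                "sequence_id": decoy_id,
                "kind": "decoy",
                "activity_symbols": "",
                "reference_id": "",
                "target_identity": np.nan,
                "realized_identity": np.nan,
                "planted_osc_class": "",
                "planted_altsqe": "",
            }
        )
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# experiment scenarios


@dataclass
class ExperimentScenario:
    name: str
    inhibitor: str  # "none" for the untreated timecourse
    times_h: list[float]
    concentrations: list[float]  # nonzero arms; a 0 control arm is implied
    baselines: dict[str, dict[float, float]]  # analyte -> time -> mg/g
    multipliers: dict[str, dict[float, float]]  # analyte -> conc -> fold
    qpcr_conc_uM: float | None = None
    qpcr_times_h: list[float] = field(default_factory=list)
    qpcr_log2fc: dict[str, dict[float, float]] = field(default_factory=dict)
    qpcr_ref_gene: str = "actin"
    noise_cv: float = 0.05
    ct_sd: float = 0.05
    n_replicates: int = 3
    seed: int = 0
    dcw_g: float = 0.1
    is_amount_mg: float = 1.0
    is_signal: float = 1000.0

    def __post_init__(self):
        for analyte, by_time in self.baselines.items():
            if any(v <= 0 for v in by_time.values()):
                raise ScenarioError(f"{analyte}: baselines must be > 0")
        for analyte, by_conc in self.multipliers.items():
            if any(m < 0 for m in by_conc.values()):
                raise ScenarioError(f"{analyte}: multipliers must be >= 0")
        if self.n_replicates < 1:
            raise ScenarioError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ScenarioError("noise CV must be >= 0")


def load_scenario(
    name_or_path: str | Path,
    seed: int = 0,
    noise_cv: float | None = None,
    n_replicates: int | None = None,
) -> ExperimentScenario:
    """Load a bundled scenario by name, or any scenario YAML by path."""
    path = Path(name_or_path)
    if not path.exists():
        from sterolpath import data_path

        path = Path(str(data_path("scenarios", f"{name_or_path}.yaml")))
    doc = yaml.safe_load(path.read_text())

    def _fkeys(d):
        return {float(k): float(v) for k, v in d.items()}

    kwargs = dict(
        name=doc["name"],
        inhibitor=doc["inhibitor"],
        times_h=[float(t) for t in doc["times_h"]],
        concentrations=[float(c) for c in doc.get("concentrations", [])],
        baselines={a: _fkeys(d) for a, d in doc["baselines"].items()},
        multipliers={a: _fkeys(d) for a, d in doc.get("multipliers", {}).items()},
        qpcr_conc_uM=doc.get("qpcr_conc_uM"),
        qpcr_times_h=[float(t) for t in doc.get("qpcr_times_h", [])],
        qpcr_log2fc={g: _fkeys(d) for g, d in doc.get("qpcr_log2fc", {}).items()},
        seed=seed,
    )
    if "noise_cv" in doc:
        kwargs["noise_cv"] = float(doc["noise_cv"])
    if noise_cv is not None:
        kwargs["noise_cv"] = noise_cv
    if n_replicates is not None:
        kwargs["n_replicates"] = n_replicates
    return ExperimentScenario(**kwargs)


def _baseline_at(scenario: ExperimentScenario, analyte: str, time_h: float) -> float:
    by_time = scenario.baselines[analyte]
    if time_h in by_time:
        return by_time[time_h]
    if len(by_time) == 1:
        return next(iter(by_time.values()))
    raise ScenarioError(f"{analyte}: no baseline at {time_h} h")


def _noisy(rng: np.random.Generator, value: float, cv: float) -> float:
    if cv == 0 or value == 0:
        return value
    return max(0.0, value * (1.0 + cv * rng.standard_normal()))


def generate_experiment(
    scenario: ExperimentScenario,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (measurement table, qPCR table, truth table).

    Treated replicate values are baseline × multiplier × (1 + noise); the
    0 µM control arm is always included. Peak signals are derived so the
    internal-standard ratio recovers the planted mg/g value exactly in
    noise-free mode.
    """
    rng = np.random.default_rng(scenario.seed)
    meas_rows, truth_rows = [], []
    concs = [0.0] + [c for c in scenario.concentrations if c != 0]
    sample = 0
    for analyte in scenario.baselines:
        by_conc = scenario.multipliers.get(analyte, {})
        for time_h in scenario.times_h:
            baseline = _baseline_at(scenario, analyte, time_h)
            for conc in concs:
                if conc == 0.0:
                    mult = 1.0
                elif conc in by_conc:
                    mult = by_conc[conc]
                else:
                    continue  # no planted effect for this arm
                true_value = baseline * mult
                truth_rows.append(
                    {
                        "analyte": analyte,
                        "inhibitor": scenario.inhibitor if conc else "none",
                        "conc_uM": conc,
                        "time_h": time_h,
                        "true_value_mg_per_g": true_value,
                        "true_fold": mult,
                    }
                )
                for rep in range(1, scenario.n_replicates + 1):
                    sample += 1
                    value = _noisy(rng, true_value, scenario.noise_cv)
                    peak = (
                        value
                        * scenario.dcw_g
                        / scenario.is_amount_mg
                        * scenario.is_signal
                    )
                    meas_rows.append(
                        {
                            "sample_id": f"{scenario.name}_{sample:04d}",
                            "inhibitor": scenario.inhibitor if conc else "none",
                            "conc_uM": conc,
                            "time_h": time_h,
                            "analyte": analyte,
                            "peak_signal": peak,
                            "is_signal": scenario.is_signal,
                            "is_amount_mg": scenario.is_amount_mg,
                            "dcw_g": scenario.dcw_g,
                            "replicate": rep,
                        }
                    )

    qpcr_rows = []
    base_dct = 6.0  # control-condition Ct gap target - reference
    for gene, by_time in scenario.qpcr_log2fc.items():
        for time_h, log2fc in by_time.items():
            truth_rows.append(
                {
                    "analyte": f"transcript:{gene}",
                    "inhibitor": scenario.inhibitor,
                    "conc_uM": scenario.qpcr_conc_uM,
                    "time_h": time_h,
                    "true_value_mg_per_g": np.nan,
                    "true_fold": 2.0 ** log2fc,
                }
            )
            for condition, dct in (
                ("none", base_dct),
                (scenario.inhibitor, base_dct - log2fc),
            ):
                for rep in range(1, scenario.n_replicates + 1):
                    ct_ref = 16.0 + (
                        scenario.ct_sd * rng.standard_normal()
                        if scenario.noise_cv > 0
                        else 0.0
                    )
                    ct_target = ct_ref + dct + (
                        scenario.ct_sd * rng.standard_normal()
                        if scenario.noise_cv > 0
                        else 0.0
                    )
                    qpcr_rows.append(
                        {
                            "gene": gene,
                            "ref_gene": scenario.qpcr_ref_gene,
                            "inhibitor": condition,
                            "conc_uM": scenario.qpcr_conc_uM if condition != "none" else 0.0,
                            "time_h": time_h,
                            "ct_target": ct_target,
                            "ct_ref": ct_ref,
                            "replicate": rep,
                        }
                    )
    return (
        pd.DataFrame(meas_rows),
        pd.DataFrame(qpcr_rows),
        pd.DataFrame(truth_rows),
    )


BUNDLED_SCENARIOS = (
    "growth_timecourse",
    "mevinolin",
    "fosmidomycin",
    "terbinafine",
    "ketoconazole",
)
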