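"""Enzyme-activity inventory and sterol reaction graph.

The catalog holds one :class:`EnzymeActivity` per distinct (symbol, EC)
pair, each carrying the locus assigned in the studied genome (or ABSENT)
and its reference orthologs in yeast / Arabidopsis / human, and a set of
:class:`ReactionEdge` rows encoding the postulated reaction scheme from
acetyl-CoA through farnesyl pyrophosphate to cholesterol and stigmasterol.

File formats (tab-separated, one header line):

* activity table — ``section  symbol  name  ec  assigned_gene  ref_species
  ref_id  identity_pct  evalue  supplemental``, one row per (activity,
  reference ortholog); empty strings for missing values.
* edge table — ``substrate  product  symbol``.

``supplemental`` marks activities discovered by a dedicated homology
search rather than the primary genome inventory (the alternative squalene
epoxidase); they are excluded from inventory counts but participate in the
reaction graph.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

ABSENT = "ABSENT"
SECTIONS = ("terpenoid_backbone_MVA", "terpenoid_backbone_MEP", "sterol")

_EC_PART = re.compile(r"^\d+\.\d+\.\d+\.(\d+|-)$")


def _ec_ok(ec: str) -> bool:
    # composite ECs for bifunctional enzymes are slash-joined
    return bool(ec) and all(_EC_PART.match(part) for part in ec.split("/"))


@dataclass(frozen=True)
class ReferenceOrtholog:
    species: str
    ref_id: str
    sequence: str | None = None
    reported_identity_pct: float | None = None
    reported_evalue: float | None = None


@dataclass
class EnzymeActivity:
    symbol: str
    name: str
    ec: str
    section: str
    assigned_gene: str  # locus identifier or ABSENT
    reference_orthologs: list[ReferenceOrtholog] = field(default_factory=list)
    supplemental: bool = False

    @property
    def key(self) -> tuple[str, str]:
        return (self.symbol, self.ec)

    @property
    def present(self) -> bool:
        return self.assigned_gene != ABSENT


@dataclass(frozen=True)
class ReactionEdge:
    substrate: str
    product: str
    activity_symbol: str


@dataclass
class PathwayCatalog:
    activities: list[EnzymeActivity]
    edges: list[ReactionEdge]

    @property
    def metabolites(self) -> set[str]:
        out: set[str] = set()
        for e in self.edges:
            out.add(e.substrate)
            out.add(e.product)
        return out

    @property
    def symbols(self) -> set[str]:
        return {a.symbol for a in self.activities}

    def activity(self, symbol: str, ec: str | None = None) -> EnzymeActivity:
        hits = [
            a
            for a in self.activities
            if a.symbol == symbol and (ec is None or a.ec == ec)
        ]
        if not hits:
            raise KeyError(f"no activity {symbol!r} in catalog")
        return hits[0]

    def section_activities(self, section: str) -> list[EnzymeActivity]:
        return [a for a in self.activities if a.section == section]

    def section_counts(self) -> dict[str, int]:
        """Distinct (symbol, EC) entries per section, all activities."""
        out = {s: 0 for s in SECTIONS}
        for a in self.activities:
            out[a.section] += 1
        return out

    def inventory_count(self, section: str) -> int:
        """Distinct (symbol, EC) entries of the primary genome inventory
        (supplemental activities excluded)."""
        return sum(
            1
            for a in self.activities
            if a.section == section and not a.supplemental
        )

    def graph(self, present_symbols: Iterable[str] | None = None) -> nx.DiGraph:
        """Reaction graph; optionally restricted to edges whose catalyzing
        activity symbol is in ``present_symbols``."""
        keep = None if present_symbols is None else set(present_symbols)
        g = nx.DiGraph()
        g.add_nodes_from(self.metabolites)
        for e in self.edges:
            if keep is None or e.activity_symbol in keep:
                g.add_edge(e.substrate, e.product, activity=e.activity_symbol)
        return g


class CatalogError(ValueError):
    """Raised when a catalog file fails to load or validate."""


def validate_catalog(catalog: PathwayCatalog) -> list[str]:
    """Return a list of invariant violations (empty iff valid)."""
    violations: list[str] = []
    if not catalog.activities:
        violations.append("catalog has no activities")
    seen: set[tuple[str, str]] = set()
    for a in catalog.activities:
        if not _ec_ok(a.ec):
            violations.append(f"activity {a.symbol}: malformed EC {a.ec!r}")
        if a.section not in SECTIONS:
            violations.append(f"activity {a.symbol}: unknown section {a.section!r}")
        if a.key in seen:
            violations.append(f"duplicate activity entry ({a.symbol}, {a.ec})")
        seen.add(a.key)
        for ref in a.reference_orthologs:
            ident = ref.reported_identity_pct
            if ident is not None and not (0.0 <= ident <= 100.0):
                violations.append(
                    f"activity {a.symbol}: reference {ref.ref_id} identity "
                    f"{ident} outside [0, 100]"
                )
            if ref.reported_evalue is not None and ref.reported_evalue < 0:
                violations.append(
                    f"activity {a.symbol}: reference {ref.ref_id} negative E-value"
                )
    symbols = catalog.symbols
    for e in catalog.edges:
        if e.activity_symbol not in symbols:
            violations.append(
                f"edge {e.substrate} -> {e.product}: unknown activity "
                f"symbol {e.activity_symbol!r}"
            )
        if e.substrate == e.product:
            violations.append(f"edge {e.substrate} -> {e.product}: self-loop")
    return violations


def _parse_float(cell: str, what: str, row: int) -> float | None:
    cell = cell.strip()
    if cell in ("", "-", "NA"):
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise CatalogError(f"row {row}: bad {what} {cell!r}") from exc


_ACT_COLUMNS = [
    "section",
    "symbol",
    "name",
    "ec",
    "assigned_gene",
    "ref_species",
    "ref_id",
    "identity_pct",
    "evalue",
    "supplemental",
]


def load_catalog(
    activities_path: str | Path,
    edges_path: str | Path | None = None,
) -> PathwayCatalog:
    """Load and validate a catalog from its TSV files.

    Raises :class:`CatalogError` naming the offending row on malformed EC,
    duplicate (symbol, EC) conflict, dangling edge, or empty activity list.
    """
    activities_path = Path(activities_path)
    by_key: dict[tuple[str, str], EnzymeActivity] = {}
    with open(activities_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ACT_COLUMNS:
            raise CatalogError(
                f"{activities_path}: unexpected header {header!r}"
            )
        for i, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(_ACT_COLUMNS):
                raise CatalogError(
                    f"{activities_path} row {i}: expected "
                    f"{len(_ACT_COLUMNS)} columns, got {len(cells)}"
                )
            row = dict(zip(_ACT_COLUMNS, cells))
            if not _ec_ok(row["ec"]):
                raise CatalogError(
                    f"{activities_path} row {i}: malformed EC {row['ec']!r}"
                )
            key = (row["symbol"], row["ec"])
            supplemental = row["supplemental"].strip() in ("1", "yes", "true")
            act = by_key.get(key)
            if act is None:
                act = EnzymeActivity(
                    symbol=row["symbol"],
                    name=row["name"],
                    ec=row["ec"],
                    section=row["section"],
                    assigned_gene=row["assigned_gene"] or ABSENT,
                    supplemental=supplemental,
                )
                by_key[key] = act
            else:
                # extra reference-ortholog row for an existing activity:
                # the activity-level cells must agree
                if (
                    act.section != row["section"]
                    or act.name != row["name"]
                    or act.assigned_gene != (row["assigned_gene"] or ABSENT)
                ):
                    raise CatalogError(
                        f"{activities_path} row {i}: duplicate entry "
                        f"({key[0]}, {key[1]}) with conflicting fields"
                    )
            if row["ref_id"].strip() not in ("", "-"):
                act.reference_orthologs.append(
                    ReferenceOrtholog(
                        species=row["ref_species"],
                        ref_id=row["ref_id"],
                        reported_identity_pct=_parse_float(
                            row["identity_pct"], "identity", i
                        ),
                        reported_evalue=_parse_float(row["evalue"], "E-value", i),
                    )
                )
    if not by_key:
        raise CatalogError(f"{activities_path}: empty activity list")

    edges: list[ReactionEdge] = []
    if edges_path is not None:
        with open(edges_path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["substrate", "product", "symbol"]:
                raise CatalogError(f"{edges_path}: unexpected header {header!r}")
            for i, line in enumerate(fh, start=2):
                if not line.strip() or line.startswith("#"):
                    continue
                cells = line.rstrip("\n").split("\t")
                if len(cells) != 3:
                    raise CatalogError(f"{edges_path} row {i}: expected 3 columns")
                edges.append(ReactionEdge(*cells))

    catalog = PathwayCatalog(activities=list(by_key.values()), edges=edges)
    violations = validate_catalog(catalog)
    if violations:
        raise CatalogError("; ".join(violations))
    return catalog


def write_catalog(
    catalog: PathwayCatalog,
    activities_path: str | Path,
    edges_path: str | Path | None = None,
) -> None:
    """Write a catalog back to the TSV schemas read by :func:`load_catalog`."""

    def fmt(x: float | None) -> str:
        return "" if x is None else repr(x)

    with open(activities_path, "w") as fh:
        fh.write("\t".join(_ACT_COLUMNS) + "\n")
        for a in catalog.activities:
            refs = a.reference_orthologs or [ReferenceOrtholog("", "")]
            for ref in refs:
                fh.write(
                    "\t".join(
                        [
                            a.section,
                            a.symbol,
                            a.name,
                            a.ec,
                            a.assigned_gene,
                            ref.species,
                            ref.ref_id,
                            fmt(ref.reported_identity_pct),
                            fmt(ref.reported_evalue),
                            "1" if a.supplemental else "0",
                        ]
                    )
                    + "\n"
                )
    if edges_path is not None:
        with open(edges_path, "w") as fh:
            fh.write("substrate\tproduct\tsymbol\n")
            for e in catalog.edges:
                fh.write(f"{e.substrate}\t{e.product}\t{e.activity_symbol}\n")


def load_default_catalog() -> PathwayCatalog:
    """Load the bundled catalog (activity inventory + reaction graph)."""
    from sterolpath import data_path

    return load_catalog(data_path("catalog.tsv"), data_path("edges.tsv"))
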