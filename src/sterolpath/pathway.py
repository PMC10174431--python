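"""Pathway-level inference: backbone verdict, routes, in-silico knockouts.

Presence/absence calls for the catalog activities are lifted to three
conclusions: which isoprenoid backbone route (mevalonate vs plastidial
methylerythritol-phosphate) supplies IPP/DMAPP, which end sterols are
reachable through the reaction graph, and what breaks when an activity is
removed — the computational analogue of the specific enzyme inhibitors
(mevinolin → HMGR, terbinafine → squalene epoxidase, ketoconazole →
CYP51G1).

Reachability is plain directed-graph search from a source metabolite
(acetyl-CoA by default) over edges whose catalyzing activity is called
present; the alternative squalene epoxidase substitutes for the absent
conventional one when its detection verdict is ``present``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from sterolpath.annotate import OrthologCall
from sterolpath.catalog import PathwayCatalog

MVA_SYMBOLS = ("ACAT", "HMGS", "HMGR", "MK", "PMK", "MPDC", "IPI", "GPS", "FPS")
MEP_SYMBOLS = ("DXS", "DXR", "ISPD", "CDPMEK", "ISPF", "HDS", "HDR")

SOURCE_METABOLITE = "acetyl-CoA"
DEFAULT_TARGETS = ("cholesterol", "stigmasterol")


class PathwayError(ValueError):
    pass


@dataclass
class BackboneVerdict:
    mva_found: list[str]
    mva_total: int
    mep_found: list[str]
    mep_total: int
    verdict: str  # MVA_only | MEP_only | both | neither | incomplete


@dataclass
class RouteReport:
    source: str
    present_symbols: set[str]
    reachable: dict[str, bool]  # target metabolite -> reachable
    paths: dict[str, list[str]]  # target -> ordered activity symbols
    blocking: dict[str, list[str]]  # unreachable target -> missing symbols
    terminal_metabolites: list[str]  # reachable dead ends


@dataclass
class KnockoutResult:
    knocked: list[str]
    before: RouteReport
    after: RouteReport
    newly_unreachable: list[str] = field(default_factory=list)


def found_symbols(calls: Iterable[OrthologCall]) -> set[str]:
    return {c.activity_symbol for c in calls if c.status == "found"}


def infer_backbone(
    calls: Sequence[OrthologCall], catalog: PathwayCatalog
) -> BackboneVerdict:
    """MVA-vs-MEP verdict from per-activity presence calls.

    The verdict is ``MVA_only`` iff every MVA activity is found and no MEP
    activity is (symmetrically ``MEP_only``); full presence of both sets is
    ``both``, full absence ``neither``, anything else ``incomplete``.
    """
    called = {c.activity_symbol for c in calls}
    missing = [
        s for s in (*MVA_SYMBOLS, *MEP_SYMBOLS)
        if s in catalog.symbols and s not in called
    ]
    if missing:
        raise PathwayError(f"no calls for backbone activities: {', '.join(missing)}")
    present = found_symbols(calls)
    mva_found = sorted(present & set(MVA_SYMBOLS))
    mep_found = sorted(present & set(MEP_SYMBOLS))
    mva_all = len(mva_found) == len(MVA_SYMBOLS)
    mep_all = len(mep_found) == len(MEP_SYMBOLS)
    if mva_all and not mep_found:
        verdict = "MVA_only"
    elif mep_all and not mva_found:
        verdict = "MEP_only"
    elif mva_all and mep_all:
        verdict = "both"
    elif not mva_found and not mep_found:
        verdict = "neither"
    else:
        verdict = "incomplete"
    return BackboneVerdict(
        mva_found=mva_found,
        mva_total=len(MVA_SYMBOLS),
        mep_found=mep_found,
        mep_total=len(MEP_SYMBOLS),
        verdict=verdict,
    )


def _route_report(
    catalog: PathwayCatalog,
    present: set[str],
    targets: Sequence[str],
    source: str,
) -> RouteReport:
    all_metabolites = catalog.metabolites
    for t in targets:
        if t not in all_metabolites:
            raise PathwayError(f"unknown target metabolite {t!r}")
    if source not in all_metabolites:
        raise PathwayError(f"unknown source metabolite {source!r}")

    g = catalog.graph(present)
    full = catalog.graph()  # all activities, for blocking analysis
    reachable_set = {source} | nx.descendants(g, source)

    reachable, paths, blocking = {}, {}, {}
    for t in targets:
        ok = t in reachable_set
        reachable[t] = ok
        if ok:
            node_path = nx.shortest_path(g, source, t)
            paths[t] = [
                g.edges[u, v]["activity"]
                for u, v in zip(node_path, node_path[1:])
            ]
        else:
            # every full-graph path must traverse >= 1 absent activity;
            # collect the absent activities on any full-graph path
            miss: set[str] = set()
            if t in ({source} | nx.descendants(full, source)):
                for node_path in nx.all_simple_paths(full, source, t):
                    acts = [
                        full.edges[u, v]["activity"]
                        for u, v in zip(node_path, node_path[1:])
                    ]
                    miss.update(a for a in acts if a not in present)
            blocking[t] = sorted(miss)
    terminals = sorted(
        node for node in reachable_set if g.out_degree(node) == 0
    )
    return RouteReport(
        source=source,
        present_symbols=set(present),
        reachable=reachable,
        paths=paths,
        blocking=blocking,
        terminal_metabolites=terminals,
    )


def assemble_routes(
    calls: Sequence[OrthologCall],
    catalog: PathwayCatalog,
    targets: Sequence[str] = DEFAULT_TARGETS,
    altsqe_present: bool = False,
    source: str = SOURCE_METABOLITE,
) -> RouteReport:
    """Reachability of target sterols over the present-activity subgraph.

    ``altsqe_present`` injects the alternative squalene epoxidase edge when
    its dedicated detection produced a ``present`` verdict (it substitutes
    for the absent conventional epoxidase).
    """
    present = found_symbols(calls)
    if altsqe_present:
        present.add("AltSQE")
    return _route_report(catalog, present, targets, source)


def simulate_knockout(
    calls: Sequence[OrthologCall],
    catalog: PathwayCatalog,
    knocked: Sequence[str],
    targets: Sequence[str] = DEFAULT_TARGETS,
    altsqe_present: bool = False,
    source: str = SOURCE_METABOLITE,
) -> KnockoutResult:
    """Recompute routes with the knocked activities treated as absent."""
    unknown = [s for s in knocked if s not in catalog.symbols]
    if unknown:
        raise PathwayError(f"unknown activity symbols: {', '.join(unknown)}")
    before = assemble_routes(calls, catalog, targets, altsqe_present, source)
    present_after = before.present_symbols - set(knocked)
    after = _route_report(catalog, present_after, targets, source)
    newly = [
        t for t in targets if before.reachable[t] and not after.reachable[t]
    ]
    return KnockoutResult(
        knocked=list(knocked), before=before, after=after, newly_unreachable=newly
    )
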