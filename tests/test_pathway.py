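import numpy as np
import pytest

from sterolpath.annotate import OrthologCall
from sterolpath.pathway import (
    MEP_SYMBOLS,
    MVA_SYMBOLS,
    PathwayError,
    assemble_routes,
    infer_backbone,
    simulate_knockout,
)


def _calls(found: set[str], catalog) -> list[OrthologCall]:
    return [
        OrthologCall(
            activity_symbol=a.symbol,
            status="found" if a.symbol in found else "not_found",
        )
        for a in catalog.activities
    ]


@pytest.fixture(scope="module")
def table_found(catalog):
    """The bundled inventory's presence pattern: everything with an
    assigned locus except the supplemental epoxidase (handled separately)."""
    return {
        a.symbol
        for a in catalog.activities
        if a.present and a.symbol != "AltSQE"
    }


# --- independent oracle: dict-based BFS reachability ----------------------


def bfs_reachable(catalog, present: set[str], source: str = "acetyl-CoA") -> set[str]:
    adj: dict[str, list[str]] = {}
    for e in catalog.edges:
        if e.activity_symbol in present:
            adj.setdefault(e.substrate, []).append(e.product)
    seen = {source}
    stack = [source]
    while stack:
        for nxt in adj.get(stack.pop(), []):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return seen


# --------------------------------------------------------------------------


class TestInferBackbone:
    def test_full_mva_no_mep_is_mva_only(self, catalog, table_found):
        verdict = infer_backbone(_calls(table_found, catalog), catalog)
        assert verdict.verdict == "MVA_only"
        assert len(verdict.mva_found) == 9
        assert verdict.mep_found == []
        assert verdict.mep_total == 7

    def test_everything_found_is_both(self, catalog):
        all_syms = {a.symbol for a in catalog.activities}
        assert infer_backbone(_calls(all_syms, catalog), catalog).verdict == "both"

    def test_missing_hmgr_is_incomplete_with_gap(self, catalog, table_found):
        verdict = infer_backbone(
            _calls(table_found - {"HMGR"}, catalog), catalog
        )
        assert verdict.verdict == "incomplete"
        assert "HMGR" not in verdict.mva_found

    def test_nothing_found_is_neither(self, catalog):
        assert infer_backbone(_calls(set(), catalog), catalog).verdict == "neither"

    def test_missing_call_records_rejected(self, catalog):
        calls = [
            OrthologCall(activity_symbol="ACAT", status="found"),
        ]
        with pytest.raises(PathwayError, match="HMGR"):
            infer_backbone(calls, catalog)

    def test_permutation_invariant(self, catalog, table_found):
        calls = _calls(table_found, catalog)
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = [calls[i] for i in rng.permutation(len(calls))]
            assert infer_backbone(perm, catalog).verdict == "MVA_only"


class TestAssembleRoutes:
    def test_full_inventory_reaches_both_sterols(self, catalog, table_found):
        report = assemble_routes(
            _calls(table_found, catalog), catalog, altsqe_present=True
        )
        assert report.reachable == {"cholesterol": True, "stigmasterol": True}
        # reachable targets carry explicit activity-labeled paths
        assert report.paths["cholesterol"][0] == "ACAT"
        assert "CYP710A" in report.paths["stigmasterol"]

    def test_without_any_epoxidase_sterols_blocked_at_squalene(
        self, catalog, table_found
    ):
        report = assemble_routes(
            _calls(table_found, catalog), catalog, altsqe_present=False
        )
        assert report.reachable == {"cholesterol": False, "stigmasterol": False}
        assert "squalene" in report.terminal_metabolites
        for target in ("cholesterol", "stigmasterol"):
            assert set(report.blocking[target]) & {"SQE", "AltSQE"}

    def test_osc_removal_blocks_at_epoxysqualene(self, catalog, table_found):
        report = assemble_routes(
            _calls(table_found - {"LAS", "CAS"}, catalog),
            catalog,
            altsqe_present=True,
        )
        assert not report.reachable["cholesterol"]
        assert not report.reachable["stigmasterol"]
        assert report.terminal_metabolites == ["2,3-epoxysqualene"]

    def test_smt_removal_blocks_only_stigmasterol(self, catalog, table_found):
        report = assemble_routes(
            _calls(table_found - {"SMT"}, catalog), catalog, altsqe_present=True
        )
        assert report.reachable["cholesterol"]
        assert not report.reachable["stigmasterol"]
        assert report.blocking["stigmasterol"] == ["SMT"]

    def test_unknown_target_rejected(self, catalog, table_found):
        with pytest.raises(PathwayError, match="unknown target"):
            assemble_routes(
                _calls(table_found, catalog), catalog, targets=("ergosterol",)
            )

    def test_reachability_matches_bfs_oracle(self, catalog, table_found):
        rng = np.random.default_rng(42)
        symbols = sorted(table_found | {"AltSQE"})
        for _ in range(50):
            present = {s for s in symbols if rng.random() < 0.8}
            report = assemble_routes(
                _calls(present, catalog), catalog, altsqe_present="AltSQE" in present
            )
            oracle = bfs_reachable(catalog, present)
            for target in ("cholesterol", "stigmasterol"):
                assert report.reachable[target] == (target in oracle)


class TestSimulateKnockout:
    @pytest.mark.parametrize("knocked", [["CYP51G1"], ["AltSQE"]])
    def test_shared_step_knockout_removes_both_sterols(
        self, catalog, table_found, knocked
    ):
        result = simulate_knockout(
            _calls(table_found, catalog), catalog, knocked, altsqe_present=True
        )
        assert sorted(result.newly_unreachable) == ["cholesterol", "stigmasterol"]

    def test_altsqe_knockout_terminates_at_squalene(self, catalog, table_found):
        result = simulate_knockout(
            _calls(table_found, catalog), catalog, ["AltSQE"], altsqe_present=True
        )
        assert result.after.terminal_metabolites == ["squalene"]

    def test_smt_knockout_spares_cholesterol(self, catalog, table_found):
        result = simulate_knockout(
            _calls(table_found, catalog), catalog, ["SMT"], altsqe_present=True
        )
        assert result.newly_unreachable == ["stigmasterol"]

    def test_empty_knockout_is_identity(self, catalog, table_found):
        result = simulate_knockout(
            _calls(table_found, catalog), catalog, [], altsqe_present=True
        )
        assert result.after.reachable == result.before.reachable
        assert result.newly_unreachable == []

    def test_unknown_symbol_rejected(self, catalog, table_found):
        with pytest.raises(PathwayError, match="GHOST"):
            simulate_knockout(
                _calls(table_found, catalog), catalog, ["GHOST"]
            )

    def test_single_knockout_blockers_match_brute_force_scan(
        self, catalog, table_found
    ):
        """The set of single activities whose loss removes both end sterols
        is derived independently by brute force and must agree."""
        present = table_found | {"AltSQE"}
        expected_both_blocked = set()
        for symbol in sorted(present):
            reach = bfs_reachable(catalog, present - {symbol})
            if "cholesterol" not in reach and "stigmasterol" not in reach:
                expected_both_blocked.add(symbol)
        # the unique-path steps shared by both branches must be in the scan
        assert {"SQS", "AltSQE", "CYP51G1", "FK"} <= expected_both_blocked
        got = set()
        for symbol in sorted(present):
            result = simulate_knockout(
                _calls(table_found, catalog), catalog, [symbol], altsqe_present=True
            )
            if sorted(result.newly_unreachable) == ["cholesterol", "stigmasterol"]:
                got.add(symbol)
        assert got == expected_both_blocked

    def test_knockout_monotonicity_over_random_sets(self, catalog, table_found):
        """Knocking any superset of activities never enlarges reachability."""
        rng = np.random.default_rng(7)
        symbols = sorted(table_found | {"AltSQE"})
        calls = _calls(table_found, catalog)
        for _ in range(100):
            k = int(rng.integers(0, 6))
            knocked = list(rng.choice(symbols, size=k, replace=False))
            extra = [s for s in symbols if s not in knocked]
            superset = knocked + list(
                rng.choice(extra, size=min(2, len(extra)), replace=False)
            )
            small = simulate_knockout(
                calls, catalog, knocked, altsqe_present=True
            ).after
            big = simulate_knockout(
                calls, catalog, superset, altsqe_present=True
            ).after
            small_reach = {t for t, ok in small.reachable.items() if ok}
            big_reach = {t for t, ok in big.reachable.items() if ok}
            assert big_reach <= small_reach
            # the after-set is always contained in the before-set
            assert big_reach <= {
                t
                for t, ok in simulate_knockout(
                    calls, catalog, [], altsqe_present=True
                ).before.reachable.items()
                if ok
            }
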