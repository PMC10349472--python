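"""Event-driven campaign controller: triggers, actions, CIP, sterility, runs."""

import numpy as np
import pandas as pd
import pytest

from mbrtwin.mass_balance import Mixture
from mbrtwin.orchestration import (
    ActionKind,
    CIPParams,
    PendingAction,
    PlateLayout,
    ProtocolError,
    SchedulingError,
    TriggerRule,
    VolumeLedger,
    WellRole,
    WellState,
    check_sterility,
    evaluate_triggers,
    execute_action,
    run_campaign,
    run_cip,
    screening_rules,
    wildtype_rules,
)
from mbrtwin.synthetic_data import GrowthModelConfig


class TestLayout:
    def test_default_flowerplate(self):
        layout = PlateLayout.default()
        assert layout.n_wells == 48
        assert len(layout.wells(WellRole.PRECULTURE)) == 12
        assert len(layout.wells(WellRole.MAIN)) == 36
        linked = [m for mains in layout.links.values() for m in mains]
        assert len(linked) == len(set(linked)) == 36
        assert all(len(m) == 3 for m in layout.links.values())

    def test_cycle_time_follows_optodes(self):
        assert PlateLayout.default(optodes=False).cycle_min == 4.0
        assert PlateLayout.default(optodes=True).cycle_min == 13.0

    def test_bad_links_rejected(self):
        with pytest.raises(ValueError):
            PlateLayout(roles={"A01": WellRole.MAIN},
                        links={"A01": ("A01",)})


def series(well, values, cycle_h=0.1):
    return pd.DataFrame({
        "well": well, "time_h": np.arange(len(values)) * cycle_h,
        "channel": "backscatter", "value": values,
    })


class TestEvaluateTriggers:
    rule = TriggerRule("induce", 3.7, ActionKind.INDUCE, WellRole.MAIN)

    def test_no_crossing_no_action(self):
        ts = series("A02", [1.0, 2.0, 3.0])
        assert evaluate_triggers(ts, [self.rule], {"A02": WellRole.MAIN}) == []

    def test_one_shot_consumes_noise_dip_recrossing(self):
        ts = series("A02", [3.0, 3.8, 3.5, 3.9])
        acts = evaluate_triggers(ts, [self.rule], {"A02": WellRole.MAIN})
        assert len(acts) == 1
        assert acts[0].time_h == pytest.approx(0.1)
        multi = TriggerRule("induce", 3.7, ActionKind.INDUCE, WellRole.MAIN,
                            one_shot=False)
        assert len(evaluate_triggers(ts, [multi], {"A02": WellRole.MAIN})) == 2

    def test_role_filter(self):
        ts = series("A01", [3.0, 4.0])
        assert evaluate_triggers(ts, [self.rule], {"A01": WellRole.PRECULTURE}) == []

    def test_unsorted_series_rejected(self):
        ts = series("A02", [1.0, 4.0]).iloc[::-1]
        with pytest.raises(ValueError):
            evaluate_triggers(ts, [self.rule], {"A02": WellRole.MAIN})

    def test_threshold_boundary_is_at_or_above(self):
        ts = series("A02", [3.69, 3.7])
        acts = evaluate_triggers(ts, [self.rule], {"A02": WellRole.MAIN})
        assert len(acts) == 1


class TestExecuteAction:
    def setup_method(self):
        self.layout = PlateLayout.default()
        self.wells = {n: WellState(role=r) for n, r in self.layout.roles.items()}
        pre = self.wells["A01"]
        pre.mixture = Mixture(800, {"biomass_od": 5.5, "substrate_g_per_L": 2.0})

    def test_triplicate_inoculation_od(self):
        action = PendingAction(10.0, "A01", "inoculate",
                               ActionKind.INOCULATE_MAINS)
        events = execute_action(action, self.wells, self.layout)
        assert len(events) == 3
        for m in self.layout.links["A01"]:
            assert self.wells[m].mixture.conc("biomass_od") == pytest.approx(
                5.5 * 20 / 800
            )
            assert self.wells[m].mixture.volume_uL == pytest.approx(800)
        assert self.wells["A01"].mixture.volume_uL == pytest.approx(740)

    def test_induction_reaches_target_concentration(self):
        main = self.wells["A02"]
        main.mixture = Mixture(800, {"biomass_od": 1.0})
        act = PendingAction(12.0, "A02", "induce", ActionKind.INDUCE,
                            {"iptg_uM": 250.0})
        execute_action(act, self.wells, self.layout)
        assert main.mixture.conc("iptg_uM") == pytest.approx(250.0)
        assert main.induced_at_h == 12.0

    def test_harvest_guard_and_roles(self):
        main = self.wells["A02"]
        main.mixture = Mixture(800, {"biomass_od": 5.0})
        harvest = PendingAction(15.0, "A02", "harvest", ActionKind.HARVEST)
        execute_action(harvest, self.wells, self.layout)
        assert main.harvested
        assert main.mixture.volume_uL == pytest.approx(100.0)
        with pytest.raises(ProtocolError):
            execute_action(harvest, self.wells, self.layout)
        with pytest.raises(ProtocolError):
            execute_action(
                PendingAction(15.0, "A02", "induce", ActionKind.INDUCE),
                self.wells, self.layout,
            )
        with pytest.raises(ProtocolError):
            execute_action(
                PendingAction(15.0, "A02", "inoculate",
                              ActionKind.INOCULATE_MAINS),
                self.wells, self.layout,
            )


def dirty_wells(n=3, volume=100.0):
    wells = {}
    for i in range(n):
        w = WellState(role=WellRole.MAIN,
                      mixture=Mixture(volume, {"biomass_od": 5.0}),
                      harvested=True)
        wells[f"W{i}"] = w
    return wells


class TestCip:
    def test_medium_wash_carryover_and_kill(self):
        wells = dirty_wells()
        res = run_cip(wells, protocol="medium_wash")
        for name, w in wells.items():
            trace = res.disinfectant_trace[name]
            # after the second medium wash, before refill
            assert trace[-2] <= 0.02
            # refilled well is even cleaner and ready for cultivation
            assert res.final_disinfectant_pct(name) <= 0.02
            assert not w.viable
            assert w.mixture.volume_uL == pytest.approx(810.0)
            assert w.cip_count == 1
        assert res.elapsed_h == pytest.approx(2.0, rel=0.1)

    def test_methanol_protocol_duration_and_dry_wells(self):
        wells = dirty_wells()
        res = run_cip(wells, protocol="methanol")
        assert res.elapsed_h == pytest.approx(11.0, rel=0.1)
        for name, w in wells.items():
            assert w.mixture.volume_uL == 0.0
            assert res.final_disinfectant_pct(name) == 0.0
            assert not w.viable

    def test_cip_blocked_while_cultivating(self):
        wells = dirty_wells()
        wells["W1"].harvested = False
        with pytest.raises(SchedulingError):
            run_cip(wells, protocol="medium_wash")

    def test_volume_ledger_balances(self):
        wells = dirty_wells()
        ledger = VolumeLedger()
        ledger.dispense("initial_broth", sum(w.mixture.volume_uL
                                             for w in wells.values()))
        run_cip(wells, protocol="medium_wash", ledger=ledger)
        assert ledger.discrepancy(wells) == pytest.approx(0.0, abs=1e-9)


class TestSterility:
    growth = GrowthModelConfig(mu_max=0.3, lag_h=0.0, noise_sd_au=0.0)

    def refilled(self, od, viable):
        return WellState(role=WellRole.MAIN, viable=viable,
                         mixture=Mixture(800, {"biomass_od": od,
                                               "substrate_g_per_L": 10.0}))

    def test_killed_well_is_sterile(self):
        res = check_sterility(self.refilled(0.001, viable=False), self.growth)
        assert res.sterile and not res.indeterminate

    def test_viable_residual_detected_within_24h(self):
        res = check_sterility(self.refilled(0.001, viable=True), self.growth)
        # OD 0.001 at mu 0.3/h grows to ~1.34 in 24 h: clearly detected
        assert not res.sterile
        assert res.final_od == pytest.approx(0.001 * np.exp(0.3 * 24), rel=1e-6)

    def test_zero_duration_is_indeterminate(self):
        res = check_sterility(self.refilled(0.001, viable=True), self.growth,
                              duration_h=0.0)
        assert res.indeterminate and not res.sterile


class TestCampaign:
    def test_single_run_structure(self):
        res = run_campaign(n_runs=1, seed=1)
        assert res.count("inoculate_preculture") == 12
        assert res.count("inoculate_main") == 36
        assert res.count("harvest") == 36
        assert len(res.samples) == 36
        assert res.cip_results == []

    def test_three_runs_interleave_two_cip_phases(self):
        res = run_campaign(n_runs=3, seed=2)
        assert len(res.cip_results) == 2
        actions = [e.action for e in res.events]
        # CIP phases sit strictly between run completions
        run_marks = [i for i, a in enumerate(actions) if a == "run_complete"]
        cip_marks = [i for i, a in enumerate(actions) if a == "cip_done"]
        assert len(run_marks) == 3 and len(cip_marks) == 2
        assert run_marks[0] < cip_marks[0] < run_marks[1] < cip_marks[1] < run_marks[2]
        assert res.count("harvest") == 108

    def test_volume_audit_balances_across_campaign(self):
        res = run_campaign(n_runs=2, seed=3)
        assert res.audit_discrepancy_uL() == pytest.approx(0.0, abs=1e-6)

    def test_trigger_determinism(self):
        a = run_campaign(n_runs=1, seed=7)
        b = run_campaign(n_runs=1, seed=7)
        assert a.to_jsonl() == b.to_jsonl()
        pd.testing.assert_frame_equal(a.timeseries, b.timeseries)

    def test_post_cip_wells_meet_carryover_invariant(self):
        res = run_campaign(n_runs=2, seed=4)
        cip = res.cip_results[0]
        for name in res.wells:
            assert cip.final_disinfectant_pct(name) <= 0.02

    def test_screening_rules_induce_then_harvest_after_delay(self):
        res = run_campaign(rules=screening_rules(iptg_uM=250.0), n_runs=1,
                           seed=5)
        induces = {e.well: e for e in res.events if e.action == "induce"}
        harvests = {e.well: e for e in res.events if e.action == "harvest"}
        assert len(induces) == 36
        assert len(harvests) == 36
        for well, ind in induces.items():
            assert ind.params["iptg_uM_final"] == pytest.approx(250.0)
            assert harvests[well].time_h - ind.time_h == pytest.approx(4.0)
        assert (res.samples["iptg_uM"] > 0).all()

    def test_empty_layout_rejected(self):
        layout = PlateLayout(roles={"A01": WellRole.UNUSED}, links={})
        with pytest.raises(SchedulingError):
            run_campaign(layout=layout, n_runs=1)

    def test_timeout_is_logged_failure(self):
        growth = GrowthModelConfig(mu_max=0.05, cycle_min=4.0)  # too slow
        with pytest.raises(SchedulingError):
            run_campaign(growth=growth, n_runs=1, max_run_h=5.0)

    def test_secreted_product_appears_in_samples(self):
        layout = PlateLayout.default()
        rates = {m: 0.5 for m in layout.wells(WellRole.MAIN)}
        res = run_campaign(rules=screening_rules(), n_runs=1, seed=6,
                           production_rates=rates)
        # 4 h of production at 0.5 U/mL/h, modulo dilution by the IPTG bolus
        assert res.samples["product_U_per_mL"].between(1.5, 2.1).all()
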