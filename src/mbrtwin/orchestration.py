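"""Event-driven controller for autonomous microbioreactor campaigns.

This module is the digital twin of the platform's control logic: a 48-well
FlowerPlate with 12 preculture wells in the outer columns, each linked to
three adjacent main-culture wells; backscatter-triggered inoculation,
induction and harvest; plate-level clean-in-place (CIP) between runs; and
consecutive, fully autonomous cultivation runs.

Time advances on the measurement cycle grid (13 min with pH/DO optodes,
4 min without) and triggers are evaluated only at sample instants: an
upward crossing is the first sample at or above the threshold after a
sample strictly below it, with no interpolation, so a trigger time is
accurate to one cycle. Each well triggers individually.

Liquid handling goes through :mod:`mbrtwin.mass_balance`, and every
action appends an immutable :class:`EventRecord`, so a finished campaign
carries a complete, auditable log: volumes are conserved exactly between
wells, troughs, waste, samples and evaporation.

Two CIP protocols are modelled (durations are derived from per-plate
liquid-handling passes plus fixed incubation/evaporation steps):

- ``medium_wash`` (~2 h): disinfectant pre-wash of the residual broth,
  800 µL disinfectant incubated 20 min (kills all viable biomass),
  two-step removal down to ~10 µL, two 700 µL washes with fresh medium,
  refill with 800 µL medium. Carry-over follows the residual-chain
  arithmetic: two washes leave ≤ 0.02 % (v/v) disinfectant before refill.
- ``methanol`` (~11 h): disinfectant incubation and removal, replacement
  of the ~10 µL residue by 400 µL methanol, removal, and a long (default
  10 h) evaporation step that clears the volatile residue.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .mass_balance import Mixture, mix, ParameterError
from .synthetic_data import GrowthModelConfig

__all__ = [
    "WellRole",
    "PlateLayout",
    "TriggerRule",
    "PendingAction",
    "EventRecord",
    "WellState",
    "CIPParams",
    "CIPResult",
    "SterilityResult",
    "CampaignResult",
    "ProtocolError",
    "SchedulingError",
    "evaluate_triggers",
    "execute_action",
    "run_cip",
    "check_sterility",
    "run_campaign",
    "wildtype_rules",
    "screening_rules",
]


class ProtocolError(RuntimeError):
    """An action was requested on a well whose state/role forbids it."""


class SchedulingError(RuntimeError):
    """A campaign-level ordering constraint was violated."""


class WellRole(str, Enum):
    PRECULTURE = "preculture"
    MAIN = "main"
    UNUSED = "unused"


@dataclass(frozen=True)
class PlateLayout:
    """Well roles and preculture-to-main links of a cultivation plate.

    The default 48-well FlowerPlate layout places 12 precultures in the
    outer columns (1 and 8 of a 6x8 plate) and links each to the three
    adjacent inner wells of its row half, giving 12 + 36 = 48 wells.
    """

    roles: Mapping[str, WellRole]
    links: Mapping[str, tuple[str, ...]]
    optodes: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "roles", dict(self.roles))
        object.__setattr__(self, "links", {k: tuple(v) for k, v in self.links.items()})
        linked: list[str] = []
        for pre, mains in self.links.items():
            if self.roles.get(pre) is not WellRole.PRECULTURE:
                raise ValueError(f"link source {pre} is not a preculture")
            for m in mains:
                if self.roles.get(m) is not WellRole.MAIN:
                    raise ValueError(f"link target {m} is not a main well")
            linked.extend(mains)
        if len(linked) != len(set(linked)):
            raise ValueError("preculture->main links overlap")

    @property
    def n_wells(self) -> int:
        return len(self.roles)

    @property
    def cycle_min(self) -> float:
        return 13.0 if self.optodes else 4.0

    def wells(self, role: WellRole | None = None) -> list[str]:
        if role is None:
            return sorted(self.roles)
        return sorted(w for w, r in self.roles.items() if r is role)

    @classmethod
    def default(cls, optodes: bool = False) -> "PlateLayout":
        rows = "ABCDEF"
        roles: dict[str, WellRole] = {}
        links: dict[str, tuple[str, ...]] = {}
        for r in rows:
            left, right = f"{r}01", f"{r}08"
            roles[left] = roles[right] = WellRole.PRECULTURE
            left_mains = tuple(f"{r}{c:02d}" for c in (2, 3, 4))
            right_mains = tuple(f"{r}{c:02d}" for c in (5, 6, 7))
            for m in left_mains + right_mains:
                roles[m] = WellRole.MAIN
            links[left] = left_mains
            links[right] = right_mains
        return cls(roles=roles, links=links, optodes=optodes)


class ActionKind(str, Enum):
    INOCULATE_MAINS = "inoculate_mains"
    INDUCE = "induce"
    HARVEST = "harvest"
    HARVEST_AFTER_DELAY = "harvest_after_delay"
    START_CIP = "start_cip"


@dataclass(frozen=True)
class TriggerRule:
    """A declarative control rule: threshold crossing -> action.

    The platform's stock rules: main-culture inoculation when a
    preculture crosses 5.5 a.u. (exponential phase), IPTG induction when
    a main culture crosses 3.7 a.u. (early exponential), harvest either
    on a threshold or a fixed delay after induction (4 h).
    """

    name: str
    threshold_au: float
    action: ActionKind
    applies_to: WellRole
    channel: str = "backscatter"
    delay_h: float = 0.0
    one_shot: bool = True
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.threshold_au <= 0:
            raise ParameterError("trigger threshold must be > 0")
        object.__setattr__(self, "params", dict(self.params))


@dataclass(frozen=True)
class PendingAction:
    time_h: float
    well: str
    rule: str
    action: ActionKind
    params: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class EventRecord:
    """One executed action; the campaign log is an append-only list."""

    time_h: float
    well: str
    action: str
    params: Mapping[str, object] = field(default_factory=dict)
    outcome: str = "ok"

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, sort_keys=True, default=str)


@dataclass
class WellState:
    """Mutable physical state of one cultivation well."""

    role: WellRole
    mixture: Mixture = field(default_factory=lambda: Mixture(0.0, {}))
    viable: bool = True
    induced_at_h: float | None = None
    harvested: bool = False
    cip_count: int = 0
    lag_until_h: float = 0.0
    production_rate: float = 0.0   # U/mL per h after induction

    @property
    def od(self) -> float:
        return self.mixture.conc("biomass_od")


def wildtype_rules(threshold_au: float = 5.5) -> list[TriggerRule]:
    """Consecutive-cultivation validation: sample mains at the same threshold
    that fires main-culture inoculation from the precultures."""
    return [
        TriggerRule("inoculate", threshold_au, ActionKind.INOCULATE_MAINS,
                    WellRole.PRECULTURE),
        TriggerRule("harvest", threshold_au, ActionKind.HARVEST, WellRole.MAIN),
    ]


def screening_rules(
    iptg_uM: float = 250.0,
    induction_threshold_au: float = 3.7,
    inoculation_threshold_au: float = 5.5,
    harvest_delay_h: float = 4.0,
) -> list[TriggerRule]:
    """Secretion-screening workflow: inoculate at 5.5 a.u., induce with
    IPTG at 3.7 a.u., harvest 4 h after induction."""
    return [
        TriggerRule("inoculate", inoculation_threshold_au,
                    ActionKind.INOCULATE_MAINS, WellRole.PRECULTURE),
        TriggerRule("induce", induction_threshold_au, ActionKind.INDUCE,
                    WellRole.MAIN, params={"iptg_uM": iptg_uM}),
        TriggerRule("harvest", induction_threshold_au,
                    ActionKind.HARVEST_AFTER_DELAY, WellRole.MAIN,
                    delay_h=harvest_delay_h),
    ]


# ---------------------------------------------------------------------------
# trigger evaluation (batch form over a recorded time series)
# ---------------------------------------------------------------------------

def evaluate_triggers(
    ts: pd.DataFrame,
    rules: Sequence[TriggerRule],
    roles: Mapping[str, WellRole],
) -> list[PendingAction]:
    """Scan a recorded long-format time series for rule crossings.

    An upward crossing at sample k means value[k-1] < threshold <=
    value[k]; the action is stamped at sample k's time. One-shot rules
    fire at most once per well; wells trigger independently of each
    other. The series must be time-sorted per well.
    """
    required = {"well", "time_h", "channel", "value"}
    if not required <= set(ts.columns):
        raise ValueError(f"time series needs columns {sorted(required)}")
    actions: list[PendingAction] = []
    for well, sub in ts.groupby("well"):
        role = roles.get(well)
        for rule in rules:
            if role is not rule.applies_to:
                continue
            chan = sub[sub["channel"] == rule.channel]
            t = chan["time_h"].to_numpy(dtype=float)
            v = chan["value"].to_numpy(dtype=float)
            if np.any(np.diff(t) < 0):
                raise ValueError(f"time series for well {well} is unsorted")
            crossings = np.flatnonzero((v[1:] >= rule.threshold_au)
                                       & (v[:-1] < rule.threshold_au)) + 1
            if rule.one_shot:
                crossings = crossings[:1]
            for k in crossings:
                actions.append(PendingAction(
                    time_h=float(t[k]) + rule.delay_h, well=str(well),
                    rule=rule.name, action=rule.action, params=rule.params,
                ))
    actions.sort(key=lambda a: (a.time_h, a.well, a.rule))
    return actions


# ---------------------------------------------------------------------------
# liquid-handling bookkeeping
# ---------------------------------------------------------------------------

FRESH_MEDIUM = {"substrate_g_per_L": 10.0}


@dataclass
class VolumeLedger:
    """Campaign-wide volume audit: sources, sinks and well inventory."""

    dispensed: dict[str, float] = field(default_factory=dict)
    waste_uL: float = 0.0
    sampled_uL: float = 0.0
    evaporated_uL: float = 0.0

    def dispense(self, source: str, v: float) -> None:
        self.dispensed[source] = self.dispensed.get(source, 0.0) + v

    def total_in(self) -> float:
        return sum(self.dispensed.values())

    def total_out(self) -> float:
        return self.waste_uL + self.sampled_uL + self.evaporated_uL

    def discrepancy(self, wells: Mapping[str, WellState]) -> float:
        """Dispensed minus (still in wells + waste + samples + evaporated)."""
        in_wells = sum(w.mixture.volume_uL for w in wells.values())
        return self.total_in() - self.total_out() - in_wells


def _add(well: WellState, volume_uL: float, composition: Mapping[str, float],
         ledger: VolumeLedger | None, source: str) -> None:
    well.mixture = mix(well.mixture, Mixture(volume_uL, composition))
    if ledger is not None:
        ledger.dispense(source, volume_uL)


def _remove_to(well: WellState, residual_uL: float,
               ledger: VolumeLedger | None, sink: str = "waste") -> float:
    """Aspirate down to ``residual_uL``; returns the removed volume."""
    removed = max(well.mixture.volume_uL - residual_uL, 0.0)
    _, well.mixture = well.mixture.split(removed)
    if ledger is not None:
        if sink == "waste":
            ledger.waste_uL += removed
        elif sink == "sample":
            ledger.sampled_uL += removed
        elif sink == "evaporation":
            ledger.evaporated_uL += removed
    return removed


# ---------------------------------------------------------------------------
# action execution
# ---------------------------------------------------------------------------

def execute_action(
    action: PendingAction,
    wells: Mapping[str, WellState],
    layout: PlateLayout,
    ledger: VolumeLedger | None = None,
    main_medium_uL: float = 780.0,
    transfer_uL: float = 20.0,
    iptg_bolus_uL: float = 20.0,
    residual_broth_uL: float = 100.0,
) -> list[EventRecord]:
    """Apply one pending action to the well map; returns the event records.

    Volumes and concentrations are updated by exact mass balance; the
    inducer is added as a small bolus (default 20 µL) of a concentrated
    stock sized so the stated final concentration is met exactly.
    """
    well = wells.get(action.well)
    if well is None:
        raise ProtocolError(f"unknown well {action.well}")
    t = action.time_h
    events: list[EventRecord] = []

    if action.action is ActionKind.INOCULATE_MAINS:
        if well.role is not WellRole.PRECULTURE:
            raise ProtocolError(f"{action.well} is not a preculture")
        if well.harvested:
            raise ProtocolError(f"{action.well} already harvested")
        for target_name in layout.links[action.well]:
            target = wells[target_name]
            if target.harvested or target.mixture.conc("biomass_od") > 0:
                raise ProtocolError(f"main well {target_name} is not fresh")
            top_up = max(main_medium_uL - target.mixture.volume_uL, 0.0)
            if top_up > 0:
                _add(target, top_up, FRESH_MEDIUM, ledger, "medium")
            inoculum, well.mixture = well.mixture.split(transfer_uL)
            target.mixture = mix(target.mixture, inoculum)
            # exponential-phase inoculum: main cultures start growing at once
            target.viable = True
            target.lag_until_h = t
            events.append(EventRecord(
                t, target_name, "inoculate_main",
                params={"from": action.well, "v_transfer_uL": transfer_uL,
                        "v_medium_uL": top_up,
                        "od_start": round(target.mixture.conc("biomass_od"), 6)},
            ))
    elif action.action is ActionKind.INDUCE:
        if well.role is not WellRole.MAIN:
            raise ProtocolError(f"induction on non-main well {action.well}")
        if well.harvested:
            raise ProtocolError(f"{action.well} already harvested")
        if well.induced_at_h is not None:
            raise ProtocolError(f"{action.well} already induced")
        target_uM = float(action.params.get("iptg_uM", 250.0))
        v = well.mixture.volume_uL
        stock_uM = target_uM * (v + iptg_bolus_uL) / iptg_bolus_uL
        _add(well, iptg_bolus_uL, {"iptg_uM": stock_uM}, ledger, "iptg_stock")
        well.induced_at_h = t
        events.append(EventRecord(
            t, action.well, "induce",
            params={"iptg_uM_final": round(well.mixture.conc("iptg_uM"), 6),
                    "bolus_uL": iptg_bolus_uL},
        ))
    elif action.action in (ActionKind.HARVEST, ActionKind.HARVEST_AFTER_DELAY):
        if well.harvested:
            raise ProtocolError(f"{action.well} already harvested")
        if well.role is WellRole.UNUSED:
            raise ProtocolError(f"harvest on unused well {action.well}")
        sample = dict(well.mixture.components)
        v_removed = _remove_to(well, residual_broth_uL, ledger, sink="sample")
        well.harvested = True
        events.append(EventRecord(
            t, action.well, "harvest",
            params={"v_sample_uL": round(v_removed, 6),
                    "od": round(sample.get("biomass_od", 0.0), 6),
                    "product_U_per_mL": sample.get("product_U_per_mL", 0.0),
                    "iptg_uM": sample.get("iptg_uM", 0.0)},
        ))
    else:
        raise ProtocolError(f"cannot execute action {action.action}")
    return events


# ---------------------------------------------------------------------------
# clean-in-place
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CIPParams:
    """Volumes and timings of the CIP protocols.

    ``pass_min`` is the duration of one liquid-handling pass over the
    whole plate (one reagent addition or one aspiration run across all
    wells); protocol durations are whole-plate pass counts times this,
    plus the fixed incubation/evaporation steps. Aspiration speeds are
    carried as metadata only (they motivate the residual-volume presets:
    ~10 µL is reachable for solvent-like liquids, 100 µL is the
    conservative worst case for spent culture broth).
    """

    residual_broth_uL: float = 100.0
    residual_solvent_uL: float = 10.0
    prewash_uL: float = 500.0
    disinfectant_uL: float = 800.0
    incubation_min: float = 20.0
    wash_uL: float = 700.0
    n_washes: int = 2
    refill_uL: float = 800.0
    methanol_uL: float = 400.0
    evaporation_h: float = 10.0
    pass_min: float = 8.0
    aspiration_speeds_uL_per_s: tuple[float, float] = (250.0, 70.0)


@dataclass(frozen=True)
class CIPResult:
    protocol: str
    elapsed_h: float
    #: per well: disinfectant % v/v after each dilution step
    disinfectant_trace: Mapping[str, tuple[float, ...]]
    events: tuple[EventRecord, ...]

    def final_disinfectant_pct(self, well: str) -> float:
        trace = self.disinfectant_trace[well]
        return trace[-1] if trace else 0.0


DISINFECTANT = {"disinfectant_pct": 100.0}
METHANOL = {"methanol_pct": 100.0}


def run_cip(
    wells: Mapping[str, WellState],
    protocol: str = "medium_wash",
    params: CIPParams | None = None,
    t0_h: float = 0.0,
    ledger: VolumeLedger | None = None,
    require_harvested: bool = True,
) -> CIPResult:
    """Run one plate-level CIP protocol over all given wells.

    CIP uses barrier semantics: it may only start once every cultivated
    well has been harvested (or explicitly designated for cleaning via
    ``require_harvested=False``). All wells are processed together; the
    elapsed time is the sum of per-plate pass times plus incubation (and,
    for the methanol protocol, evaporation).
    """
    p = params or CIPParams()
    for name, w in wells.items():
        if require_harvested and w.mixture.conc("biomass_od") > 0 and not w.harvested:
            raise SchedulingError(
                f"CIP requested while well {name} is still cultivating"
            )
    events: list[EventRecord] = []
    traces: dict[str, list[float]] = {name: [] for name in wells}
    passes = 0
    t = t0_h

    def log(action: str, well: str = "*", **kw) -> None:
        events.append(EventRecord(t, well, action, params=kw))

    # common base: dispose of the bulk liquid (conservative 100 µL residual)
    for name, w in wells.items():
        _remove_to(w, min(p.residual_broth_uL, w.mixture.volume_uL), ledger)
    passes += 1
    log("cip_dispose_bulk", residual_uL=p.residual_broth_uL)

    if protocol == "medium_wash":
        # pre-wash: 500 µL disinfectant onto the broth residue, removed in
        # two steps (fast + slow aspiration) down to the solvent residual
        for w in wells.values():
            _add(w, p.prewash_uL, DISINFECTANT, ledger, "disinfectant")
        passes += 1
        for w in wells.values():
            _remove_to(w, p.residual_solvent_uL, ledger)
        passes += 2
        log("cip_prewash", v_uL=p.prewash_uL,
            aspiration_uL_per_s=p.aspiration_speeds_uL_per_s)

    # disinfection: 800 µL, 20 min shaken incubation kills viable biomass
    for w in wells.values():
        _add(w, p.disinfectant_uL, DISINFECTANT, ledger, "disinfectant")
    passes += 1
    t = t0_h + (passes * p.pass_min + p.incubation_min) / 60.0
    for name, w in wells.items():
        w.viable = False
        w.mixture = w.mixture.with_conc("biomass_od", 0.0)
        traces[name].append(w.mixture.conc("disinfectant_pct"))
    log("cip_disinfect", v_uL=p.disinfectant_uL,
        incubation_min=p.incubation_min)
    for w in wells.values():
        _remove_to(w, p.residual_solvent_uL, ledger)
    passes += 2  # fast + slow aspiration pass

    if protocol == "medium_wash":
        for i in range(p.n_washes):
            for name, w in wells.items():
                _add(w, p.wash_uL, FRESH_MEDIUM, ledger, "medium")
                _remove_to(w, p.residual_solvent_uL, ledger)
                traces[name].append(w.mixture.conc("disinfectant_pct"))
            passes += 2
            log("cip_wash", step=i + 1, v_uL=p.wash_uL)
        for name, w in wells.items():
            _add(w, p.refill_uL, FRESH_MEDIUM, ledger, "medium")
            traces[name].append(w.mixture.conc("disinfectant_pct"))
        passes += 1
        log("cip_refill", v_uL=p.refill_uL)
        elapsed_h = (passes * p.pass_min + p.incubation_min) / 60.0
    elif protocol == "methanol":
        for name, w in wells.items():
            _add(w, p.methanol_uL, METHANOL, ledger, "methanol")
            traces[name].append(w.mixture.conc("disinfectant_pct"))
        passes += 1
        for w in wells.values():
            _remove_to(w, p.residual_solvent_uL, ledger)
        passes += 2
        log("cip_methanol_wash", v_uL=p.methanol_uL)
        # evaporation clears the volatile residue entirely: the well ends
        # dry, so the carried-over disinfectant amount is zero
        for name, w in wells.items():
            traces[name].append(w.mixture.conc("disinfectant_pct"))
            _remove_to(w, 0.0, ledger, sink="evaporation")
            w.mixture = Mixture(0.0, {})
            traces[name].append(0.0)
        log("cip_evaporate", duration_h=p.evaporation_h)
        elapsed_h = (passes * p.pass_min + p.incubation_min) / 60.0 + p.evaporation_h
    else:
        raise ValueError(f"unknown CIP protocol {protocol!r}")

    for w in wells.values():
        w.harvested = False
        w.induced_at_h = None
        w.cip_count += 1
    t = t0_h + elapsed_h
    log("cip_done", protocol=protocol, elapsed_h=round(elapsed_h, 4))
    return CIPResult(
        protocol=protocol, elapsed_h=elapsed_h,
        disinfectant_trace={k: tuple(v) for k, v in traces.items()},
        events=tuple(events),
    )


# ---------------------------------------------------------------------------
# sterility check
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SterilityResult:
    sterile: bool
    indeterminate: bool
    backscatter_rise_au: float
    final_od: float


def check_sterility(
    well: WellState,
    growth_config: GrowthModelConfig,
    duration_h: float = 24.0,
    detection_threshold_au: float = 0.2,
) -> SterilityResult:
    """Incubation test: does anything grow out of a cleaned, refilled well?

    Any viable residual biomass is grown with the given kinetics for
    ``duration_h``; the well counts as sterile iff the resulting
    backscatter rise stays below ``detection_threshold_au``. A
    non-positive duration cannot prove sterility: the result is flagged
    indeterminate (and not sterile).
    """
    od0 = well.mixture.conc("biomass_od") if well.viable else 0.0
    if duration_h <= 0:
        if od0 > 0:
            return SterilityResult(False, True, 0.0, od0)
        return SterilityResult(True, True, 0.0, 0.0)
    cfg = growth_config.replace(od0=od0) if od0 > 0 else growth_config.replace(od0=0.0)
    od_end = float(cfg.od_at(duration_h)) if od0 > 0 else 0.0
    rise = growth_config.gain_au_per_od * (od_end - od0)
    return SterilityResult(
        sterile=rise < detection_threshold_au,
        indeterminate=False,
        backscatter_rise_au=rise,
        final_od=od_end,
    )


# ---------------------------------------------------------------------------
# campaign engine
# ---------------------------------------------------------------------------

@dataclass
class CampaignResult:
    events: list[EventRecord]
    timeseries: pd.DataFrame
    samples: pd.DataFrame
    wells: dict[str, WellState]
    cip_results: list[CIPResult]
    ledger: VolumeLedger

    def events_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"time_h": e.time_h, "well": e.well, "action": e.action,
              "outcome": e.outcome, **{f"p_{k}": v for k, v in e.params.items()}}
             for e in self.events]
        )

    def to_jsonl(self) -> str:
        """Event log as JSON lines, time-ordered."""
        return "\n".join(e.to_json() for e in self.events)

    def count(self, action: str) -> int:
        return sum(1 for e in self.events if e.action == action)

    def audit_discrepancy_uL(self) -> float:
        return self.ledger.discrepancy(self.wells)


def _grow_step(well: WellState, cfg: GrowthModelConfig,
               t_prev: float, t_now: float) -> None:
    """Advance one well's biomass/substrate over [t_prev, t_now]."""
    if not well.viable or well.harvested:
        return
    od = well.mixture.conc("biomass_od")
    substrate = well.mixture.conc("substrate_g_per_L")
    if od <= 0:
        return
    dt = max(0.0, t_now - max(t_prev, well.lag_until_h))
    comp = dict(well.mixture.components)
    if dt > 0 and substrate > 0:
        od_new = min(od * math.exp(cfg.mu_max * dt),
                     od + cfg.yield_od_per_g * substrate)
        comp["substrate_g_per_L"] = max(
            substrate - (od_new - od) / cfg.yield_od_per_g, 0.0
        )
        comp["biomass_od"] = od_new
    if well.induced_at_h is not None and well.production_rate > 0:
        dt_prod = max(0.0, t_now - max(t_prev, well.induced_at_h))
        comp["product_U_per_mL"] = comp.get("product_U_per_mL", 0.0) \
            + well.production_rate * dt_prod
    well.mixture = Mixture(well.mixture.volume_uL, comp)


def run_campaign(
    layout: PlateLayout | None = None,
    rules: Sequence[TriggerRule] | None = None,
    growth: GrowthModelConfig | None = None,
    n_runs: int = 1,
    cip_protocol: str = "medium_wash",
    cip_params: CIPParams | None = None,
    seed: int = 0,
    wcb_od: float = 4.0,
    preculture_medium_uL: float = 780.0,
    inoculum_uL: float = 20.0,
    production_rates: Mapping[str, float] | None = None,
    max_run_h: float = 40.0,
) -> CampaignResult:
    """Simulate ``n_runs`` consecutive autonomous cultivation runs.

    Each run: precultures are inoculated from a working cell bank (OD 4
    stock, 20 µL into 780 µL medium -> OD 0.1), wells are measured every
    cycle, trigger rules fire per well, main cultures are inoculated /
    induced / harvested, and — between runs — the whole plate goes
    through the chosen CIP protocol. No manual events appear in the log.

    ``production_rates`` optionally maps main-well names to secreted
    product formation rates (U/mL per h, active after induction), so
    harvest samples carry product concentrations.

    Raises :class:`SchedulingError` if a run does not complete within
    ``max_run_h`` (e.g. a preculture never reaches its trigger); the
    failure is logged before raising.
    """
    layout = layout or PlateLayout.default()
    rules = list(rules) if rules is not None else wildtype_rules()
    growth = growth or GrowthModelConfig(cycle_min=13.0 if layout.optodes else 4.0)
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    precultures = layout.wells(WellRole.PRECULTURE)
    mains = layout.wells(WellRole.MAIN)
    if not precultures or not mains:
        raise SchedulingError("empty campaign: layout assigns no cultivation wells")

    wells = {name: WellState(role=layout.roles[name]) for name in layout.roles}
    if production_rates:
        for name, rate in production_rates.items():
            wells[name].production_rate = float(rate)
    ledger = VolumeLedger()
    events: list[EventRecord] = []
    ts_rows: list[dict] = []
    sample_rows: list[dict] = []
    cip_results: list[CIPResult] = []
    cycle_h = growth.cycle_min / 60.0
    t = 0.0

    for run in range(1, n_runs + 1):
        run_start = t
        # inoculate precultures from the cell bank
        for name in precultures:
            w = wells[name]
            top_up = max(preculture_medium_uL - w.mixture.volume_uL, 0.0)
            if top_up > 0:
                _add(w, top_up, FRESH_MEDIUM, ledger, "medium")
            _add(w, inoculum_uL, {"biomass_od": wcb_od}, ledger, "wcb")
            w.viable = True
            w.lag_until_h = t + growth.lag_h
            events.append(EventRecord(
                t, name, "inoculate_preculture",
                params={"run": run, "v_uL": inoculum_uL, "wcb_od": wcb_od,
                        "od_start": round(w.mixture.conc("biomass_od"), 6)},
            ))

        fired: set[tuple[str, str]] = set()       # (rule name, well)
        prev_signal: dict[str, float] = {}
        scheduled: list[PendingAction] = []
        noise_rng = {name: child_rng(seed, "campaign", run, name)
                     for name in wells}
        n_steps = int(math.ceil(max_run_h / cycle_h))
        completed = False
        for _ in range(n_steps + 1):
            # growth over the last cycle, then a measurement at time t
            for name, w in wells.items():
                _grow_step(w, growth, t - cycle_h, t)
            signals: dict[str, float] = {}
            for name, w in wells.items():
                if w.harvested or w.mixture.conc("biomass_od") <= 0:
                    continue
                noise = 0.0
                if growth.noise_sd_au > 0:
                    noise = float(noise_rng[name]
                                  .normal(0.0, growth.noise_sd_au))
                sig = (growth.gain_au_per_od * w.mixture.conc("biomass_od")
                       + growth.offset_au + noise)
                signals[name] = sig
                ts_rows.append({"run": run, "well": name, "time_h": t,
                                "channel": "backscatter", "value": sig})

            # due delayed actions first, then fresh threshold crossings
            due = [a for a in scheduled if a.time_h <= t + 1e-9]
            scheduled = [a for a in scheduled if a.time_h > t + 1e-9]
            pending = list(due)
            for rule in rules:
                for name, sig in signals.items():
                    if wells[name].role is not rule.applies_to:
                        continue
                    key = (rule.name, name)
                    if rule.one_shot and key in fired:
                        continue
                    prev = prev_signal.get(name)
                    if prev is not None and prev < rule.threshold_au <= sig:
                        fired.add(key)
                        act_time = t + rule.delay_h
                        action = PendingAction(act_time, name, rule.name,
                                               rule.action, rule.params)
                        if rule.delay_h > 0:
                            scheduled.append(action)
                            events.append(EventRecord(
                                t, name, "schedule",
                                params={"rule": rule.name, "due_h": act_time}))
                        else:
                            pending.append(action)
            for action in sorted(pending, key=lambda a: (a.time_h, a.well)):
                recs = execute_action(action, wells, layout, ledger)
                for rec in recs:
                    events.append(rec)
                    if rec.action == "harvest":
                        sample_rows.append({
                            "run": run, "well": rec.well, "time_h": rec.time_h,
                            "volume_uL": rec.params["v_sample_uL"],
                            "od": rec.params["od"],
                            "product_U_per_mL": rec.params["product_U_per_mL"],
                            "iptg_uM": rec.params["iptg_uM"],
                        })
            prev_signal = signals
            if all(wells[m].harvested or wells[m].mixture.conc("biomass_od") <= 0
                   for m in mains) and any(wells[m].harvested for m in mains):
                completed = True
                break
            t += cycle_h
        if not completed:
            events.append(EventRecord(t, "*", "timeout_failure",
                                      params={"run": run,
                                              "max_run_h": max_run_h},
                                      outcome="failed"))
            raise SchedulingError(
                f"run {run} did not complete within {max_run_h} h"
            )
        events.append(EventRecord(t, "*", "run_complete",
                                  params={"run": run,
                                          "duration_h": round(t - run_start, 4)}))

        if run < n_runs:
            # remove preculture liquid, then clean all wells in place
            for name in precultures:
                wells[name].harvested = True
                _remove_to(wells[name], cip_params.residual_broth_uL
                           if cip_params else 100.0, ledger)
                events.append(EventRecord(t, name, "remove_preculture_liquid"))
            cip = run_cip(wells, protocol=cip_protocol, params=cip_params,
                          t0_h=t, ledger=ledger)
            events.extend(cip.events)
            cip_results.append(cip)
            t += cip.elapsed_h

    # delayed actions are stamped at their due time, which can precede the
    # sample instant they were executed at; a stable sort restores strict
    # time order without disturbing same-instant append order
    events.sort(key=lambda e: e.time_h)
    return CampaignResult(
        events=events,
        timeseries=pd.DataFrame(ts_rows),
        samples=pd.DataFrame(sample_rows),
        wells=wells,
        cip_results=cip_results,
        ledger=ledger,
    )
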