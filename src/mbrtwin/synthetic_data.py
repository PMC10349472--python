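"""Synthetic data generators with known ground truth.

Everything the analysis pipeline consumes can be generated here: batch
growth curves read out as backscatter at fixed measurement cycles,
secreted-enzyme activities with run-level (batch) random effects, and
4-nitrophenol absorbance kinetics for the photometric activity assay.
Because every generator exposes its ground truth (true stop time, true
activity, true variance components), the estimators elsewhere in the
package can be tested as recovery problems.

Growth model
------------
Batch growth is modelled as lag -> single-rate exponential -> hard stop:

    OD(t) = od0                                   t <= lag
    OD(t) = od0 * exp(mu_max * (t - lag))         lag < t <= t_stop
    OD(t) = od0 + Y * S0                          t > t_stop

where the stop is substrate exhaustion: the culture stops the moment the
cumulative biomass formed equals the yield ``Y`` (OD per g/L) times the
initial substrate ``S0`` (g/L), i.e. at

    t_stop = lag + ln(1 + Y * S0 / od0) / mu_max.

No Monod saturation term is used: wild-type *C. glutamicum* on glucose
shows a sharp exponential-to-stationary transition, which is exactly the
feature the derivative-based batch-time detector keys on, and a hard stop
reproduces it with one parameter fewer.

The optical readout is backscatter in arbitrary units (a.u.):

    backscatter = gain * OD + offset + noise,  noise ~ N(0, noise_sd).

The instrument gives no absolute backscatter/OD calibration, so gain and
offset are free configuration, chosen by default so that the operational
trigger thresholds (2, 3.7 and 5.5 a.u.) fall inside the exponential
phase. Measurements are taken on a fixed cycle grid: every 13 min for
plates with pH/DO optodes, every 4 min without.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from ._rng import child_rng
from .mass_balance import ParameterError

__all__ = [
    "GrowthModelConfig",
    "SecretionEffectConfig",
    "simulate_batch_growth",
    "simulate_secretion",
    "simulate_assay_kinetics",
    "make_replicate_design",
]


@dataclass(frozen=True)
class GrowthModelConfig:
    """Parameters of the lag/exponential/hard-stop growth model.

    Defaults are calibrated so that a culture inoculated to OD 0.1 on
    10 g/L glucose reaches stationary phase after ~12.7 h, the magnitude
    typical for wild-type *C. glutamicum* batches in this format.

    Attributes
    ----------
    mu_max : float
        Maximum specific growth rate (1/h).
    lag_h : float
        Lag-phase duration after inoculation (h).
    substrate_g_per_L : float
        Initial substrate concentration (g/L).
    yield_od_per_g : float
        OD units formed per g/L substrate consumed.
    od0 : float
        OD at inoculation.
    gain_au_per_od, offset_au : float
        Backscatter calibration: signal = gain*OD + offset (a.u.).
    noise_sd_au : float
        SD of additive Gaussian measurement noise (a.u.).
    cycle_min : float
        Measurement cycle time in minutes (13 with optodes, 4 without).
    seed : int
        Root RNG seed.
    """

    mu_max: float = 0.4735
    lag_h: float = 1.5
    substrate_g_per_L: float = 10.0
    yield_od_per_g: float = 2.0
    od0: float = 0.1
    gain_au_per_od: float = 1.0
    offset_au: float = 0.0
    noise_sd_au: float = 0.05
    cycle_min: float = 13.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_max <= 0:
            raise ParameterError(f"mu_max must be > 0, got {self.mu_max}")
        for name in ("lag_h", "substrate_g_per_L", "yield_od_per_g", "od0",
                     "noise_sd_au"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.cycle_min <= 0:
            raise ParameterError("cycle_min must be > 0")

    @property
    def od_max(self) -> float:
        """Stationary-phase OD: inoculum plus yield from all substrate."""
        return self.od0 + self.yield_od_per_g * self.substrate_g_per_L

    @property
    def t_stop_h(self) -> float:
        """Substrate-exhaustion time (h); inf if the inoculum is zero."""
        if self.od0 == 0 or self.od_max == self.od0:
            return math.inf
        return self.lag_h + math.log(self.od_max / self.od0) / self.mu_max

    def od_at(self, t_h: np.ndarray | float) -> np.ndarray | float:
        """Noise-free OD of the model at time ``t_h`` since inoculation."""
        t = np.asarray(t_h, dtype=float)
        grown = self.od0 * np.exp(self.mu_max * np.clip(t - self.lag_h, 0, None))
        od = np.minimum(grown, self.od_max)
        return od if od.shape else float(od)

    def backscatter_at(self, t_h: np.ndarray | float) -> np.ndarray | float:
        """Noise-free backscatter (a.u.) at time ``t_h``."""
        return self.gain_au_per_od * self.od_at(t_h) + self.offset_au

    def replace(self, **kwargs) -> "GrowthModelConfig":
        return replace(self, **kwargs)


def simulate_batch_growth(
    config: GrowthModelConfig,
    duration_h: float,
    well: str = "A01",
    include_aux_channels: bool = False,
) -> pd.DataFrame:
    """Simulate one well's backscatter time series on the cycle grid.

    Returns a long-format table with columns ``well, time_h, channel,
    value`` and samples at t = 0, cycle, 2*cycle, ... up to and including
    ``duration_h`` (if it lies on the grid). With ``noise_sd_au = 0`` the
    series is deterministic and non-decreasing up to the stop time.

    ``include_aux_channels`` adds smooth pH/DO placeholder traces (a
    monotone pH drop and a DO dip tracking growth); no estimator in this
    package consumes them, they exist so that exported tables have the
    shape of a real multi-channel run.
    """
    if duration_h <= 0:
        raise ParameterError(f"duration_h must be > 0, got {duration_h}")
    cycle_h = config.cycle_min / 60.0
    n = int(math.floor(duration_h / cycle_h + 1e-9)) + 1
    t = np.arange(n) * cycle_h
    signal = np.asarray(config.backscatter_at(t), dtype=float)
    if config.noise_sd_au > 0:
        rng = child_rng(config.seed, "growth", well)
        signal = signal + rng.normal(0.0, config.noise_sd_au, size=t.shape)
    frames = [pd.DataFrame({"well": well, "time_h": t,
                            "channel": "backscatter", "value": signal})]
    if include_aux_channels:
        od = np.asarray(config.od_at(t), dtype=float)
        frac = od / config.od_max
        ph = 7.0 - 0.8 * frac           # smooth acidification placeholder
        do = 100.0 - 70.0 * np.where(t < config.t_stop_h, frac, 0.2)
        frames.append(pd.DataFrame({"well": well, "time_h": t,
                                    "channel": "pH", "value": ph}))
        frames.append(pd.DataFrame({"well": well, "time_h": t,
                                    "channel": "DO", "value": do}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# secreted activity with batch effects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SecretionEffectConfig:
    """Generative model for secreted activities with run-level effects.

    activity = strain mean (+ or x) inducer effect
               + batch effect(batch)        ~ N(0, batch_sd)
               + biological-replicate noise ~ N(0, bio_sd)
               + technical-replicate noise  ~ N(0, tech_sd)

    All replicates sharing a batch (run) ID share one batch-effect draw;
    all technical replicates of a biological replicate share one
    biological draw. Negative results are clamped to 0 and flagged.

    ``iptg_effect`` maps inducer concentration (µM) to an additive shift
    in U/mL, or, with ``iptg_multiplicative=True``, to a unitless factor.
    """

    strain_means: Mapping[str, float] = field(default_factory=dict)
    iptg_effect: Mapping[float, float] = field(default_factory=dict)
    iptg_multiplicative: bool = False
    batch_sd: float = 0.3
    bio_sd: float = 0.1
    tech_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("batch_sd", "bio_sd", "tech_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if any(v < 0 for v in self.strain_means.values()):
            raise ParameterError("strain means must be non-negative")
        object.__setattr__(self, "strain_means", dict(self.strain_means))
        object.__setattr__(self, "iptg_effect", dict(self.iptg_effect))

    def expected(self, strain: str, iptg_uM: float) -> float:
        """Noise-free expected activity for a strain x inducer cell."""
        base = self.strain_means[strain]
        eff = self.iptg_effect.get(iptg_uM, 1.0 if self.iptg_multiplicative else 0.0)
        return base * eff if self.iptg_multiplicative else base + eff


#: twelve Sec-type signal peptides screened in the secretion case study,
#: with plausible mean cutinase activities (U/mL) spanning the observed
#: strong (Bsn, NprB, NprE, YncM) to weak (Epr, Pel, YpjP) range
DEFAULT_SIGNAL_PEPTIDE_MEANS: dict[str, float] = {
    "Bsn": 2.8, "NprB": 2.7, "NprE": 2.9, "YncM": 2.6,
    "AmyE": 1.8, "LipA": 1.6, "Mpr": 1.5, "YoaW": 1.4,
    "YwbN": 1.2, "Epr": 0.6, "Pel": 0.5, "YpjP": 0.4,
}


def make_replicate_design(
    strains: list[str],
    iptg_levels: list[float],
    n_bio: int = 3,
    n_tech: int = 2,
    strategy: str = "spread",
    n_batches: int | None = None,
) -> pd.DataFrame:
    """Build a replicate-design table for :func:`simulate_secretion`.

    Two placement strategies for biological replicates:

    - ``same_plate``: all biological replicates of a strain x inducer cell
      run in the same batch (one plate per inducer level);
    - ``spread``: the i-th biological replicate of every cell runs in
      batch i, so each cell spans ``n_bio`` consecutive batches.

    Returns a table with columns strain, iptg_uM, batch, bio_rep, tech_rep.
    """
    if strategy not in ("same_plate", "spread"):
        raise ValueError(f"unknown strategy {strategy!r}")
    rows = []
    for strain in strains:
        for j, iptg in enumerate(iptg_levels):
            for b in range(n_bio):
                if strategy == "same_plate":
                    batch = f"batch{j + 1}"
                else:
                    batch = f"batch{b + 1}"
                for tr in range(n_tech):
                    rows.append({"strain": strain, "iptg_uM": iptg,
                                 "batch": batch, "bio_rep": b + 1,
                                 "tech_rep": tr + 1})
    df = pd.DataFrame(rows)
    df["strategy"] = strategy
    return df


def simulate_secretion(
    design: pd.DataFrame, config: SecretionEffectConfig
) -> pd.DataFrame:
    """Draw true secreted activities for every row of a replicate design.

    The design must have columns strain, iptg_uM, batch, bio_rep, tech_rep.
    Returns the design with added columns ``activity_U_per_mL`` and
    ``clamped`` (True where a negative draw was clamped to 0). Reproducible
    under a fixed seed; each batch and each (batch, strain, iptg, bio_rep)
    group has its own child RNG stream, so results for one group do not
    depend on the presence of others.
    """
    required = {"strain", "iptg_uM", "batch", "bio_rep", "tech_rep"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design lacks columns: {sorted(missing)}")
    unknown = set(design["strain"]) - set(config.strain_means)
    if unknown:
        raise KeyError(f"unknown strain(s): {sorted(unknown)}")

    batch_effects = {
        b: child_rng(config.seed, "batch", b).normal(0.0, config.batch_sd)
        for b in design["batch"].unique()
    }
    out = design.copy()
    activities = np.empty(len(out))
    for i, row in enumerate(out.itertuples(index=False)):
        mean = config.expected(row.strain, row.iptg_uM)
        bio = child_rng(
            config.seed, "bio", row.batch, row.strain, row.iptg_uM, row.bio_rep
        ).normal(0.0, config.bio_sd)
        tech = child_rng(
            config.seed, "tech", row.batch, row.strain, row.iptg_uM,
            row.bio_rep, row.tech_rep,
        ).normal(0.0, config.tech_sd)
        activities[i] = mean + batch_effects[row.batch] + bio + tech
    out["clamped"] = activities < 0
    out["activity_U_per_mL"] = np.clip(activities, 0.0, None)
    return out


# ---------------------------------------------------------------------------
# assay kinetics
# ---------------------------------------------------------------------------

def simulate_assay_kinetics(
    true_EA: float,
    m_standard: float,
    DF: float,
    read_interval_min: float = 0.5,
    n_reads: int = 20,
    noise_sd: float = 0.0,
    blank_au: float = 0.05,
    seed: int = 0,
    well: str = "assay",
) -> pd.DataFrame:
    """Simulate a 4-nitrophenol absorbance kinetic read for a known activity.

    Inverts the activity relation EA = dA410/dt * (1/m_standard) * DF: the
    absorbance at 410 nm rises linearly at ``true_EA * m_standard / DF``
    a.u./min from the blank level, plus optional Gaussian read noise. The
    first read is the blank level (plus noise).

    Returns a table with columns ``well, time_min, absorbance``.
    """
    if m_standard <= 0:
        raise ParameterError(f"m_standard must be > 0, got {m_standard}")
    if DF < 1:
        raise ParameterError(f"dilution factor must be >= 1, got {DF}")
    if n_reads < 1 or read_interval_min <= 0:
        raise ParameterError("need n_reads >= 1 and a positive read interval")
    t = np.arange(n_reads) * read_interval_min
    slope = true_EA * m_standard / DF
    a = blank_au + slope * t
    if noise_sd > 0:
        rng = child_rng(seed, "assay", well)
        a = a + rng.normal(0.0, noise_sd, size=t.shape)
    return pd.DataFrame({"well": well, "time_min": t, "absorbance": a})
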