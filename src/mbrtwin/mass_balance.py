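"""Exact volume and concentration bookkeeping for liquid handling.

All liquid-handling arithmetic of the platform reduces to three ideal-mixing
primitives: combining two liquids (:func:`mix`), inoculating a target volume
from a cell stock (:func:`inoculate`), and the repeated add-and-remove
dilution chain that governs carry-over of residual disinfectant during
clean-in-place (:func:`residual_chain`).

Concentrations are treated as linearly volume-weighted quantities regardless
of their unit basis (glycerol % w/v, disinfectant/methanol % v/v, substrate
g/L, biomass as OD equivalents, product U/mL, inducer µM). Density
corrections and non-ideal mixing are deliberately out of scope; at the
concentrations handled here (≤ 50 % glycerol, dilute cultures) the linear
approximation is the one practitioners use on the bench, e.g. equal-volume
addition of saline to a 25 % glycerol stock yields 12.5 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Mixture",
    "DilutionChain",
    "mix",
    "inoculate",
    "residual_chain",
]

#: species whose concentration is a percentage and therefore bounded by 100
PERCENT_SPECIES = ("glycerol_pct", "disinfectant_pct", "methanol_pct")


class ParameterError(ValueError):
    """A physically impossible parameter (negative volume, >100 %, ...)."""


@dataclass(frozen=True)
class Mixture:
    """A homogeneous liquid: a volume plus per-species concentrations.

    Parameters
    ----------
    volume_uL:
        Total volume in microlitres; may be zero (an empty well).
    components:
        Mapping species name -> concentration. Unit conventions by suffix:
        ``*_pct`` are percentages (w/v or v/v as the species dictates),
        ``*_g_per_L`` mass concentrations, ``biomass_od`` OD600 equivalents,
        ``*_U_per_mL`` activities, ``*_uM`` molar concentrations.
        Species not listed are at concentration 0.
    """

    volume_uL: float
    components: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.volume_uL < 0:
            raise ParameterError(f"volume must be >= 0, got {self.volume_uL}")
        for species, conc in self.components.items():
            if conc < 0:
                raise ParameterError(f"{species}: concentration {conc} < 0")
            if species in PERCENT_SPECIES and conc > 100:
                raise ParameterError(f"{species}: {conc} % exceeds 100 %")
        # freeze the mapping so Mixture is hashable-by-value in practice
        object.__setattr__(self, "components", dict(self.components))

    def conc(self, species: str) -> float:
        """Concentration of ``species`` (0 if absent)."""
        return self.components.get(species, 0.0)

    def amount(self, species: str) -> float:
        """Extensive amount: concentration x volume (unit: conc-unit * µL)."""
        return self.conc(species) * self.volume_uL

    def with_conc(self, species: str, value: float) -> "Mixture":
        comp = dict(self.components)
        comp[species] = value
        return Mixture(self.volume_uL, comp)

    def split(self, v_uL: float) -> tuple["Mixture", "Mixture"]:
        """Withdraw ``v_uL``; returns (withdrawn, remaining), same composition."""
        if v_uL < 0 or v_uL > self.volume_uL + 1e-9:
            raise ParameterError(
                f"cannot withdraw {v_uL} µL from {self.volume_uL} µL"
            )
        v_uL = min(v_uL, self.volume_uL)
        return (
            Mixture(v_uL, self.components),
            Mixture(self.volume_uL - v_uL, self.components),
        )


def mix(a: Mixture, b: Mixture) -> Mixture:
    """Ideal mixing: volumes add, species amounts are conserved.

    Commutative and associative; mixing with an empty (0 µL) mixture is the
    identity.
    """
    v = a.volume_uL + b.volume_uL
    if v == 0:
        return Mixture(0.0, {})
    species = set(a.components) | set(b.components)
    comp = {s: (a.amount(s) + b.amount(s)) / v for s in species}
    return Mixture(v, comp)


def inoculate(stock_od: float, v_transfer_uL: float, v_medium_uL: float) -> float:
    """OD after transferring ``v_transfer_uL`` of a stock into fresh medium.

    Returns ``stock_od * v_transfer / (v_transfer + v_medium)``, e.g. 20 µL
    of an OD 4 stock into 780 µL medium gives OD 0.1.
    """
    if stock_od < 0 or v_transfer_uL < 0 or v_medium_uL < 0:
        raise ParameterError("negative OD or volume")
    total = v_transfer_uL + v_medium_uL
    if total == 0:
        raise ParameterError("total volume is zero")
    return stock_od * v_transfer_uL / total


@dataclass(frozen=True)
class DilutionChain:
    """Trace of a repeated add-and-remove wash sequence.

    ``trace[i]`` is the residual concentration after wash ``i+1``; the
    closed form is ``c0 * (residual / (residual + wash))**n``.
    """

    c0: float
    residual_uL: float
    wash_uL: float
    trace: tuple[float, ...]

    @property
    def final(self) -> float:
        return self.trace[-1] if self.trace else self.c0

    @property
    def n_washes(self) -> int:
        return len(self.trace)

    def to_frame(self) -> pd.DataFrame:
        """Audit-log form: one row per wash step."""
        rows = [
            {
                "step": i + 1,
                "added_uL": self.wash_uL,
                "residual_uL": self.residual_uL,
                "concentration": c,
            }
            for i, c in enumerate(self.trace)
        ]
        return pd.DataFrame(rows, columns=["step", "added_uL", "residual_uL", "concentration"])


def residual_chain(
    c0: float, residual_uL: float, wash_uL: float, n_washes: int
) -> DilutionChain:
    """Carry-over dilution of a residual liquid by repeated washing.

    Each wash adds ``wash_uL`` of clean liquid to the ``residual_uL`` left
    in the well and removes back down to ``residual_uL``, multiplying the
    contaminant concentration by ``residual / (residual + wash)``. With the
    platform defaults (10 µL residual, 700 µL washes) two washes of a pure
    disinfectant residue leave ~0.02 % (v/v).
    """
    if residual_uL <= 0 or wash_uL <= 0:
        raise ParameterError("residual and wash volumes must be positive")
    if n_washes < 0:
        raise ParameterError("n_washes must be >= 0")
    if c0 < 0:
        raise ParameterError("initial concentration must be >= 0")
    factor = residual_uL / (residual_uL + wash_uL)
    trace = []
    c = c0
    for _ in range(n_washes):
        c *= factor
        trace.append(c)
    return DilutionChain(c0, residual_uL, wash_uL, tuple(trace))


def mix_all(mixtures: Iterable[Mixture]) -> Mixture:
    """Fold :func:`mix` over an iterable (order-independent)."""
    out = Mixture(0.0, {})
    for m in mixtures:
        out = mix(out, m)
    return out
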