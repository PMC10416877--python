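"""Closed-form laboratory math used across the pipeline.

Ionization charges of acid/base groups at a given pH (Henderson–Hasselbalch
degree of dissociation), the percentage-displacement readout of fluorescent
indicator displacement (FID) titrations, the class-threshold labelers that
binarize continuous endpoints (Kd, ΔTm, IC50, selectivity verdicts), and the
FRET-melting stabilizer call used when triaging screened ligands.

All functions are pure and operate on the endpoint's native units
(µM for Kd/IC50, °C for ΔTm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "IonizableGroup",
    "degree_of_dissociation",
    "group_charge",
    "percent_displacement",
    "label_endpoint",
    "fret_stabilizer_call",
    "ENDPOINT_THRESHOLDS",
]

#: Class thresholds per endpoint, on native units.  Positives are strict
#: "<" for the affinity/potency endpoints (Kd < 1 µM, IC50 < 10 µM) and
#: ">=" for thermal stabilization (ΔTm >= 15 °C).
ENDPOINT_THRESHOLDS = {
    "Kd": ("lt", 1.0),      # µM
    "dTm": ("ge", 15.0),    # °C
    "IC50": ("lt", 10.0),   # µM
}

#: ΔTm cut-off (°C) above which a ligand is called a G4 stabilizer in
#: FRET melting follow-up experiments.  Strictly greater-than.
FRET_STABILIZER_CUTOFF = 4.0


@dataclass(frozen=True)
class IonizableGroup:
    """An ionizable group of a ligand: an acid or a base with a known pKa."""

    kind: str  # "acid" | "base"
    pka: float
    ph: float = 7.4  # physiological pH used for docking charge assignment

    def __post_init__(self) -> None:
        if self.kind not in ("acid", "base"):
            raise ValueError(f"unknown ionizable group kind: {self.kind!r}")
        if not math.isfinite(self.pka):
            raise ValueError("pKa must be finite")


def degree_of_dissociation(pka: float, ph: float) -> float:
    """Degree of dissociation α = 1 / (10^(pKa − pH) + 1).

    Strictly decreasing in (pKa − pH); α = 0.5 exactly when pKa = pH.
    """
    if not (math.isfinite(pka) and math.isfinite(ph)):
        raise ValueError("pKa and pH must be finite")
    return 1.0 / (10.0 ** (pka - ph) + 1.0)


def group_charge(group: IonizableGroup) -> float:
    """Fractional charge of an ionizable group at ``group.ph``.

    Acid groups carry −α; base groups carry +(1 − α), with α evaluated
    at the group's own pKa.
    """
    alpha = degree_of_dissociation(group.pka, group.ph)
    if group.kind == "acid":
        return -alpha
    return 1.0 - alpha


def percent_displacement(fa: float, fa0: float) -> float:
    """Percentage displacement PD = 100 − (FA / FA0) · 100.

    ``fa0`` is the fluorescence area before ligand addition; ``fa`` the
    area at the current ligand concentration.  PD = 0 when nothing is
    displaced and 100 when the fluorescent indicator is fully displaced.
    """
    if not (math.isfinite(fa) and math.isfinite(fa0)):
        raise ValueError("fluorescence areas must be finite")
    if fa0 <= 0:
        raise ValueError("FA0 must be positive")
    if fa < 0:
        raise ValueError("FA must be non-negative")
    return 100.0 - (fa / fa0) * 100.0


def label_endpoint(endpoint_name: str, value) -> int:
    """Binary class of a continuous endpoint under the pre-defined cut-offs.

    Kd:   positive (1) iff value < 1 µM
    dTm:  positive (1) iff value >= 15 °C
    IC50: positive (1) iff value < 10 µM
    selectivity: categorical verdict, positive iff "selective"

    Boundary values follow the printed inequalities exactly: Kd = 1 µM and
    IC50 = 10 µM are negative, ΔTm = 15 °C is positive.
    """
    if endpoint_name == "selectivity":
        v = str(value).strip().lower()
        if v in ("selective", "1", "positive"):
            return 1
        if v in ("non-selective", "nonselective", "0", "negative"):
            return 0
        raise ValueError(f"unrecognized selectivity verdict: {value!r}")
    try:
        op, cutoff = ENDPOINT_THRESHOLDS[endpoint_name]
    except KeyError:
        raise ValueError(f"unknown endpoint: {endpoint_name!r}") from None
    x = float(value)
    if op == "lt":
        return int(x < cutoff)
    return int(x >= cutoff)


def fret_stabilizer_call(delta_tm: float) -> bool:
    """Whether a ligand counts as a G4 stabilizer in FRET melting follow-up.

    True iff ΔTm > 4 °C (strict inequality; 4.0 °C is not a stabilizer).
    """
    return float(delta_tm) > FRET_STABILIZER_CUTOFF
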