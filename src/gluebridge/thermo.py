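"""Binding free-energy bookkeeping for ternary-complex cooperativity.

Two closed-form operations:

* conversion of a dissociation constant to a standard binding free energy,
  dG0 = R T ln(Kd / c0) with c0 = 1 mol/L, R = 1.9872e-3 kcal/(mol K) and
  first-order error propagation sd(dG) = R T sd(Kd) / Kd;
* the cooperative free energy of a molecular-glue ternary complex,
  dG0_coop = dG_bind(ternary) - dG_bind(binary target-glue), with the
  component SDs combined in quadrature (independent errors).  Negative
  values indicate positive cooperativity: the glue-bound effector makes
  protein-protein association more favourable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "GAS_CONSTANT_KCAL",
    "STANDARD_CONC",
    "KdMeasurement",
    "EnergyRecord",
    "CoopResult",
    "kd_to_free_energy",
    "cooperativity",
]

#: gas constant in kcal mol^-1 K^-1
GAS_CONSTANT_KCAL = 1.9872e-3

#: standard-state concentration, mol L^-1
STANDARD_CONC = 1.0


@dataclass(frozen=True)
class KdMeasurement:
    """A dissociation constant with uncertainty.

    ``kd`` and ``kd_sd`` are in mol/L; ``temperature`` in K.  The default is
    298.0 K, the common whole-kelvin rounding of 25 C in affinity work: at
    this temperature R*T*ln(12.0e-9) = -10.80 kcal/mol and
    R*T*ln(41.2e-9) = -10.07 kcal/mol at two decimals, matching the
    published conversions for the reference ternary complexes (298.15 K
    would give -10.81/-10.08).
    """

    kd: float
    kd_sd: float = 0.0
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("Kd must be positive")
        if self.kd_sd < 0:
            raise ValueError("Kd SD must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class EnergyRecord:
    """A labelled binding free energy, mean +/- SD, in kcal/mol.

    ``provenance`` records whether the number was computed from a Kd or
    taken as printed (e.g. an MM/GBSA result consumed as input).
    """

    label: str
    dg: float
    sd: float
    provenance: str = "printed"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("SD must be non-negative")

    def rounded(self, ndigits: int = 2) -> "EnergyRecord":
        """Presentation copy rounded to ``ndigits`` decimals."""
        return EnergyRecord(self.label, round(self.dg, ndigits), round(self.sd, ndigits),
                            self.provenance)


@dataclass(frozen=True)
class CoopResult:
    """Cooperative free energy with its components, kcal/mol."""

    dg_coop: float
    sd: float
    ternary: EnergyRecord
    binary: EnergyRecord


def kd_to_free_energy(m: KdMeasurement, label: str = "") -> EnergyRecord:
    """Standard binding free energy from a dissociation constant.

    dG0 = R T ln(Kd / c0); the SD is propagated to first order,
    sd(dG0) = R T sd(Kd) / Kd.  Rounding happens only at presentation.
    """
    rt = GAS_CONSTANT_KCAL * m.temperature
    dg = rt * math.log(m.kd / STANDARD_CONC)
    sd = rt * m.kd_sd / m.kd
    return EnergyRecord(label=label, dg=dg, sd=sd, provenance="computed-from-Kd")


def cooperativity(ternary: EnergyRecord, binary_target_glue: EnergyRecord) -> CoopResult:
    """Cooperative free energy of ternary-complex formation.

    dG0_coop = dG_bind(ternary complex) - dG_bind(target-glue binary
    complex); SDs combine in quadrature.
    """
    dg = ternary.dg - binary_target_glue.dg
    sd = math.sqrt(ternary.sd ** 2 + binary_target_glue.sd ** 2)
    return CoopResult(dg_coop=dg, sd=sd, ternary=ternary, binary=binary_target_glue)
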