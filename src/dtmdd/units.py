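"""Concentration unit handling.

Serum infliximab is assayed in mg/L while the binding model works in molar
units (nM).  Conversion happens exactly once, at the data boundary; model
internals never see mg/L.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Default molar mass of an IgG1 monoclonal antibody (g/mol).
DEFAULT_MW = 149_000.0


@dataclass(frozen=True)
class UnitSystem:
    """Linear mg/L <-> nM conversion for the drug.

    Parameters
    ----------
    mw : float
        Molar mass of the drug in g/mol.  Default 149,000 (IgG1).
    """

    mw: float = DEFAULT_MW

    def __post_init__(self) -> None:
        if not self.mw > 0:
            raise ValueError(f"molar mass must be positive, got {self.mw}")

    @property
    def mgL_to_nM(self) -> float:
        """Multiplicative factor converting mg/L to nM."""
        return 1e6 / self.mw

    def to_nM(self, value_mgL):
        """Convert a concentration (or dose amount, mg -> nmol) to molar units."""
        return value_mgL * (1e6 / self.mw)

    def to_mgL(self, value_nM):
        """Convert a molar concentration back to mass units."""
        return value_nM * (self.mw / 1e6)


def convert_concentration(value_mgL, units: UnitSystem | None = None):
    """mg/L -> nM.  Vectorised; raises on negative scalar input."""
    import numpy as np

    units = units or UnitSystem()
    if np.any(np.asarray(value_mgL) < 0):
        raise ValueError("concentration must be non-negative")
    return units.to_nM(value_mgL)
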