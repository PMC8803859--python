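"""Physical constants in the package's canonical unit system.

Canonical units throughout the library: time in minutes, length in
micrometres (electrode areas in mm**2), concentration in micromolar,
current in nanoamperes.  The Faraday constant is carried pre-converted so
that calibration-slope expressions of the form ``F * A * D / H`` evaluate
directly to nA per uM:

    F [C mol-1] * A [mm2] * (D/H) [um min-1] * c [uM]
      = F * 1e-6 m2 * (1e-6/60) m s-1 * 1e-3 mol m-3
      = F * 1e-15/60 A  ->  * 1e9 nA

hence ``F_eff = 96485.332 * 1e-6 / 60`` nA min mm-2 um-1 uM-1.
"""

from __future__ import annotations

from dataclasses import dataclass

#: CODATA Faraday constant, C per mole of electrons.
FARADAY_C_PER_MOL = 96485.33212

#: Faraday constant in canonical units (nA min mm-2 um-1 uM-1).
FARADAY_CANONICAL = FARADAY_C_PER_MOL * 1e-6 / 60.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Charge-transfer constants of the amperometric readout.

    Parameters
    ----------
    faraday : float
        Charge per mole of electrons, in canonical units
        (nA min mm-2 um-1 uM-1).  The default corresponds to
        96485.332 C mol-1.
    n_electrons : int
        Electrons transferred per H2O2 oxidized.  The current-flux
        relation is written without an explicit electron count (the
        factor is folded into effective constants such as the mass
        transport coefficient), so the default is 1; set 2 to make the
        two-electron stoichiometry explicit.
    """

    faraday: float = FARADAY_CANONICAL
    n_electrons: int = 1

    def __post_init__(self) -> None:
        if self.faraday <= 0:
            raise ValueError("faraday must be positive")
        if self.n_electrons < 1:
            raise ValueError("n_electrons must be >= 1")

    @property
    def f_eff(self) -> float:
        """Effective F (faraday times electron count) in canonical units."""
        return self.faraday * self.n_electrons
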