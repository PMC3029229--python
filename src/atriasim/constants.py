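"""Physical constants and fixed extracellular conditions.

Unit system used throughout the package: mV, ms, mM, nL, pA, pF-free
capacitance in nF.  Diffusion coefficients are stored in um^2/s (their
literature unit) and converted where used.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed physical constants and extracellular ion concentrations.

    F is in C/mol, R in mJ/(mol K), T in K and the extracellular
    concentrations in mM.  ``RTF`` is the thermal voltage R*T/F in mV.
    """

    F: float = 96478.0
    R: float = 8314.0
    T: float = 306.15
    Na_o: float = 130.0
    Ca_o: float = 1.8
    K_o: float = 5.4

    @property
    def RTF(self) -> float:
        return self.R * self.T / self.F

    def nernst(self, z: float, c_out: float, c_in: float) -> float:
        """Nernst equilibrium potential (mV) for valence ``z``."""
        import math

        if c_in <= 0 or c_out <= 0:
            raise ValueError("Nernst potential requires positive concentrations")
        return self.RTF / z * math.log(c_out / c_in)
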