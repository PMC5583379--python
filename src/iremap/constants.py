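"""Physical constants shared by the forward and inverse measurement chains.

A single authoritative definition is used everywhere so that the Biot-Savart
synthesis, the phase encoding and the Ampere-law inversion cannot drift apart.
"""

import math

#: Vacuum permeability, T m / A.
MU_0: float = 4.0e-7 * math.pi

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_PROTON: float = 2.675e8

#: Conversion factor: 1 kV/cm expressed in V/m.
V_PER_M_PER_KV_PER_CM: float = 1.0e5
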