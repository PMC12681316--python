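"""Shared physical constants.

All spatial quantities in this package are expressed in millimetres, field
amplitudes in tesla (with microtesla at user-facing interfaces), currents in
ampere and times in milliseconds unless stated otherwise.
"""

import math

#: Vacuum permeability [T·m/A].
MU0 = 4e-7 * math.pi

#: Relative permeability of the medium surrounding the wire. Tissue and
#: ASTM-phantom gel are nonmagnetic, so this is fixed at 1.
MU_R = 1.0

#: Millimetre → metre conversion.
MM = 1e-3

#: Microtesla → tesla conversion.
UT = 1e-6
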