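"""Unit system and physical constants.

Single source of truth for units used throughout the package:

* energy        eV
* length        angstrom (A)
* time          femtosecond (fs)
* mass          amu (linear coordinates), amu*A^2 (angular coordinates)
* angles        degrees at every external interface, radians internally

With these base units a kinetic energy ``0.5 * m * v**2`` computed from a
mass in amu and a velocity in A/fs comes out in amu*A^2/fs^2; the constant
:data:`KE_TO_EV` converts that to eV.  All engine-internal masses are
pre-multiplied by :data:`KE_TO_EV` so that forces in eV/A divided by an
internal mass give accelerations in A/fs^2 directly.
"""

#: 1 amu * A^2 / fs^2 expressed in eV.
KE_TO_EV = 103.6427

#: Reduced Planck constant in eV * fs.
HBAR = 0.6582120

#: Boltzmann constant in eV / K.
KB = 8.617333262e-5
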