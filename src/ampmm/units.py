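"""Global unit conventions.

Energies in kJ/mol, lengths in Angstrom, charges in units of the elementary
charge e, time in fs, temperature in K, masses in g/mol (u).  Derived
constants below are the only place numerical unit conversions live.
"""

#: Coulomb constant, kJ mol^-1 A e^-2
KE = 138.935458

#: Boltzmann constant (= molar gas constant), kJ mol^-1 K^-1
KB = 0.008314462618

#: Converts (kJ/mol/A) / (g/mol) to acceleration in A/fs^2.
#: 1 kJ/(g*A) = 1e6 m^2/s^2 / A = 0.0001 A/fs^2.
ACC = 1.0e-4

#: Converts (g/mol) * (A/fs)^2 to kJ/mol (inverse of ACC).
KIN = 1.0e4

#: Element masses in g/mol for the small element set used throughout.
MASSES = {
    1: 1.008, 6: 12.011, 7: 14.007, 8: 15.999,
    9: 18.998, 15: 30.974, 16: 32.06, 17: 35.45,
}

#: Element symbols <-> atomic numbers (covers the supported set).
SYMBOLS = {
    1: "H", 6: "C", 7: "N", 8: "O", 9: "F", 15: "P", 16: "S", 17: "Cl",
    28: "Ni",
}
NUMBERS = {v: k for k, v in SYMBOLS.items()}
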