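"""Physical constants and standard atomic masses shared across the package."""

#: Boltzmann constant in kcal mol^-1 K^-1 (the conventional MD unit system).
KB_KCAL_MOL_K: float = 0.0019872041

#: Standard atomic masses in amu, keyed by element symbol.
STANDARD_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}
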