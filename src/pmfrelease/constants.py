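"""Physical constants and shared defaults (molar energy units: kJ/mol, nm, ps, K)."""

#: Boltzmann constant in kJ mol^-1 K^-1 (equals the molar gas constant R).
KB = 0.008314462618

#: Default simulation temperature (physiological), K.
DEFAULT_TEMPERATURE = 310.0

#: Temperature used for alchemical/solvation examples, K.
ALCHEMY_TEMPERATURE = 300.0


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(k_B T) in mol/kJ."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB * temperature)
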