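"""Physical constants and unit conventions.

The package works in kcal/mol, Å, K and ps throughout.
"""

#: Boltzmann constant in kcal/mol/K.
KB = 0.0019872


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(k_B T) in mol/kcal."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB * temperature)
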