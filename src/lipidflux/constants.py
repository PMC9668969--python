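"""Physical constants and package-wide unit conventions.

Units are fixed package-wide: seconds, kcal/mol, kelvin, angstrom, mole
fraction.  Converters belong at the I/O boundary only.
"""

#: Gas constant in kcal/(mol K).
GAS_CONSTANT_KCAL: float = 0.0019872041

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE: float = 303.15


def rt_kcal(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy RT in kcal/mol at ``temperature`` (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return GAS_CONSTANT_KCAL * temperature
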