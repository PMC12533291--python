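"""Physical constants used throughout the package.

Units are kcal, mol, K and Å everywhere; affinities are molar against a 1 M
standard state.
"""

#: Gas constant, kcal·mol⁻¹·K⁻¹.
R_KCAL: float = 1.9872e-3

#: Analysis temperature (K); matches the simulation conditions the grids
#: are assumed to come from.
DEFAULT_TEMPERATURE_K: float = 300.0

#: Standard-state concentration (M) for Kd ↔ ΔG conversion.
STANDARD_CONCENTRATION_M: float = 1.0
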