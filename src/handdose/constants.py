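"""Physical constants used across the package (CODATA 2018 where exact)."""

ELECTRON_REST_MEV = 0.51099895
"""Electron rest-mass energy, MeV."""

ANNIHILATION_PHOTON_MEV = 0.51099895
"""Energy of each annihilation photon, MeV."""

MEV_TO_J = 1.602176634e-13
"""Conversion factor, MeV -> joule (exact)."""

CLASSICAL_ELECTRON_RADIUS_CM = 2.8179403262e-13

AVOGADRO = 6.02214076e23

F18_HALF_LIFE_S = 6600.0
"""Fluorine-18 physical half-life (110 min), seconds."""

F18_BETA_PLUS_FRACTION = 0.967
"""Fluorine-18 positron-emission branching ratio (EC remainder)."""

F18_BETA_ENDPOINT_MEV = 0.6335
"""Fluorine-18 beta-plus endpoint kinetic energy, MeV."""
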