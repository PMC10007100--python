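"""Physical constants shared across the energy-balance and soil modules."""

#: Stefan-Boltzmann constant [W m-2 K-4]
STEFAN_BOLTZMANN = 5.670374419e-8

#: Energy to vaporize a unit mass of water [J kg-1], as used when converting
#: instantaneous latent heat flux (W m-2) to an evaporation rate (mm h-1).
LATENT_HEAT_VAPORIZATION = 2_454_000.0

#: Value used to mark undefined pixels in raster operations. All per-pixel
#: operations propagate NaN.
MISSING = float("nan")

#: Landsat-8 shortwave band names used for broadband albedo.
ALBEDO_BANDS = ("B2", "B3", "B4", "B5", "B6", "B7")

#: Broadband albedo weights per shortwave band (dimensionless). They sum to 1.
ALBEDO_WEIGHTS = {
    "B2": 0.293,
    "B3": 0.274,
    "B4": 0.233,
    "B5": 0.156,
    "B6": 0.033,
    "B7": 0.011,
}
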