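"""Physical constants shared across the package."""

#: Proton gyromagnetic ratio, MHz/T.  Multiplying a chemical shift in ppm by
#: ``GAMMA_MHZ_PER_T * B0`` yields the frequency offset in Hz.
GAMMA_MHZ_PER_T: float = 42.577

#: Temperature coefficient of the water resonance, ppm per degree Celsius,
#: referenced to body temperature.  Water moves downfield as temperature
#: drops, so the apparent water-fat separation grows below 37 C.
WATER_SHIFT_PPM_PER_DEGC: float = -0.01

#: Reference temperature (C) at which packaged fat spectra are calibrated.
REFERENCE_TEMPERATURE_C: float = 37.0
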