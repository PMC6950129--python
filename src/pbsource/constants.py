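"""Reference constants for lead isotope work.

Certified isotope-ratio standards used to calibrate MC-ICP-MS lead
measurements, and the instrument precision envelope that the noise model
in :mod:`pbsource.synthetic` emulates.
"""

# NBS 981 certified common-lead isotope ratios (dimensionless).
NBS981_208_206 = 2.167710
NBS981_207_206 = 0.914750
NBS981_206_204 = 16.9405
NBS981_207_204 = 15.4963
NBS981_208_204 = 36.7219

# NBS 997 thallium standard, used as the internal mass-bias monitor.
NBS997_205TL_203TL = 2.3871

# Repeatability of the lead ratio measurements (relative standard deviation).
MEASUREMENT_REPEATABILITY = {
    "207Pb/206Pb": 0.0002,
    "208Pb/206Pb": 0.0002,
    "206Pb/204Pb": 0.0004,
}

# Overall relative error range of the case-study measurement campaign:
# 0.02% to 0.09%.
NOISE_RELATIVE_SD_MIN = 0.0002
NOISE_RELATIVE_SD_MAX = 0.0009
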