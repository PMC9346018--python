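"""Published per-flexion-angle stress tables of a two-knee virtual
trochleoplasty FE study, used as worked-example inputs for the statistics
operators and as regression anchors for the summary pipeline.

Values are MPa (pressures, Von Mises equivalent stresses), degrees (tilt),
percent (bisect offset) and mm^2 (areas).  Group keys: ``healthy``, the
trochleodysplastic knee ``preop``, and the virtual surgery at correction
factors 0.5 / 1.0 / 1.5.  ``PRESSURE_FILM_REFERENCE`` carries the
pressure-sensitive-film summary statistics (Powers et al.) used for the
literature comparison.
"""

THETAS = (30, 45, 60, 75)

PEAK_PRESSURE = {
    "healthy": {30: 2.17, 45: 1.9, 60: 1.79, 75: 2.0},
    "preop": {30: 2.61, 45: 2.72, 60: 2.45, 75: 1.95},
    0.5: {30: 2.99, 45: 4.16, 60: 2.52, 75: 2.4},
    1.0: {30: 5.41, 45: 3.75, 60: 2.57, 75: 2.36},
    1.5: {30: 4.31, 45: 4.06, 60: 2.7, 75: 2.39},
}

MEAN_PRESSURE = {
    "healthy": {30: 0.85, 45: 0.78, 60: 0.74, 75: 0.76},
    "preop": {30: 1.03, 45: 1.18, 60: 0.94, 75: 0.89},
    0.5: {30: 1.05, 45: 1.32, 60: 1.32, 75: 0.98},
    1.0: {30: 1.2, 45: 1.37, 60: 1.24, 75: 1.0},
    1.5: {30: 1.36, 45: 1.44, 60: 1.41, 75: 1.06},
}

# Von Mises equivalent stress, (patella, trochlea) pairs
PEAK_VMES = {
    "healthy": {30: (0.844, 1.027), 45: (0.724, 0.945), 60: (0.893, 0.834), 75: (1.002, 0.905)},
    "preop": {30: (0.94, 0.939), 45: (1.302, 1.381), 60: (0.919, 1.06), 75: (0.975, 1.067)},
    0.5: {30: (1.719, 1.141), 45: (1.433, 1.948), 60: (1.238, 1.293), 75: (1.025, 1.208)},
    1.0: {30: (1.985, 1.636), 45: (1.395, 1.795), 60: (1.16, 1.338), 75: (0.989, 1.36)},
    1.5: {30: (1.359, 1.608), 45: (1.623, 1.923), 60: (1.336, 1.57), 75: (0.979, 1.204)},
}

MEAN_VMES = {
    "healthy": {30: (0.46, 0.43), 45: (0.43, 0.41), 60: (0.42, 0.41), 75: (0.43, 0.46)},
    "preop": {30: (0.5, 0.47), 45: (0.55, 0.59), 60: (0.47, 0.52), 75: (0.46, 0.52)},
    0.5: {30: (0.49, 0.5), 45: (0.64, 0.69), 60: (0.55, 0.62), 75: (0.52, 0.61)},
    1.0: {30: (0.62, 0.74), 45: (0.63, 0.74), 60: (0.56, 0.65), 75: (0.51, 0.63)},
    1.5: {30: (0.62, 0.7), 45: (0.66, 0.72), 60: (0.61, 0.67), 75: (0.51, 0.57)},
}

ALIGNMENT = {
    "patellar_tilt": {"healthy": 12.0, "preop": 18.0, 0.5: 9.0, 1.0: 7.0, 1.5: 5.0},
    "bisect_offset": {"healthy": 48.5, "preop": 76.0, 0.5: 66.0, 1.0: 58.0, 1.5: 53.0},
}

# pooled (mean, SD) over the four flexion angles
CONTACT_AREA_SUMMARY = {
    "healthy": (640.0, 96.4),
    "preop": (598.1, 37.6),
    "postop": (478.4, 57.2),
}

# pressure-sensitive-film experiments under the same loading protocol
PRESSURE_FILM_REFERENCE = {
    "peak": (1.44, 0.21, 4),
    "mean": (0.66, 0.02, 4),
}
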