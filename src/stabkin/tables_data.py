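"""Embedded reference tables for the three heterocyclic scaffolds.

Relative energies (kcal/mol, vs the reactant; kinds E+ZPE, ΔE°, ΔH°, ΔG°),
RRKM rate constants (s^-1) for the six forward channels, and intermediate
half-lives (s), each at three levels of theory:

    A = CBS-QB3, B = M06-2X/Jun-cc-pVTZ (Jun-cc-pV(T+d)Z for S),
    C = M06-2X/6-311+g(2df,2p)

Values are stored as the printed strings so golden-file comparisons can be
string-exact; :func:`stabkin.fixtures.reference_tables` parses them to floats.
Two obvious typographical artifacts in the source tables (doubled "E−"
exponent markers) are normalized here.
"""

LEVELS = ("A", "B", "C")
LEVEL_NAMES = {
    "A": "CBS-QB3",
    "B": "M06-2X/Jun-cc-pVTZ",
    "C": "M06-2X/6-311+g(2df,2p)",
}
COMPOUNDS = ("pyrrolone", "furanone", "thiophenone")
HETEROATOM = {"pyrrolone": "N", "furanone": "O", "thiophenone": "S"}
TEMPS = ("298.15", "300", "310", "320", "330", "340", "350", "360")
CHANNELS = ("R->IN1", "R->IN4", "IN1->IN2", "IN2->IN3", "IN4->IN3", "IN3->P")
INTERMEDIATES = ("IN1", "IN2", "IN3", "IN4")

# species -> level -> (E+ZPE, dE, dH, dG)
RELATIVE_ENERGIES = {
    "pyrrolone": {
        "R-N":   {"A": ("0.00", "0.00", "0.00", "0.00"),
                  "B": ("0.00", "0.00", "0.00", "0.00"),
                  "C": ("0.00", "0.00", "0.00", "0.00")},
        "IN1-N": {"A": ("30.33", "30.46", "30.46", "30.30"),
                  "B": ("30.50", "30.77", "30.77", "29.39"),
                  "C": ("30.86", "30.94", "30.94", "30.85")},
        "IN2-N": {"A": ("9.40", "9.41", "9.41", "9.41"),
                  "B": ("9.98", "10.04", "10.04", "9.80"),
                  "C": ("9.84", "9.91", "9.91", "9.71")},
        "IN3-N": {"A": ("35.91", "36.03", "36.03", "35.59"),
                  "B": ("35.82", "36.38", "36.38", "34.86"),
                  "C": ("35.63", "36.25", "36.25", "34.63")},
        "IN4-N": {"A": ("39.11", "39.27", "39.27", "39.06"),
                  "B": ("47.87", "48.99", "48.99", "45.98"),
                  "C": ("47.41", "48.53", "48.53", "45.66")},
        "TS1-N": {"A": ("43.65", "43.48", "43.48", "43.92"),
                  "B": ("41.58", "41.43", "41.43", "41.68"),
                  "C": ("41.83", "41.68", "41.68", "42.01")},
        "TS2-N": {"A": ("49.60", "49.35", "49.35", "50.00"),
                  "B": ("49.09", "48.78", "48.78", "49.43"),
                  "C": ("49.23", "48.96", "48.96", "49.55")},
        "TS3-N": {"A": ("45.37", "45.03", "45.03", "45.85"),
                  "B": ("43.79", "43.36", "43.36", "44.24"),
                  "C": ("43.82", "43.43", "43.43", "44.25")},
        "TS4-N": {"A": ("72.07", "71.88", "71.88", "72.43"),
                  "B": ("71.03", "70.85", "70.85", "71.28"),
                  "C": ("71.25", "71.12", "71.12", "71.47")},
        "TS5-N": {"A": ("65.54", "65.42", "65.42", "65.78"),
                  "B": ("62.70", "62.47", "62.47", "63.00"),
                  "C": ("63.55", "63.52", "63.52", "63.59")},
        "TS6-N": {"A": ("67.47", "67.32", "67.32", "67.78"),
                  "B": ("66.69", "66.46", "66.46", "66.97"),
                  "C": ("66.88", "66.68", "66.68", "67.14")},
        "P-N":   {"A": ("17.09", "17.32", "17.32", "17.13"),
                  "B": ("15.18", "15.46", "15.46", "14.99"),
                  "C": ("14.91", "15.18", "15.18", "14.80")},
    },
    "furanone": {
        "R-O":   {"A": ("0.00", "0.00", "0.00", "0.00"),
                  "B": ("0.00", "0.00", "0.00", "0.00"),
                  "C": ("0.00", "0.00", "0.00", "0.00")},
        "IN1-O": {"A": ("45.34", "40.25", "40.25", "37.53"),
                  "B": ("42.67", "42.92", "42.92", "42.39"),
                  "C": ("43.20", "43.90", "43.90", "42.44")},
        "IN2-O": {"A": ("11.77", "11.20", "11.20", "10.95"),
                  "B": ("11.98", "12.03", "12.03", "11.80"),
                  "C": ("11.93", "12.01", "12.01", "11.73")},
        "IN3-O": {"A": ("25.61", "23.84", "23.84", "21.72"),
                  "B": ("23.79", "24.16", "24.16", "23.07"),
                  "C": ("23.58", "23.96", "23.96", "22.86")},
        "IN4-O": {"A": ("43.68", "44.43", "44.43", "41.52"),
                  "B": ("41.64", "42.73", "42.73", "40.06"),
                  "C": ("41.35", "42.42", "42.42", "39.76")},
        "TS1-O": {"A": ("53.14", "52.58", "52.58", "52.24"),
                  "B": ("49.76", "49.77", "49.77", "49.73"),
                  "C": ("50.15", "50.15", "50.15", "50.13")},
        "TS2-O": {"A": ("61.99", "59.22", "59.22", "59.31"),
                  "B": ("58.60", "58.56", "58.56", "58.66"),
                  "C": ("58.90", "58.90", "58.90", "58.92")},
        "TS3-O": {"A": ("50.95", "49.87", "49.87", "50.48"),
                  "B": ("48.33", "47.98", "47.98", "48.66"),
                  "C": ("48.55", "48.22", "48.22", "48.86")},
        "TS4-O": {"A": ("80.46", "77.97", "77.97", "78.23"),
                  "B": ("76.94", "76.86", "76.86", "77.06"),
                  "C": ("77.45", "77.36", "77.36", "77.57")},
        "TS5-O": {"A": ("79.34", "77.85", "77.85", "77.65"),
                  "B": ("74.87", "74.99", "74.99", "74.81"),
                  "C": ("75.43", "75.58", "75.58", "75.34")},
        "TS6-O": {"A": ("67.51", "63.45", "63.45", "62.55"),
                  "B": ("62.60", "62.95", "62.95", "61.99"),
                  "C": ("62.70", "63.08", "63.08", "62.05")},
        "P-O":   {"A": ("20.00", "21.33", "21.33", "20.79"),
                  "B": ("19.17", "19.51", "19.51", "18.91"),
                  "C": ("19.06", "19.39", "19.39", "18.81")},
    },
    "thiophenone": {
        "R-S":   {"A": ("0.00", "0.00", "0.00", "0.00"),
                  "B": ("0.00", "0.00", "0.00", "0.00"),
                  "C": ("0.00", "0.00", "0.00", "0.00")},
        "IN1-S": {"A": ("40.02", "40.29", "40.29", "39.80"),
                  "B": ("39.91", "40.13", "40.13", "39.78"),
                  "C": ("40.48", "40.74", "40.74", "40.32")},
        "IN2-S": {"A": ("10.94", "11.06", "11.06", "10.64"),
                  "B": ("11.96", "12.10", "12.10", "11.61"),
                  "C": ("11.93", "12.07", "12.07", "11.58")},
        "IN3-S": {"A": ("30.75", "31.30", "31.30", "29.22"),
                  "B": ("33.22", "33.41", "33.41", "32.53"),
                  "C": ("33.09", "33.29", "33.29", "32.38")},
        "IN4-S": {"A": ("47.04", "48.09", "48.09", "45.36"),
                  "B": ("43.96", "45.14", "45.14", "41.67"),
                  "C": ("44.40", "45.28", "45.28", "42.99")},
        "TS1-S": {"A": ("47.14", "47.10", "47.10", "47.24"),
                  "B": ("45.66", "45.56", "45.57", "45.82"),
                  "C": ("46.24", "46.17", "46.17", "46.38")},
        "TS2-S": {"A": ("50.95", "50.84", "50.84", "51.16"),
                  "B": ("51.61", "51.46", "51.46", "51.86"),
                  "C": ("52.17", "52.03", "52.03", "52.41")},
        "TS3-S": {"A": ("44.80", "44.53", "44.53", "45.11"),
                  "B": ("43.14", "42.81", "42.81", "43.51"),
                  "C": ("43.46", "43.14", "43.14", "43.81")},
        "TS4-S": {"A": ("69.25", "69.15", "69.15", "69.43"),
                  "B": ("69.31", "69.19", "69.20", "69.50"),
                  "C": ("70.01", "69.92", "69.92", "70.18")},
        "TS5-S": {"A": ("61.19", "61.33", "61.33", "61.18"),
                  "B": ("60.54", "60.56", "60.56", "60.65"),
                  "C": ("61.23", "61.27", "61.27", "61.33")},
        "TS6-S": {"A": ("57.88", "58.06", "58.06", "57.44"),
                  "B": ("55.79", "55.80", "55.80", "55.87"),
                  "C": ("57.03", "57.10", "57.10", "57.05")},
        "P-S":   {"A": ("10.35", "10.73", "10.73", "10.08"),
                  "B": ("9.78", "10.21", "10.21", "9.37"),
                  "C": ("10.04", "10.46", "10.46", "9.66")},
    },
}

# compound -> level -> T -> six channel rates (s^-1) in CHANNELS order
RATE_CONSTANTS = {
    "pyrrolone": {
        "A": {
            "298.15": ("2.49E-19", "1.76E-33", "1.52E+04", "8.50E-02", "1.11E+02", "1.01E-14"),
            "300":    ("3.84E-19", "3.06E-33", "1.63E+04", "9.50E-02", "1.27E+02", "1.31E-14"),
            "310":    ("3.64E-18", "5.52E-32", "2.32E+04", "1.70E-01", "2.50E+02", "5.16E-14"),
            "320":    ("3.02E-17", "8.79E-31", "3.25E+04", "2.97E-01", "4.62E+02", "1.92E-13"),
            "330":    ("2.23E-16", "1.24E-29", "4.47E+04", "5.06E-01", "8.08E+02", "6.74E-13"),
            "340":    ("1.47E-15", "1.57E-28", "6.05E+04", "8.42E-01", "1.35E+03", "2.25E-12"),
            "350":    ("8.73E-15", "1.78E-27", "8.06E+04", "1.37E+00", "2.15E+03", "7.13E-12"),
            "360":    ("4.72E-14", "1.82E-26", "1.06E+05", "2.18E+00", "3.30E+03", "2.15E-11"),
        },
        "B": {
            "298.15": ("6.03E-18", "2.99E-32", "2.78E+03", "2.89E-02", "5.92E+02", "1.56E-14"),
            "300":    ("9.17E-18", "5.33E-32", "2.98E+03", "3.22E-02", "6.31E+02", "1.97E-14"),
            "310":    ("8.09E-17", "1.10E-30", "4.23E+03", "5.69E-02", "8.83E+02", "6.85E-14"),
            "320":    ("6.27E-16", "1.94E-29", "5.93E+03", "9.81E-02", "1.22E+03", "2.28E-13"),
            "330":    ("4.31E-15", "2.91E-28", "8.18E+03", "1.66E-01", "1.66E+03", "7.31E-13"),
            "340":    ("2.66E-14", "3.81E-27", "1.11E+04", "2.74E-01", "2.24E+03", "2.25E-12"),
            "350":    ("1.48E-13", "4.37E-26", "1.49E+04", "4.44E-01", "2.98E+03", "6.63E-12"),
            "360":    ("7.53E-13", "4.45E-25", "1.97E+04", "7.07E-01", "3.92E+03", "1.88E-11"),
        },
        "C": {
            "298.15": ("3.43E-18", "1.48E-32", "1.58E+04", "1.32E-01", "4.86E+02", "2.35E-14"),
            "300":    ("5.23E-18", "2.65E-32", "1.68E+04", "1.46E-01", "5.20E+02", "2.96E-14"),
            "310":    ("4.69E-17", "5.60E-31", "2.31E+04", "2.45E-01", "7.45E+02", "1.01E-13"),
            "320":    ("3.68E-16", "1.00E-29", "3.14E+04", "4.04E-01", "1.05E+03", "3.37E-13"),
            "330":    ("2.57E-15", "1.55E-28", "4.21E+04", "6.54E-01", "1.46E+03", "1.08E-12"),
            "340":    ("1.60E-14", "2.08E-27", "5.56E+04", "1.04E+00", "1.99E+03", "3.35E-12"),
            "350":    ("9.04E-14", "2.44E-26", "7.26E+04", "1.64E+00", "2.68E+03", "1.00E-11"),
            "360":    ("4.65E-13", "2.55E-25", "9.38E+04", "2.53E+00", "3.56E+03", "2.90E-11"),
        },
    },
    "furanone": {
        "A": {
            "298.15": ("1.09E-25", "6.92E-42", "2.04E+02", "1.03E-02", "5.20E+05", "1.80E-16"),
            "300":    ("1.87E-25", "1.26E-41", "2.21E+02", "1.15E-02", "5.69E+05", "2.37E-16"),
            "310":    ("3.02E-24", "3.71E-40", "3.33E+02", "2.08E-02", "8.94E+05", "9.81E-16"),
            "320":    ("4.14E-23", "1.02E-38", "4.91E+02", "3.67E-02", "1.32E+06", "3.81E-15"),
            "330":    ("4.86E-22", "2.37E-37", "7.10E+02", "6.34E-02", "1.85E+06", "1.39E-14"),
            "340":    ("4.96E-21", "4.95E-36", "1.01E+03", "1.07E-01", "2.46E+06", "4.80E-14"),
            "350":    ("4.46E-20", "9.08E-35", "1.41E+03", "1.78E-01", "3.15E+06", "1.57E-13"),
            "360":    ("3.55E-19", "1.48E-33", "1.95E+03", "2.89E-01", "3.91E+06", "4.86E-13"),
        },
        "B": {
            "298.15": ("3.85E-24", "8.63E-40", "5.35E+04", "3.99E+00", "1.85E+05", "5.17E-12"),
            "300":    ("6.45E-24", "1.61E-39", "5.61E+04", "4.30E+00", "2.05E+05", "6.29E-12"),
            "310":    ("9.39E-23", "4.11E-38", "7.23E+04", "6.44E+00", "3.41E+05", "1.80E-11"),
            "320":    ("1.16E-21", "9.20E-37", "9.26E+04", "9.57E+00", "5.34E+05", "5.03E-11"),
            "330":    ("1.24E-20", "1.82E-35", "1.18E+05", "1.41E+01", "7.88E+05", "1.38E-10"),
            "340":    ("1.15E-19", "3.22E-34", "1.50E+05", "2.07E+01", "1.11E+06", "3.68E-10"),
            "350":    ("9.39E-19", "5.09E-33", "1.89E+05", "3.01E+01", "1.49E+06", "9.59E-10"),
            "360":    ("6.86E-18", "7.21E-32", "2.37E+05", "4.36E+01", "1.92E+06", "2.43E-09"),
        },
        "C": {
            "298.15": ("2.37E-24", "8.77E-40", "4.38E+04", "3.71E+00", "1.67E+05", "6.95E-14"),
            "300":    ("3.98E-24", "1.62E-39", "4.58E+04", "3.99E+00", "1.85E+05", "8.68E-14"),
            "310":    ("5.90E-23", "4.01E-38", "5.82E+04", "5.84E+00", "3.17E+05", "2.85E-13"),
            "320":    ("7.40E-22", "8.78E-37", "7.36E+04", "8.49E+00", "5.07E+05", "9.05E-13"),
            "330":    ("7.99E-21", "1.71E-35", "9.25E+04", "1.23E+01", "7.64E+05", "2.78E-12"),
            "340":    ("7.51E-20", "2.97E-34", "1.16E+05", "1.76E+01", "1.09E+06", "8.29E-12"),
            "350":    ("6.23E-19", "4.64E-33", "1.44E+05", "2.50E+01", "1.49E+06", "2.39E-11"),
            "360":    ("4.61E-18", "6.51E-32", "1.78E+05", "3.54E+01", "1.95E+06", "6.66E-11"),
        },
    },
    "thiophenone": {
        "A": {
            "298.15": ("5.66E-22", "5.13E-32", "7.30E+07", "1.98E+03", "1.75E+08", "1.43E-09"),
            "300":    ("9.13E-22", "9.47E-32", "7.39E+07", "2.06E+03", "1.60E+08", "1.73E-09"),
            "310":    ("1.10E-20", "2.31E-30", "7.89E+07", "2.56E+03", "1.45E+08", "4.74E-09"),
            "320":    ("1.15E-19", "4.69E-29", "8.41E+07", "3.19E+03", "1.32E+08", "1.26E-08"),
            "330":    ("1.04E-18", "8.01E-28", "8.97E+07", "3.96E+03", "1.19E+08", "3.23E-08"),
            "340":    ("8.29E-18", "1.17E-26", "9.55E+07", "4.93E+03", "1.08E+08", "8.03E-08"),
            "350":    ("5.89E-17", "1.47E-25", "1.02E+08", "6.12E+03", "9.67E+07", "1.94E-07"),
            "360":    ("3.77E-16", "1.62E-24", "1.08E+08", "7.61E+03", "8.67E+07", "4.53E-07"),
        },
        "B": {
            "298.15": ("4.21E-21", "1.77E-31", "3.16E+07", "4.30E+03", "3.43E+06", "1.54E-08"),
            "300":    ("6.72E-21", "3.23E-31", "3.22E+07", "4.48E+03", "3.51E+06", "1.81E-08"),
            "310":    ("7.68E-20", "7.44E-30", "3.51E+07", "5.59E+03", "4.01E+06", "4.31E-08"),
            "320":    ("7.56E-19", "1.43E-28", "3.82E+07", "6.99E+03", "4.54E+06", "1.01E-07"),
            "330":    ("6.50E-18", "2.32E-27", "4.17E+07", "8.77E+03", "5.11E+06", "2.34E-07"),
            "340":    ("4.93E-17", "3.22E-26", "4.55E+07", "1.10E+04", "5.74E+06", "5.30E-07"),
            "350":    ("3.34E-16", "3.89E-25", "4.96E+07", "1.38E+04", "6.41E+06", "1.18E-06"),
            "360":    ("2.04E-15", "4.11E-24", "5.41E+07", "1.73E+04", "7.13E+06", "2.56E-06"),
        },
        "C": {
            "298.15": ("1.65E-21", "4.53E-32", "2.88E+07", "2.98E+03", "1.11E+07", "1.08E-08"),
            "300":    ("2.66E-21", "8.34E-32", "2.93E+07", "3.10E+03", "1.15E+07", "1.27E-08"),
            "310":    ("3.14E-20", "2.00E-30", "3.19E+07", "3.87E+03", "1.34E+07", "3.03E-08"),
            "320":    ("3.18E-19", "4.00E-29", "3.48E+07", "4.85E+03", "1.54E+07", "7.15E-08"),
            "330":    ("2.81E-18", "6.74E-28", "3.80E+07", "6.08E+03", "1.77E+07", "1.66E-07"),
            "340":    ("2.19E-17", "9.72E-27", "4.14E+07", "7.63E+03", "2.02E+07", "3.77E-07"),
            "350":    ("1.52E-16", "1.21E-25", "4.52E+07", "9.59E+03", "2.30E+07", "8.39E-07"),
            "360":    ("9.51E-16", "1.32E-24", "4.93E+07", "1.20E+04", "2.60E+07", "1.83E-06"),
        },
    },
}

# compound -> level -> T -> four intermediate half-lives (s) in INTERMEDIATES order
HALF_LIVES = {
    "pyrrolone": {
        "A": {
            "298.15": ("1.83E-08", "7.90E+00", "4.18E+01", "5.08E-04"),
            "300":    ("1.78E-08", "7.06E+00", "3.67E+01", "4.51E-04"),
            "310":    ("1.51E-08", "3.93E+00", "1.84E+01", "2.47E-04"),
            "320":    ("1.29E-08", "2.24E+00", "9.56E+00", "1.43E-04"),
            "330":    ("1.11E-08", "1.31E+00", "5.12E+00", "8.72E-05"),
            "340":    ("9.61E-09", "7.88E-01", "2.82E+00", "5.54E-05"),
            "350":    ("8.36E-09", "4.83E-01", "1.60E+00", "3.66E-05"),
            "360":    ("7.31E-09", "3.02E-01", "9.26E-01", "2.50E-05"),
        },
        "B": {
            "298.15": ("1.22E-08", "2.36E+01", "6.28E+01", "5.76E-06"),
            "300":    ("1.20E-08", "2.12E+01", "5.55E+01", "5.57E-06"),
            "310":    ("1.07E-08", "1.20E+01", "2.91E+01", "4.66E-06"),
            "320":    ("9.61E-09", "6.92E+00", "1.57E+01", "3.91E-06"),
            "330":    ("8.63E-09", "4.09E+00", "8.69E+00", "3.30E-06"),
            "340":    ("7.77E-09", "2.47E+00", "4.94E+00", "2.79E-06"),
            "350":    ("7.00E-09", "1.52E+00", "2.88E+00", "2.37E-06"),
            "360":    ("6.33E-09", "9.53E-01", "1.72E+00", "2.02E-06"),
        },
        "C": {
            "298.15": ("1.69E-09", "5.19E+00", "1.67E+01", "8.74E-06"),
            "300":    ("1.66E-09", "4.71E+00", "1.48E+01", "8.38E-06"),
            "310":    ("1.50E-09", "2.80E+00", "8.11E+00", "6.72E-06"),
            "320":    ("1.37E-09", "1.69E+00", "4.54E+00", "5.42E-06"),
            "330":    ("1.25E-09", "1.04E+00", "2.60E+00", "4.40E-06"),
            "340":    ("1.14E-09", "6.54E-01", "1.52E+00", "3.60E-06"),
            "350":    ("1.04E-09", "4.16E-01", "9.09E-01", "2.97E-06"),
            "360":    ("9.55E-10", "2.69E-01", "5.53E-01", "2.46E-06"),
        },
    },
    "furanone": {
        "A": {
            "298.15": ("3.70E-07", "6.72E+01", "2.74E+05", "1.33E-06"),
            "300":    ("3.59E-07", "6.00E+01", "2.37E+05", "1.22E-06"),
            "310":    ("3.04E-07", "3.32E+01", "1.10E+05", "7.75E-07"),
            "320":    ("2.58E-07", "1.88E+01", "5.22E+04", "5.25E-07"),
            "330":    ("2.21E-07", "1.09E+01", "2.55E+04", "3.75E-07"),
            "340":    ("1.90E-07", "6.45E+00", "1.28E+04", "2.82E-07"),
            "350":    ("1.64E-07", "3.89E+00", "6.56E+03", "2.20E-07"),
            "360":    ("1.42E-07", "2.39E+00", "3.45E+03", "1.77E-07"),
        },
        "B": {
            "298.15": ("7.83E-11", "1.74E-01", "1.98E-01", "3.75E-06"),
            "300":    ("7.78E-11", "1.61E-01", "1.83E-01", "3.39E-06"),
            "310":    ("7.55E-11", "1.08E-01", "1.20E-01", "2.03E-06"),
            "320":    ("7.31E-11", "7.24E-02", "8.00E-02", "1.30E-06"),
            "330":    ("7.08E-11", "4.90E-02", "5.36E-02", "8.80E-07"),
            "340":    ("6.86E-11", "3.35E-02", "3.62E-02", "6.27E-07"),
            "350":    ("6.64E-11", "2.30E-02", "2.46E-02", "4.67E-07"),
            "360":    ("6.42E-11", "1.59E-02", "1.69E-02", "3.60E-07"),
        },
        "C": {
            "298.15": ("1.54E-10", "1.87E-01", "1.09E+02", "4.16E-06"),
            "300":    ("1.54E-10", "1.74E-01", "9.87E+01", "3.74E-06"),
            "310":    ("1.49E-10", "1.19E-01", "5.77E+01", "2.19E-06"),
            "320":    ("1.45E-10", "8.16E-02", "3.40E+01", "1.37E-06"),
            "330":    ("1.41E-10", "5.65E-02", "2.03E+01", "9.08E-07"),
            "340":    ("1.37E-10", "3.94E-02", "1.22E+01", "6.35E-07"),
            "350":    ("1.33E-10", "2.77E-02", "7.37E+00", "4.66E-07"),
            "360":    ("1.30E-10", "1.96E-02", "4.50E+00", "3.55E-07"),
        },
    },
    "thiophenone": {
        "A": {
            "298.15": ("6.78E-11", "3.48E-04", "1.91E-02", "3.86E-09"),
            "300":    ("6.76E-11", "3.34E-04", "1.79E-02", "4.23E-09"),
            "310":    ("6.67E-11", "2.69E-04", "1.25E-02", "4.67E-09"),
            "320":    ("6.59E-11", "2.16E-04", "8.75E-03", "5.14E-09"),
            "330":    ("6.52E-11", "1.74E-04", "6.13E-03", "5.71E-09"),
            "340":    ("6.45E-11", "1.39E-04", "4.31E-03", "6.30E-09"),
            "350":    ("6.39E-11", "1.12E-04", "3.04E-03", "7.04E-09"),
            "360":    ("6.34E-11", "9.01E-05", "2.15E-03", "7.86E-09"),
        },
        "B": {
            "298.15": ("1.50E-11", "1.61E-04", "3.24E-04", "2.00E-07"),
            "300":    ("1.49E-11", "1.55E-04", "3.07E-04", "1.96E-07"),
            "310":    ("1.48E-11", "1.24E-04", "2.32E-04", "1.71E-07"),
            "320":    ("1.47E-11", "9.90E-05", "1.76E-04", "1.51E-07"),
            "330":    ("1.45E-11", "7.89E-05", "1.33E-04", "1.34E-07"),
            "340":    ("1.44E-11", "6.29E-05", "1.01E-04", "1.19E-07"),
            "350":    ("1.43E-11", "5.01E-05", "7.73E-05", "1.07E-07"),
            "360":    ("1.42E-11", "3.99E-05", "5.92E-05", "9.58E-08"),
        },
        "C": {
            "298.15": ("1.63E-11", "2.33E-04", "5.88E-04", "6.16E-08"),
            "300":    ("1.63E-11", "2.23E-04", "5.57E-04", "5.98E-08"),
            "310":    ("1.61E-11", "1.79E-04", "4.16E-04", "5.13E-08"),
            "320":    ("1.60E-11", "1.43E-04", "3.11E-04", "4.43E-08"),
            "330":    ("1.58E-11", "1.14E-04", "2.33E-04", "3.85E-08"),
            "340":    ("1.57E-11", "9.07E-05", "1.75E-04", "3.37E-08"),
            "350":    ("1.55E-11", "7.22E-05", "1.32E-04", "2.97E-08"),
            "360":    ("1.54E-11", "5.74E-05", "9.96E-05", "2.62E-08"),
        },
    },
}
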