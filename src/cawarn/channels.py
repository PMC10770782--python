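"""Channel vocabulary shared by every stage of the pipeline."""

# The seven vital signs recorded at the bedside, in fixed order.
VITAL_CHANNELS = ["HR", "SBP", "DBP", "MBP", "TEMP", "RR", "SPO2"]

# Early-warning subscore channels derived hourly from TEMP and SPO2.
EWS_CHANNELS = ["EWS_TEMP", "EWS_SPO2"]

# Full grid channel order: 7 vitals + 2 EWS subscores (C = 9).
GRID_CHANNELS = VITAL_CHANNELS + EWS_CHANNELS

# Physiologically acceptable ranges (closed intervals); observations outside
# are treated as recording artifacts and removed before bucketing.
DEFAULT_ACCEPTABLE_RANGES = {
    "HR": (20.0, 300.0),
    "SBP": (30.0, 300.0),
    "DBP": (10.0, 200.0),
    "MBP": (20.0, 250.0),
    "TEMP": (30.0, 43.0),
    "RR": (4.0, 60.0),
    "SPO2": (50.0, 100.0),
}

# Early-warning band tables.  Each entry is a list of (upper_bound, score)
# pairs scanned in order; a value <= upper_bound takes that score, values
# above every bound take the final score.  Score 0 marks the normal band and
# scores grow toward abnormality on each side (0-3).
DEFAULT_EWS_BANDS = {
    "TEMP": {"bounds": [(35.0, 3), (36.0, 1), (38.0, 0), (39.0, 1)], "above": 2},
    "SPO2": {"bounds": [(91.0, 3), (93.0, 2), (95.0, 1)], "above": 0},
}
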