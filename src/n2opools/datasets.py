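"""Reference data from the 12-day DENIS grassland-soil incubation.

These are the printed observations the package's default synthetic
scenarios emulate and against which summaries are checked: treatment-mean
cumulative gas emissions over the per-gas peak windows, the calibrated
cubic pool-mixing functions for the 1c (33 % amended area) and 3c (100 %)
treatments, and the measured N2O isotopocule time series of the unlabelled
vessels.  They are inputs to the pipeline, not outputs of it.
"""

from __future__ import annotations

import pandas as pd

from .tracer import CubicMixingFunction

#: Calibrated pool-mixing cubics (percent of emitted N2O from the
#: fertiliser pool vs days after amendment), from the 15N-labelled vessels.
MIXING_1C = CubicMixingFunction(a3=0.148, a2=-2.9435, a1=10.892, a0=55.28,
                                r_squared=0.8532, treatment="1c")
MIXING_3C = CubicMixingFunction(a3=0.092, a2=-1.8938, a1=8.5897, a0=59.56,
                                r_squared=0.8514, treatment="3c")

CALIBRATED_MIXING = {"1c": MIXING_1C, "3c": MIXING_3C}

#: Treatment-mean cumulative emissions (kg N ha-1; CO2 as kg C ha-1) over
#: the standard windows: NO day 0-4, N2O day 0-10, N2 day 4.5-9.5,
#: CO2 day 0-10.  "Total N" is the reported NO + N2O + N2 denitrification
#: total (its own windows differ slightly from the component windows).
_CUMULATIVE = {
    "1c": {"NO": 0.0079, "N2O": 6.73, "N2": 2.88, "CO2": 192.23, "Total N": 9.46},
    "3c": {"NO": 0.0183, "N2O": 19.49, "N2": 5.91, "CO2": 313.66, "Total N": 26.12},
    "control": {"NO": 0.0018, "N2O": 1.14, "N2": 3.02, "CO2": 122.41, "Total N": 4.28},
}

#: Measured isotopocule descriptors of emitted N2O in the unlabelled
#: vessels: columns are days, then delta18O / delta15N-bulk / SP (per mil)
#: per treatment.
_ISOTOPOCULES = [
    # day, (d18O, d15N-bulk, SP) for 1c, 3c, control
    (0,  25.6, -23.4, -1.6,   24.0, -23.3, -4.9,   39.7, -23.8, 22.4),
    (2,  21.4, -18.0, -6.0,   21.7, -16.9, -5.7,   18.9, -26.0, -4.1),
    (4,  37.3,  -1.1, -6.3,   38.9,  -5.5, -5.5,   30.1,  -8.1, -3.7),
    (6,  43.3,  10.4,  3.6,   41.7,  -1.2,  1.8,   31.1,  10.4,  3.9),
    (9,  39.6,  -4.2,  7.0,   42.4,   1.0,  3.1,   31.9, -19.8,  6.4),
    (11, 42.1,  51.8,  9.4,   42.1,   1.7,  4.3,   37.9, -20.7, 22.9),
]


def reference_cumulative_emissions() -> pd.DataFrame:
    """Cumulative-emission table: rows NO/N2O/N2/CO2/Total N, columns treatments."""
    return pd.DataFrame(_CUMULATIVE)


def reference_isotopocules() -> pd.DataFrame:
    """Long-format measured isotopocule series (unlabelled vessels)."""
    rows = []
    for day, *vals in _ISOTOPOCULES:
        for i, treatment in enumerate(("1c", "3c", "control")):
            d18o, dbulk, sp = vals[3 * i: 3 * i + 3]
            rows.append({"treatment": treatment, "time_days": float(day),
                         "delta_o18": d18o, "delta_bulk": dbulk, "sp": sp})
    return pd.DataFrame(rows)


#: Soil NO3--N content before priming (mg N per g dry soil); the basis of
#: the default native-pool nitrate stock.
SOIL_NO3_MG_PER_G_PRE_PRIMING = 4.6e-2
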