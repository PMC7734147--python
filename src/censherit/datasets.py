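"""Published per-event descriptive statistics of the sequential-slaughter
salmon experiment, for worked examples and accounting checks.

These are the printed summary numbers of the SW (same-body-weight) group of
the two year classes: per sampling/slaughter event, the age in days from
first feeding, how many fish were weighed, their mean body weight and mean
growth rate, and how many were actually slaughtered.  Event 0 is the initial
weighing of every fish; events 1–5 slaughtered only fish above the weight
threshold (4.2 kg at event 1, 4.4 kg after); event 6 slaughtered everyone
left.  The difference between recorded and slaughtered counts at an event is
the number of fish weighed just below the threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: (year_class, event, age_days, n_recorded, mean_bw_kg, mean_gr_gday, n_slaughtered, threshold_kg)
_ROWS = [
    ("yc1", 0, 700, 1276, 2.44, 3.49, 0, None),
    ("yc1", 1, 805, 250, 4.41, 5.48, 167, 4.2),
    ("yc1", 2, 840, 481, 4.31, 5.13, 215, 4.4),
    ("yc1", 3, 861, 449, 4.44, 5.15, 257, 4.4),
    ("yc1", 4, 887, 579, 4.23, 4.77, 290, 4.4),
    ("yc1", 5, 923, 268, 4.55, 4.92, 143, 4.4),
    ("yc1", 6, 958, 156, 4.05, 4.22, 156, None),
    ("yc2", 0, 1079, 1418, 2.73, 2.53, 0, None),
    ("yc2", 1, 1142, 349, 3.75, 3.28, 131, 4.2),
    ("yc2", 2, 1190, 233, 4.87, 4.10, 203, 4.4),
    ("yc2", 3, 1234, 359, 4.68, 3.79, 268, 4.4),
    ("yc2", 4, 1265, 486, 4.54, 3.59, 308, 4.4),
    ("yc2", 5, 1295, 282, 4.35, 3.36, 143, 4.4),
    ("yc2", 6, 1330, 333, 4.05, 3.04, 333, None),
]


def slaughter_summary() -> pd.DataFrame:
    """The published per-event summary as a tidy table."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "year_class",
            "event_index",
            "age_days",
            "n_recorded",
            "mean_bw_kg",
            "mean_gr_gday",
            "n_slaughtered",
            "threshold_kg",
        ],
    )


def summary_growth_records() -> pd.DataFrame:
    """Expand the published counts into a growth-record-shaped table.

    Each event contributes ``n_slaughtered`` rows with status
    ``observed_slaughtered`` and ``n_recorded - n_slaughtered`` rows with
    status ``observed_below_threshold``; per-fish identity and weights beyond
    the published event means are not reconstructed (every row carries the
    event mean), so the table supports accounting checks, not model fitting.
    """
    rows = []
    fish = 0
    for yc, ev, age, n_rec, bw, _gr, n_sl, thr in _ROWS:
        for i in range(n_rec):
            fish += 1
            rows.append(
                {
                    "animal": f"{yc}F{fish:05d}",
                    "event_index": ev,
                    "age_days": age,
                    "body_weight_g": bw * 1000.0,
                    "threshold_g": thr * 1000.0 if thr is not None else np.nan,
                    "status": "observed_slaughtered" if i < n_sl else "observed_below_threshold",
                    "sampling_group": f"{yc}:ev{ev}",
                }
            )
    df = pd.DataFrame(rows)
    df["growth_rate"] = df["body_weight_g"] / df["age_days"]
    df["upper_bound"] = np.nan
    return df
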