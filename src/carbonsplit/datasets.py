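"""Small published datasets shipped with the package.

Currently: the printed weekly metro passenger volumes for Nanjing
(25 Nov 2022 – 8 Jan 2023, million people/day), the one real-data table the
day-of-week statistics can be checked against end to end. Dashes in the
printed table (weeks without an observation for that weekday) are omitted.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["nanjing_metro_daily", "NANJING_METRO_WEEKLY"]

# weekday -> printed weekly values, in week order; week 1 is the calendar week
# (Sunday-start) containing the first observation, Saturday 2022-11-26.
NANJING_METRO_WEEKLY: dict[str, list[tuple[int, float]]] = {
    "Sunday": [(2, 1.00), (3, 1.26), (4, 1.62), (5, 0.93), (6, 0.55), (7, 1.28), (8, 1.43)],
    "Monday": [(2, 0.86), (3, 0.96), (4, 1.57), (5, 0.65), (6, 0.60), (7, 1.12), (8, 1.34)],
    "Tuesday": [(2, 1.75), (3, 2.05), (4, 2.38), (5, 0.97), (6, 1.03), (7, 1.07)],
    "Wednesday": [(2, 1.79), (3, 2.10), (4, 2.23), (5, 0.78), (6, 1.11), (7, 1.70)],
    "Thursday": [(2, 1.90), (3, 2.12), (4, 2.09), (5, 0.68), (6, 1.22), (7, 1.74)],
    "Friday": [(2, 1.97), (3, 2.14), (4, 1.90), (5, 0.62), (6, 1.22), (7, 1.77)],
    "Saturday": [(1, 1.81), (2, 2.16), (3, 2.33), (4, 1.72), (5, 0.67), (6, 1.40), (7, 1.90)],
}

_WEEK1_SUNDAY = pd.Timestamp("2022-11-20")  # Sunday starting week 1
_WEEKDAY_OFFSET = {  # days after the week's Sunday
    "Sunday": 0, "Monday": 1, "Tuesday": 2, "Wednesday": 3,
    "Thursday": 4, "Friday": 5, "Saturday": 6,
}


def nanjing_metro_daily() -> pd.DataFrame:
    """The 45 printed daily metro volumes as a (date, volume) table."""
    rows = []
    for weekday, values in NANJING_METRO_WEEKLY.items():
        for week, volume in values:
            date = _WEEK1_SUNDAY + pd.Timedelta(days=7 * (week - 1) + _WEEKDAY_OFFSET[weekday])
            rows.append((date, volume))
    df = pd.DataFrame(rows, columns=["date", "volume"]).sort_values("date")
    return df.reset_index(drop=True)
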