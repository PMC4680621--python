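"""Published per-whale tracking summary for the New Caledonia humpback
whale satellite-tagging programme (2007-2012 deployments).

One row per tag that transmitted usefully: platform ID, tag duration in
days, sex, minimum total track distance in km and the reported overall
mean speed in km/h (1 decimal).  These published numbers serve as worked
examples: for rows where the reported mean speed equals minimum total
distance divided by elapsed time at 1-decimal rounding, the metrics
module must reproduce the printed value from a reconstructed
constant-speed track.
"""

from __future__ import annotations

import io

import pandas as pd

_TABLE = """\
ptt,duration_days,sex,distance_km,mean_speed_kmh
24638-07,26,F,1860,2.9
24639-07,39,M,2942,3.2
24641-07,13.5,M,769,2.5
24642-07,18.5,F,938,2.2
26712-07,21.5,M,1533,3.0
27258-07,8,M,270,1.5
27259-07,52.5,F,3340,2.7
33000-07,7.5,M,608,3.7
33001-07,14.5,M,1132,3.6
37229-07,22,F,2131,4.2
37230-07,43.5,F,2114,2.0
81122-10,24.5,M,820,1.4
81123-10,36.5,F,2524,3.1
84480-10,16,F,1379,3.8
84482-10,19,M,1736,3.9
84484-10,20.5,M,467,1.1
84485-10,17.5,M,1173,2.9
84486-10,18.5,M,649,1.5
84487-10,51.5,M,4738,3.9
84488-10,19,M,2050,4.7
87774-10,35.5,M,1247,1.5
87775-10,16.5,F,584,1.6
81122-11,20,F,1733,3.7
81123-11,17,F,1092,2.9
81126-11,54.5,F,3397,2.6
84485-11,48,F,2573,2.3
84487-11,16,M,1097,3.0
84494-11,15.5,F,929,2.9
87631-11,11.5,M,1163,4.4
87638-11,23.5,F,1001,1.8
87759-11,21.5,M,2358,4.5
87760-11,31,F,1583,2.2
87762-11,9,M,264,1.3
87761-12,110,F,8540,3.2
"""


def tracking_summary() -> pd.DataFrame:
    """The published per-whale summary as a DataFrame."""
    return pd.read_csv(io.StringIO(_TABLE))


def speed_identity_rows() -> pd.DataFrame:
    """Rows whose printed mean speed equals distance / elapsed time at
    1-decimal half-up rounding — the reproducible worked examples."""
    from .metrics import round_half_up

    df = tracking_summary()
    implied = df["distance_km"] / (df["duration_days"] * 24.0)
    ok = [round_half_up(v) == s for v, s in zip(implied, df["mean_speed_kmh"])]
    return df[ok].reset_index(drop=True)
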