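"""Score a short vitals stream under both tools.

Builds six 5-min readings for one patient in which blood pressure and
vascular resistance drift out of range, scores each reading 0-3 per
parameter, and prints the instantaneous alert levels.  The MPRT-WS level
escalates once two, then three, parameters reach score 2; the NEWS level
stays Low because its five-parameter total never reaches the Medium band.
"""

from mprtws import (
    Level,
    VitalReading,
    default_band_table,
    score_stream,
    stream_from_readings,
)

readings = [
    VitalReading("demo", 0, hr=76, spo2=97, rr=15, sbp=124, dbp=78,
                 temp=36.9, sv=82, co=5.6, svr=1005),
    VitalReading("demo", 5, hr=78, spo2=97, rr=16, sbp=120, dbp=84,
                 temp=36.9, sv=80, co=5.4, svr=1150),
    VitalReading("demo", 10, hr=81, spo2=96, rr=16, sbp=112, dbp=95,
                 temp=37.0, sv=78, co=5.2, svr=1420),
    VitalReading("demo", 15, hr=85, spo2=96, rr=17, sbp=104, dbp=105,
                 temp=37.0, sv=74, co=5.0, svr=1650),
    VitalReading("demo", 20, hr=90, spo2=95, rr=18, sbp=98, dbp=112,
                 temp=37.1, sv=70, co=4.8, svr=1820),
    VitalReading("demo", 25, hr=94, spo2=95, rr=18, sbp=95, dbp=114,
                 temp=37.1, sv=68, co=4.6, svr=1905),
]

stream = stream_from_readings(readings)
scored = score_stream(
    stream, default_band_table("MPRT-WS"), default_band_table("NEWS")
)

print("t(min)  sbp dbp svr | scores sbp/dbp/svr | MPRT-WS  NEWS(total)")
for row in scored.itertuples():
    level = Level(row.instant_mprt).name
    news = Level(row.instant_news).name
    raw = stream.loc[row.Index]
    print(
        f"{row.timestamp:6.0f}  {raw.sbp:3.0f} {raw.dbp:3.0f} {raw.svr:4.0f} |"
        f"     {row.sbp_score:.0f} / {row.dbp_score:.0f} / {row.svr_score:.0f}"
        f"      | {level:<8} {news}({row.news_total})"
    )
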