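"""Observed visitor-demand tables for three Nanjing urban parks.

Field observations (2019-2020) at the most popular entrance of each park:
hourly entrance counts, stay-duration shares and visitor-type composition,
for weekdays and weekends, plus the pre-pandemic daily totals and accessible
areas used as capacity baselines. Bailuzhou Park is the small single-ring
park (15.28 ha), Xuanwu Lake Park the large multi-ring park (513 ha), and
Sun Yat-sen Mausoleum the linear commemorative scenic area (955 ha).
"""

from __future__ import annotations

from .behavior import VisitorType
from .engine import DemandTables

BAILUZHOU = "bailuzhou"
XUANWU = "xuanwu"
MAUSOLEUM = "mausoleum"

#: hourly entrance counts at the most popular gate, by park and day type
HOURLY_GATE_COUNTS: dict[str, dict[str, dict[int, float]]] = {
    BAILUZHOU: {
        "weekday": {6: 182, 7: 196, 8: 127, 9: 135, 10: 105, 11: 97, 12: 106,
                    13: 94, 14: 72, 15: 133, 16: 126, 17: 90, 18: 243, 19: 192},
        "weekend": {6: 177, 7: 186, 8: 180, 9: 196, 10: 138, 11: 51, 12: 104,
                    13: 123, 14: 132, 15: 190, 16: 132, 17: 161, 18: 292,
                    19: 237},
    },
    XUANWU: {
        "weekday": {6: 786, 7: 827, 8: 951, 9: 783, 10: 526, 11: 400, 12: 373,
                    13: 314, 14: 365, 15: 576, 16: 805, 17: 868, 18: 1954,
                    19: 1086},
        "weekend": {6: 956, 7: 876, 8: 988, 9: 1246, 10: 1457, 11: 859,
                    12: 712, 13: 1159, 14: 1502, 15: 1542, 16: 1511, 17: 1610,
                    18: 2650, 19: 2117},
    },
    MAUSOLEUM: {
        "weekday": {7: 99, 8: 384, 9: 654, 10: 423, 11: 522, 12: 435, 13: 360,
                    14: 570, 15: 393, 16: 417, 17: 120, 18: 45},
        "weekend": {7: 423, 8: 663, 9: 1674, 10: 1368, 11: 1533, 12: 1128,
                    13: 792, 14: 1260, 15: 855, 16: 870, 17: 561, 18: 168},
    },
}

#: stay-duration shares by bin (<1 h, 2 h, 4 h, >4 h), as surveyed.
#: Some columns sum slightly below 1 (survey rounding); they are
#: renormalised when demand tables are built.
STAY_DISTRIBUTIONS: dict[str, dict[str, dict[str, float]]] = {
    BAILUZHOU: {
        "weekday": {"<1h": 0.68, "2h": 0.32},
        "weekend": {"<1h": 0.56, "2h": 0.42, "4h": 0.02},
    },
    XUANWU: {
        "weekday": {"<1h": 0.73, "2h": 0.10, "4h": 0.03},
        "weekend": {"<1h": 0.52, "2h": 0.27, "4h": 0.16, ">4h": 0.05},
    },
    MAUSOLEUM: {
        "weekday": {"<1h": 0.08, "2h": 0.52, "4h": 0.33, ">4h": 0.06},
        "weekend": {"<1h": 0.07, "2h": 0.58, "4h": 0.29, ">4h": 0.06},
    },
}

#: visitor-type composition shares, as surveyed (renormalised on use)
COMPOSITIONS: dict[str, dict[str, dict[VisitorType, float]]] = {
    BAILUZHOU: {
        "weekday": {VisitorType.EXERCISER: 0.40, VisitorType.LEISURE: 0.24,
                    VisitorType.TOURIST: 0.30, VisitorType.WITH_CHILDREN: 0.03,
                    VisitorType.OTHER: 0.03},
        "weekend": {VisitorType.EXERCISER: 0.34, VisitorType.LEISURE: 0.26,
                    VisitorType.TOURIST: 0.28, VisitorType.WITH_CHILDREN: 0.07,
                    VisitorType.OTHER: 0.04},
    },
    XUANWU: {
        "weekday": {VisitorType.EXERCISER: 0.29, VisitorType.LEISURE: 0.22,
                    VisitorType.TOURIST: 0.40, VisitorType.WITH_CHILDREN: 0.04,
                    VisitorType.OTHER: 0.04},
        "weekend": {VisitorType.EXERCISER: 0.20, VisitorType.LEISURE: 0.24,
                    VisitorType.TOURIST: 0.45, VisitorType.WITH_CHILDREN: 0.07,
                    VisitorType.OTHER: 0.03},
    },
    MAUSOLEUM: {
        "weekday": {VisitorType.EXERCISER: 0.10, VisitorType.LEISURE: 0.07,
                    VisitorType.TOURIST: 0.69, VisitorType.WITH_CHILDREN: 0.0,
                    VisitorType.OTHER: 0.07},
        "weekend": {VisitorType.EXERCISER: 0.05, VisitorType.LEISURE: 0.09,
                    VisitorType.TOURIST: 0.83, VisitorType.WITH_CHILDREN: 0.0,
                    VisitorType.OTHER: 0.03},
    },
}

#: pre-pandemic daily visitor totals (the reopening upper limit)
HISTORICAL_DAILY: dict[str, dict[str, int]] = {
    BAILUZHOU: {"weekday": 4267, "weekend": 5404},
    XUANWU: {"weekday": 24088, "weekend": 41611},
    MAUSOLEUM: {"weekday": 7964, "weekend": 18288},
}

#: accessible (walkable) area in hectares
ACCESSIBLE_AREA_HA: dict[str, float] = {
    BAILUZHOU: 3.24,
    XUANWU: 28.97,
    MAUSOLEUM: 36.94,
}


def demand_tables(park: str, day_type: str = "weekday",
                  scale: float = 1.0) -> DemandTables:
    """Demand tables for one park/day type, hourly counts scaled by `scale`.

    Composition and duration shares are renormalised to sum to exactly 1
    (the surveyed columns carry rounding gaps of up to a few percent).
    """
    hourly = {h: v * scale
              for h, v in HOURLY_GATE_COUNTS[park][day_type].items()}
    comp = dict(COMPOSITIONS[park][day_type])
    ctot = sum(comp.values())
    comp = {k: v / ctot for k, v in comp.items()}
    durations = dict(STAY_DISTRIBUTIONS[park][day_type])
    dtot = sum(durations.values())
    durations = {k: v / dtot for k, v in durations.items()}
    return DemandTables(hourly=hourly, composition=comp, durations=durations)
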