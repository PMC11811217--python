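"""Canonical registry of the 205 per-beat ECG/PPG features.

Eleven fiducial landmarks are tracked per cardiac cycle, in temporal order::

    1  ppg_valley       pulse onset (foot)
    2  sdppg_a          first positive wave of the PPG second derivative
    3  dppg_peak        maximum upslope of the PPG
    4  sdppg_b          early negative sdPPG wave (at the systolic crest)
    5  ppg_peak         systolic peak
    6  sdppg_c          late-systolic positive sdPPG wave
    7  sdppg_d          late-systolic negative sdPPG wave (dicrotic onset)
    8  dppg_valley      maximum downslope (pre-notch)
    9  sdppg_e          sdPPG wave at the dicrotic notch region
    10 sdppg_f          final negative sdPPG wave
    11 ppg_valley_next  onset of the following pulse

The 205 features fall into six categories with fixed index ranges:

===========  =========  ====================================================
category     indices    definition
===========  =========  ====================================================
PTT          1-10       landmark time minus the ECG R-peak time (s)
TD           11-66      RRI plus all 55 time differences between landmarks
AM           67-111     PPG amplitude differences over the 45 primary pairs
AI           112-130    signal values at landmarks (PPG / dPPG / sdPPG)
AR           131-185    trapezoidal PPG area between the 55 landmark pairs
RI           186-205    20 dimensionless morphology ratio indices
===========  =========  ====================================================

Within a category the ordering is lexicographic over landmark pairs
(i ascending, then j ascending), with two published anchors pinned: index 47
is TD(sdPPG c − PPG peak) and index 52 is TD(sdPPG c − dPPG valley); the
pairs displaced by pinning occupy the vacated slots (46 and 53).  The AI
block comprises the PPG value at each of the ten primary landmarks, the
dPPG value at the PPG valley, dPPG peak and dPPG valley, and the sdPPG
value at the six a-f waves (19 entries).  The registry is shipped as data
so the index -> definition mapping is an explicit, testable contract.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass
from functools import lru_cache

import pandas as pd

__all__ = [
    "LANDMARKS",
    "PRIMARY_LANDMARKS",
    "CATEGORY_RANGES",
    "RI_NAMES",
    "FeatureDef",
    "build_registry",
    "registry_frame",
    "write_registry_json",
    "feature_column",
]

LANDMARKS: tuple[str, ...] = (
    "ppg_valley",
    "sdppg_a",
    "dppg_peak",
    "sdppg_b",
    "ppg_peak",
    "sdppg_c",
    "sdppg_d",
    "dppg_valley",
    "sdppg_e",
    "sdppg_f",
    "ppg_valley_next",
)
#: the ten landmarks of the current pulse (excludes the next pulse's onset)
PRIMARY_LANDMARKS: tuple[str, ...] = LANDMARKS[:10]

CATEGORY_RANGES: dict[str, tuple[int, int]] = {
    "PTT": (1, 10),
    "TD": (11, 66),
    "AM": (67, 111),
    "AI": (112, 130),
    "AR": (131, 185),
    "RI": (186, 205),
}

#: dPPG landmarks reported in the AI block
_AI_DPPG = ("ppg_valley", "dppg_peak", "dppg_valley")
#: sdPPG landmarks reported in the AI block (the six a-f waves)
_AI_SDPPG = ("sdppg_a", "sdppg_b", "sdppg_c", "sdppg_d", "sdppg_e", "sdppg_f")

RI_NAMES: tuple[str, ...] = (
    "relative_rising_time",
    "relative_falling_time",
    "rise_fall_ratio",
    "relative_crest_time",
    "relative_c_wave_time",
    "relative_notch_time",
    "late_systolic_width_ratio",
    "slope_transit_time_ratio",
    "augmentation_index",
    "dicrotic_diastolic_ratio",
    "sdppg_cdb_a",  # (c + d - b) / a
    "inflection_point_area_ratio",
    "sdppg_b_a",
    "sdppg_c_a",
    "sdppg_d_a",
    "sdppg_e_a",
    "sdppg_f_a",
    "aging_index",  # (b - c - d - e) / a
    "ppg_intensity_ratio",
    "perfusion_index",
)


@dataclass(frozen=True)
class FeatureDef:
    """One registry entry: immutable description of a per-beat feature.

    ``kind``/``params`` drive the extraction dispatch:

    - ``("ptt", landmark)`` - landmark time minus R-peak time
    - ``("rri",)`` - R-R interval
    - ``("td", lm_i, lm_j)`` - time of j minus time of i
    - ``("am", lm_i, lm_j)`` - PPG(j) minus PPG(i)
    - ``("ai", channel, landmark)`` - channel value at the landmark
    - ``("ar", lm_i, lm_j)`` - trapezoidal PPG area from i to j
    - ``("ri", name)`` - named ratio index
    """

    index: int
    name: str
    category: str
    kind: str
    params: tuple

    @property
    def unit(self) -> str:
        return {
            "PTT": "s",
            "TD": "s",
            "AM": "signal",
            "AI": "signal",
            "AR": "signal*s",
            "RI": "dimensionless",
        }[self.category]


def feature_column(index: int) -> str:
    """Column id used in matrices, e.g. ``f052``."""
    return f"f{index:03d}"


def _pairs(landmarks: tuple[str, ...]) -> list[tuple[str, str]]:
    return list(itertools.combinations(landmarks, 2))


@lru_cache(maxsize=1)
def build_registry() -> tuple[FeatureDef, ...]:
    defs: list[FeatureDef] = []

    # PTT 1-10
    for k, lm in enumerate(PRIMARY_LANDMARKS, start=1):
        defs.append(FeatureDef(k, f"ptt_{lm}", "PTT", "ptt", (lm,)))

    # TD 11-66: RRI then the 55 landmark pairs
    defs.append(FeatureDef(11, "rri", "TD", "rri", ()))
    td_pairs = _pairs(LANDMARKS)
    assert len(td_pairs) == 55
    # pin the two published indices: 47 <- (ppg_peak, sdppg_c),
    # 52 <- (sdppg_c, dppg_valley); lex order puts them at 46 and 53
    i_peak_c = td_pairs.index(("ppg_peak", "sdppg_c"))
    i_c_dv = td_pairs.index(("sdppg_c", "dppg_valley"))
    order = list(range(55))
    a, b = order.index(i_peak_c), 47 - 12  # pin TD(sdPPG c - PPG peak) at 47
    order[a], order[b] = order[b], order[a]
    a, b = order.index(i_c_dv), 52 - 12  # pin TD(sdPPG c - dPPG valley) at 52
    order[a], order[b] = order[b], order[a]
    for slot, pair_pos in enumerate(order):
        li, lj = td_pairs[pair_pos]
        defs.append(
            FeatureDef(12 + slot, f"td_{li}__{lj}", "TD", "td", (li, lj))
        )

    # AM 67-111: amplitude differences over the 45 primary-landmark pairs
    for k, (li, lj) in enumerate(_pairs(PRIMARY_LANDMARKS), start=67):
        defs.append(FeatureDef(k, f"am_{li}__{lj}", "AM", "am", (li, lj)))

    # AI 112-130
    k = 112
    for lm in PRIMARY_LANDMARKS:
        defs.append(FeatureDef(k, f"ai_ppg_{lm}", "AI", "ai", ("ppg", lm)))
        k += 1
    for lm in _AI_DPPG:
        defs.append(FeatureDef(k, f"ai_dppg_{lm}", "AI", "ai", ("dppg", lm)))
        k += 1
    for lm in _AI_SDPPG:
        defs.append(FeatureDef(k, f"ai_sdppg_{lm}", "AI", "ai", ("sdppg", lm)))
        k += 1
    assert k == 131

    # AR 131-185: areas over the 55 landmark pairs (lex order)
    for k, (li, lj) in enumerate(_pairs(LANDMARKS), start=131):
        defs.append(FeatureDef(k, f"ar_{li}__{lj}", "AR", "ar", (li, lj)))

    # RI 186-205
    for k, name in enumerate(RI_NAMES, start=186):
        defs.append(FeatureDef(k, f"ri_{name}", "RI", "ri", (name,)))

    assert len(defs) == 205
    assert [d.index for d in defs] == list(range(1, 206))
    return tuple(defs)


def category_counts() -> dict[str, int]:
    out: dict[str, int] = {}
    for d in build_registry():
        out[d.category] = out.get(d.category, 0) + 1
    return out


def registry_frame() -> pd.DataFrame:
    rows = []
    for d in build_registry():
        r = asdict(d)
        r["column"] = feature_column(d.index)
        r["unit"] = d.unit
        r["params"] = "|".join(map(str, d.params))
        rows.append(r)
    return pd.DataFrame(rows)


def write_registry_json(path) -> None:
    payload = {
        feature_column(d.index): {
            "index": d.index,
            "name": d.name,
            "category": d.category,
            "kind": d.kind,
            "params": list(d.params),
            "unit": d.unit,
        }
        for d in build_registry()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
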