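"""Measurement points, investigation areas and cohort strata.

The reference measurement plan samples the oral cavity at 16 fixed
measurement points (MP1-MP16) grouped into seven investigation areas of
comparable mucosal structure.  The mapping is fixed; stratification is by
sex and by three age groups.
"""


__all__ = [
    "REGIONS", "MP_TO_REGION", "REGION_TO_MPS", "SEXES", "AGE_GROUPS",
    "FULL_ACCESS_PATTERN", "REFERENCE_ACCESS_PATTERN", "region_of",
]

REGIONS = (
    "labial",
    "alveolar",
    "buccal",
    "sublingual",
    "hard_palate",
    "soft_palate_oropharynx",
    "tonsil",
)

MP_TO_REGION = {
    "MP1": "labial", "MP3": "labial", "MP4": "labial",
    "MP2": "alveolar", "MP5": "alveolar",
    "MP6": "buccal", "MP7": "buccal", "MP8": "buccal",
    "MP9": "sublingual", "MP10": "sublingual", "MP11": "sublingual",
    "MP12": "hard_palate",
    "MP13": "soft_palate_oropharynx", "MP14": "soft_palate_oropharynx",
    "MP15": "soft_palate_oropharynx",
    "MP16": "tonsil",
}

REGION_TO_MPS: dict[str, tuple[str, ...]] = {}
for _mp, _r in MP_TO_REGION.items():
    REGION_TO_MPS.setdefault(_r, tuple())
    REGION_TO_MPS[_r] = REGION_TO_MPS[_r] + (_mp,)

SEXES = ("male", "female", "unspecified")
AGE_GROUPS = ("<25", "25-45", ">45", "unspecified")


def region_of(measurement_point: str) -> str:
    """Investigation area of a measurement point.

    Raises ``KeyError`` with an explicit message for unknown points.
    """
    try:
        return MP_TO_REGION[measurement_point]
    except KeyError:
        raise KeyError(
            f"unknown measurement point {measurement_point!r}; expected MP1..MP16") from None


def age_group_of(age_years: float) -> str:
    if age_years < 25:
        return "<25"
    if age_years <= 45:
        return "25-45"
    return ">45"


#: every measurement point accessible in every subject
FULL_ACCESS_PATTERN = {mp: 47 for mp in MP_TO_REGION}

#: accessibility of the 16 points in the 47-subject reference cohort:
#: the anterior oral cavity (MP1-MP12) was reachable in all subjects, the
#: posterior points in progressively fewer.
REFERENCE_ACCESS_PATTERN = {**{f"MP{i}": 47 for i in range(1, 13)},
                            "MP13": 45, "MP14": 40, "MP15": 29, "MP16": 34}
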