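"""Synthetic study cohorts built from the region presets.

Emulates the reference study design: 47 adult subjects (25 male / 22
female; age groups 14 / 30 / 3 for <25, 25-45, >45 years), 16 measurement
points with the published accessibility pattern, one series of five
B-scans per accessible (subject, point).  Subject thickness is drawn from
the regional preset (sex-specific where the preset provides it); all
randomness flows from one root seed through named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import ScanGeometry
from .io_formats import StudyMetadata
from .phantom import TissueProfile, build_profile, render_series
from .regions import (FULL_ACCESS_PATTERN, MP_TO_REGION,
                      REFERENCE_ACCESS_PATTERN, region_of)

__all__ = ["Subject", "make_subjects", "subject_profile", "simulate_subject_series",
           "iter_cohort"]

REFERENCE_SEX_COUNTS = {"male": 25, "female": 22}
REFERENCE_AGE_COUNTS = {"<25": 14, "25-45": 30, ">45": 3}


@dataclass(frozen=True)
class Subject:
    subject_id: str
    sex: str
    age_group: str


def make_subjects(n_subjects: int = 47, seed: int = 0,
                  sex_counts: dict | None = None,
                  age_counts: dict | None = None) -> list[Subject]:
    """Deterministic subject roster with the requested strata counts.

    Defaults scale the reference demographics to ``n_subjects``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    if sex_counts is None:
        n_male = int(round(n_subjects * 25 / 47))
        sex_counts = {"male": n_male, "female": n_subjects - n_male}
    if age_counts is None:
        n_young = int(round(n_subjects * 14 / 47))
        n_old = max(1, int(round(n_subjects * 3 / 47))) if n_subjects >= 8 else 0
        age_counts = {"<25": n_young, ">45": n_old,
                      "25-45": n_subjects - n_young - n_old}
    sexes = [s for s, c in sex_counts.items() for _ in range(c)]
    ages = [a for a, c in age_counts.items() for _ in range(c)]
    if len(sexes) != n_subjects or len(ages) != n_subjects:
        raise ValueError("strata counts must sum to n_subjects")
    rng.shuffle(ages)
    return [Subject(f"S{i + 1:03d}", sexes[i], ages[i]) for i in range(n_subjects)]


def subject_profile(profile: TissueProfile, subject: Subject) -> TissueProfile:
    """Apply the preset's sex-specific thickness distribution if present."""
    if profile.thickness_by_sex and subject.sex in profile.thickness_by_sex:
        mean, sd = profile.thickness_by_sex[subject.sex]
        return replace(profile, thickness_mean_geom=mean, thickness_sd_geom=sd)
    return profile


def _series_seed(root_seed: int, subject_idx: int, mp: str) -> int:
    ss = np.random.SeedSequence([root_seed, 7, subject_idx, int(mp[2:])])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def simulate_subject_series(subject: Subject, mp: str, root_seed: int,
                            geometry: ScanGeometry | None = None,
                            subject_idx: int = 0,
                            profile_overrides: dict | None = None):
    """Render one subject's series at one measurement point."""
    profile = subject_profile(build_profile(region_of(mp), profile_overrides), subject)
    seed = _series_seed(root_seed, subject_idx, mp)
    series, truths = render_series(profile, geometry, seed)
    metadata = StudyMetadata(
        subject_id=subject.subject_id, measurement_point=mp, sex=subject.sex,
        age_group=subject.age_group, geometry=series.geometry,
        refractive_index=profile.refractive_index, seed=seed)
    return series, truths, metadata


def iter_cohort(n_subjects: int = 47, measurement_points=None, seed: int = 0,
                geometry: ScanGeometry | None = None,
                accessibility: str | dict = "full",
                profile_overrides: dict | None = None):
    """Yield (subject, mp, series, truths, metadata) for a whole cohort.

    ``accessibility`` is 'full', 'reference' (the published pattern: the
    posterior points are reachable in progressively fewer subjects) or an
    explicit ``{MP: n_subjects}`` mapping; the first ``n`` subjects of the
    roster are the accessible ones.
    """
    subjects = make_subjects(n_subjects, seed)
    if measurement_points is None:
        measurement_points = sorted(MP_TO_REGION, key=lambda m: int(m[2:]))
    if accessibility == "full":
        pattern = FULL_ACCESS_PATTERN
    elif accessibility == "reference":
        pattern = REFERENCE_ACCESS_PATTERN
    else:
        pattern = dict(accessibility)
    for mp in measurement_points:
        n_ok = min(pattern.get(mp, n_subjects), n_subjects)
        for idx in range(n_ok):
            overrides = None
            if profile_overrides:
                overrides = profile_overrides.get(region_of(mp))
            yield simulate_subject_series(subjects[idx], mp, seed, geometry,
                                          subject_idx=idx,
                                          profile_overrides=overrides)
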