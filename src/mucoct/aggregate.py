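"""Study-level reference statistics.

The unit of analysis is the subject's series mean: each subject
contributes one thickness value (the mean of the 5 x 5 samples of their
series) and one vessel-density value per measurement point; B-scans are
never pooled directly into cohort statistics.  Measurement points are
summarized individually, then pooled per investigation area; qualitative
criteria are reported as percentage distributions over B-scans.

Quartile convention: linear interpolation between closest ranks using
plotting positions ``(i) / (n + 1)`` (the Weibull rule), so for the
sample {1,2,3,4,5} the quartiles are 1.5 and 4.5.  Subjects missing a
measurement point are explicit absences, not zeros.  Significance tests
between strata are out of scope; only descriptive statistics are
reported.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .io_formats import fmt_pct
from .regions import region_of

__all__ = [
    "BoxplotStats", "SubjectSeriesResult", "MPEntry", "RegionSummary",
    "StudyAccounting", "make_boxplot_data", "summarize_point",
    "summarize_region", "study_accounting", "write_report",
]

QUANTILE_METHOD = "weibull"

CRITERION_CATEGORIES = {
    "surface_integrity": ("intact", "with_alterations"),
    "surface_profile": ("even", "uneven"),
    "epithelial_homogeneity": ("homogeneous", "inhomogeneous"),
    "bm_assessment": ("intact", "unsharp", "not_assessable"),
    "vessel_rating": ("low", "moderate", "high"),
    "components": ("none", "salivary_gland", "lymphoid_follicle",
                   "lymphoid_follicle+salivary_gland"),
}


@dataclass(frozen=True)
class BoxplotStats:
    """Five-number summary plus mean and SD (sample SD, ddof=1; 0 for n=1)."""

    n: int
    mean: float
    sd: float
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float


def make_boxplot_data(values) -> BoxplotStats:
    """Five-number summary + mean under the documented quartile convention."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75], method=QUANTILE_METHOD)
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return BoxplotStats(int(vals.size), float(vals.mean()), sd,
                        float(vals.min()), float(q1), float(med), float(q3),
                        float(vals.max()))


@dataclass
class SubjectSeriesResult:
    """One subject's analyzed series at one measurement point."""

    subject_id: str
    measurement_point: str
    sex: str = "unspecified"
    age_group: str = "unspecified"
    thickness_series_mean: float | None = None   # um; None = not assessable
    vessel_ratio: float | None = None
    criteria_rows: list = field(default_factory=list)  # per-B-scan label dicts
    image_count: int = 5


@dataclass
class MPEntry:
    """Per-measurement-point thickness summary with strata."""

    measurement_point: str
    n_subjects: int
    overall: BoxplotStats | None
    by_sex: dict
    by_age: dict
    values: list   # retained (subject_id, sex, age_group, value) for pooling

    def iter_strata(self):
        if self.overall is not None:
            yield "overall", "all", self.overall
        for g in sorted(self.by_sex):
            yield "sex", g, self.by_sex[g]
        for g in sorted(self.by_age):
            yield "age", g, self.by_age[g]


def _stratified(values: list) -> tuple[BoxplotStats | None, dict, dict]:
    usable = [(sid, sex, age, v) for sid, sex, age, v in values if v is not None]
    overall = make_boxplot_data([v for *_, v in usable]) if usable else None
    by_sex, by_age = {}, {}
    for key_idx, target in ((1, by_sex), (2, by_age)):
        groups: dict[str, list] = {}
        for rec in usable:
            groups.setdefault(rec[key_idx], []).append(rec[3])
        for g, vals in groups.items():
            if g != "unspecified":
                target[g] = make_boxplot_data(vals)
    return overall, by_sex, by_age


def summarize_point(results: list) -> MPEntry:
    """Summarize one measurement point over subjects.

    Subject-level series means are the unit of analysis; a single subject
    yields SD = 0 with an ``n = 1`` flag in the tables downstream.
    """
    if not results:
        raise ValueError("no results for this measurement point")
    mps = {r.measurement_point for r in results}
    if len(mps) != 1:
        raise ValueError(f"results mix measurement points: {sorted(mps)}")
    values = [(r.subject_id, r.sex, r.age_group, r.thickness_series_mean)
              for r in results]
    overall, by_sex, by_age = _stratified(values)
    return MPEntry(mps.pop(), len(results), overall, by_sex, by_age, values)


@dataclass
class RegionSummary:
    """Aggregate of one investigation area."""

    region_id: str
    per_mp: dict                      # MP -> MPEntry
    overall: BoxplotStats | None
    by_sex: dict
    by_age: dict
    criterion_pct: dict               # criterion -> {category: (count, pct)}
    vessel_stats: dict | None         # {'n', 'mean', 'sd', 'pct': {...}}
    image_count: int


def _criteria_distribution(rows: list) -> dict:
    out: dict[str, dict] = {}
    for criterion, categories in CRITERION_CATEGORIES.items():
        counts: Counter = Counter()
        for row in rows:
            label = row.get(criterion, "")
            if criterion == "components":
                label = label if label else "none"
            if label != "":
                counts[label] += 1
        total = sum(counts.values())
        if total == 0:
            continue
        dist = {}
        for category in sorted(set(categories) | set(counts)):
            if counts[category] or category in categories:
                dist[category] = (counts[category], fmt_pct(counts[category], total))
        out[criterion] = dist
    return out


def summarize_region(results: list) -> RegionSummary:
    """Pool subject-level values over the measurement points of one area."""
    if not results:
        raise ValueError("no results to summarize")
    regions = {region_of(r.measurement_point) for r in results}
    if len(regions) != 1:
        raise ValueError(f"results mix investigation areas: {sorted(regions)}")
    region = regions.pop()

    per_mp: dict[str, MPEntry] = {}
    for mp in sorted({r.measurement_point for r in results}, key=lambda m: int(m[2:])):
        per_mp[mp] = summarize_point([r for r in results if r.measurement_point == mp])

    pooled = [rec for entry in per_mp.values() for rec in entry.values]
    overall, by_sex, by_age = _stratified(pooled)

    rows = [row for r in results for row in r.criteria_rows]
    criterion_pct = _criteria_distribution(rows)

    ratios = [r.vessel_ratio for r in results if r.vessel_ratio is not None]
    vessel_stats = None
    if ratios:
        arr = np.asarray(ratios, dtype=float)
        ratings = [row["vessel_rating"] for r in results for row in r.criteria_rows
                   if row.get("vessel_rating")]
        n_rated = len(ratings)
        pct = {c: (fmt_pct(ratings.count(c), n_rated) if n_rated else 0.0)
               for c in ("low", "moderate", "high")}
        vessel_stats = {"n": int(arr.size), "mean": float(arr.mean()),
                        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                        "pct": pct}
    return RegionSummary(region, per_mp, overall, by_sex, by_age,
                         criterion_pct, vessel_stats,
                         image_count=sum(r.image_count for r in results))


@dataclass
class StudyAccounting:
    """Cohort bookkeeping: image counts, accessibility, demographics."""

    n_subjects: int
    per_area_images: dict
    total_images: int
    accessibility: dict           # MP -> (n_subjects, percent)
    sex_pct: dict                 # sex -> (count, percent)
    age_pct: dict                 # age group -> (count, percent)


def study_accounting(metadata_list: list) -> StudyAccounting:
    """Study-population accounting from one metadata record per series."""
    if not metadata_list:
        raise ValueError("no metadata records")
    seen = set()
    for m in metadata_list:
        key = (m.subject_id, m.measurement_point)
        if key in seen:
            raise ValueError(f"duplicate (subject, measurement point) record: {key}")
        seen.add(key)

    subjects = {}
    for m in metadata_list:
        subjects[m.subject_id] = (m.sex, m.age_group)
    n_subjects = len(subjects)

    per_area: Counter = Counter()
    per_mp: Counter = Counter()
    total = 0
    for m in metadata_list:
        count = m.geometry.series_length
        per_area[m.region_id] += count
        per_mp[m.measurement_point] += 1
        total += count

    accessibility = {mp: (n, fmt_pct(n, n_subjects))
                     for mp, n in sorted(per_mp.items(), key=lambda kv: int(kv[0][2:]))}
    sex_counts = Counter(s for s, _ in subjects.values())
    age_counts = Counter(a for _, a in subjects.values())
    sex_pct = {g: (c, fmt_pct(c, n_subjects)) for g, c in sorted(sex_counts.items())}
    age_pct = {g: (c, fmt_pct(c, n_subjects)) for g, c in sorted(age_counts.items())}
    return StudyAccounting(n_subjects, dict(per_area), total, accessibility,
                           sex_pct, age_pct)


def write_report(summaries: list, path, accounting: StudyAccounting | None = None) -> None:
    """Markdown report: per-criterion percentage breakdown and box-plot numbers."""
    lines = ["# Oral-mucosa OCT summary", ""]
    if accounting is not None:
        lines += ["## Study accounting", "",
                  f"- subjects: {accounting.n_subjects}",
                  f"- total images: {accounting.total_images}"]
        for area, n in sorted(accounting.per_area_images.items()):
            lines.append(f"- {area}: {n} images")
        lines.append("")
    for s in sorted(summaries, key=lambda s: s.region_id):
        lines += [f"## {s.region_id}", ""]
        if s.overall is not None:
            o = s.overall
            lines.append(
                f"- thickness (n={o.n} subject series): {o.mean:.1f} +/- {o.sd:.1f} um "
                f"[min {o.minimum:.1f}, Q1 {o.q1:.1f}, median {o.median:.1f}, "
                f"Q3 {o.q3:.1f}, max {o.maximum:.1f}]")
        for criterion, dist in sorted(s.criterion_pct.items()):
            parts = ", ".join(f"{cat} {pct:.1f}%" for cat, (cnt, pct) in sorted(dist.items()))
            lines.append(f"- {criterion}: {parts}")
        if s.vessel_stats:
            v = s.vessel_stats
            lines.append(f"- vessel density: {v['mean']:.2f} +/- {v['sd']:.2f} "
                         f"(low {v['pct']['low']}%, moderate {v['pct']['moderate']}%, "
                         f"high {v['pct']['high']}%)")
        lines.append("")
    from pathlib import Path
    Path(path).write_text("\n".join(lines))
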