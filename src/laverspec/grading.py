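"""Quality grading of dried laver: per-index grades and the composite zone.

Two grading routes are provided.  The fixed-criteria route applies the
industry cut points: moisture <= 12 g/100 g is first grade and > 12 is
third grade (there is no second moisture grade); crude protein >= 35
g/100 g is first grade, >= 30 second, below 30 third; cutting stress
>= 0.45 kg·mm first, >= 0.33 second, below third.  The data-driven route
groups samples by one-way ANOVA with Tukey's HSD at alpha = 0.05 and
ranks the groups into grades.

The composite grade collapses the three index grades into two zones:
zone 1 (premium) requires first-grade protein, first- or second-grade
cutting stress, AND compliant (first-grade) moisture; everything else is
zone 2.  A sheet that would qualify on protein and texture but exceeds
12% moisture is explicitly excluded from zone 1, and the rule trace
records that override.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import f_oneway, tukey_hsd

__all__ = [
    "GradingCriteria",
    "IndexGrades",
    "GradeAssignment",
    "TukeyGrouping",
    "DEFAULT_CRITERIA",
    "assign_grades",
    "assign_zone",
    "zone_by_mean_rating",
    "tukey_groups",
]


@dataclass(frozen=True)
class GradingCriteria:
    """Cut points of the composite grading table.

    ``moisture_first_max``: moisture <= this is first grade, above is third
    (no second grade exists for moisture).  Protein and cutting-stress cuts
    are inclusive lower bounds for grades 1 and 2.
    """

    moisture_first_max: float = 12.0
    protein_first_min: float = 35.0
    protein_second_min: float = 30.0
    cutting_first_min: float = 0.45
    cutting_second_min: float = 0.33

    def __post_init__(self) -> None:
        if not self.protein_first_min > self.protein_second_min:
            raise ValueError("protein cuts must be strictly ordered")
        if not self.cutting_first_min > self.cutting_second_min:
            raise ValueError("cutting-stress cuts must be strictly ordered")


DEFAULT_CRITERIA = GradingCriteria()


@dataclass(frozen=True)
class IndexGrades:
    """Per-index grades in {1, 2, 3}; moisture only ever takes 1 or 3."""

    moisture: int
    protein: int
    cutting_stress: int

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.moisture, self.protein, self.cutting_stress)


@dataclass(frozen=True)
class GradeAssignment:
    sample_id: str
    grades: IndexGrades
    zone: int
    trace: tuple[str, ...]


def assign_grades(record, criteria: GradingCriteria = DEFAULT_CRITERIA) -> IndexGrades:
    """Apply the fixed cut points to one quality record.

    ``record`` needs ``moisture``, ``protein`` and ``cutting_stress``
    attributes (g/100 g, g/100 g, kg·mm).  Values must be positive.
    """
    m, p, c = record.moisture, record.protein, record.cutting_stress
    if min(m, p, c) <= 0:
        raise ValueError("quality-index values must be positive")
    # moisture at exactly the cut is first grade (footnote convention)
    moisture = 1 if m <= criteria.moisture_first_max else 3
    if p >= criteria.protein_first_min:
        protein = 1
    elif p >= criteria.protein_second_min:
        protein = 2
    else:
        protein = 3
    if c >= criteria.cutting_first_min:
        cutting = 1
    elif c >= criteria.cutting_second_min:
        cutting = 2
    else:
        cutting = 3
    return IndexGrades(moisture, protein, cutting)


def assign_zone(grades: IndexGrades, sample_id: str = "") -> GradeAssignment:
    """Compose the two-zone grade from the per-index grades.

    Zone 1 iff protein grade 1, cutting grade 1 or 2, and moisture grade 1.
    The trace names the deciding condition, including the moisture
    override of an otherwise zone-1 sheet.
    """
    trace: list[str] = []
    protein_ok = grades.protein == 1
    cutting_ok = grades.cutting_stress in (1, 2)
    moisture_ok = grades.moisture == 1
    if protein_ok and cutting_ok and moisture_ok:
        zone = 1
        trace.append("zone1: first-grade protein, first/second-grade cutting, compliant moisture")
    elif protein_ok and cutting_ok:
        zone = 2
        trace.append("zone2: moisture exceeds 12% — excluded from zone 1 despite protein/cutting")
    else:
        zone = 2
        if not protein_ok:
            trace.append(f"zone2: protein grade {grades.protein} (needs 1)")
        if not cutting_ok:
            trace.append("zone2: third-grade cutting stress")
    if grades.moisture == 1 and not moisture_ok:  # unreachable; keeps trace total
        trace.append("moisture boundary")
    return GradeAssignment(sample_id, grades, zone, tuple(trace))


def zone_by_mean_rating(grades: IndexGrades) -> int:
    """Diagnostic heuristic: mean index rating <= 1.5 maps to zone 1."""
    return 1 if np.mean(grades.as_tuple()) <= 1.5 else 2


# ---------------------------------------------------------------------------
# Tukey grouping


@dataclass
class TukeyGrouping:
    """Compact-letter display from one-way ANOVA + Tukey HSD."""

    sample_ids: list[str]
    means: np.ndarray
    letters: list[str]  # per sample, e.g. "a", "ab"
    grades: list[int]  # per sample, 1 = best
    f_statistic: float
    p_value: float
    alpha: float


def _compact_letter_display(n: int, significant: np.ndarray) -> list[set[int]]:
    """Insert-absorb algorithm: maximal sets of mutually non-different samples."""
    groups: list[set[int]] = [set(range(n))]
    for i, j in itertools.combinations(range(n), 2):
        if not significant[i, j]:
            continue
        for g in [g for g in groups if i in g and j in g]:
            groups.remove(g)
            for replacement in (g - {i}, g - {j}):
                if replacement and not any(replacement <= other for other in groups):
                    groups.append(replacement)
    # absorb: drop groups contained in another
    groups = [g for g in groups if not any(g < other for other in groups)]
    return groups


def tukey_groups(
    values: dict[str, np.ndarray] | list[np.ndarray],
    alpha: float = 0.05,
    higher_is_better: bool = True,
    max_grades: int = 3,
) -> TukeyGrouping:
    """Group replicate measurements and rank groups into grades.

    ``values`` maps sample id to its replicate vector (or is a list of
    vectors).  Samples that share a letter are not significantly
    different at ``alpha``.  Grades rank the letter groups by mean —
    grade 1 is the best group (highest mean by default; pass
    ``higher_is_better=False`` for moisture-like indices) — and a sample
    spanning several letters receives the best of their grades.  Grades
    saturate at ``max_grades``.
    """
    if isinstance(values, dict):
        ids = list(values.keys())
        reps = [np.asarray(values[k], dtype=float) for k in ids]
    else:
        reps = [np.asarray(v, dtype=float) for v in values]
        ids = [f"S{i}" for i in range(len(reps))]
    if len(reps) < 2:
        raise ValueError("need at least 2 samples")
    if any(r.size < 2 for r in reps):
        raise ValueError("need at least 2 replicates per sample")
    n = len(reps)
    means = np.array([r.mean() for r in reps])

    within_var = sum(float(np.sum((r - r.mean()) ** 2)) for r in reps)
    if within_var == 0.0:
        # zero residual variance: any mean difference is significant
        significant = np.abs(means[:, None] - means[None, :]) > 0
        f_stat, p_val = np.inf, 0.0
        if np.all(~significant):
            f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = f_oneway(*reps)
        res = tukey_hsd(*reps)
        significant = res.pvalue < alpha
        np.fill_diagonal(significant, False)

    groups = _compact_letter_display(n, significant)
    group_means = [float(np.mean([means[i] for i in g])) for g in groups]
    order = np.argsort(group_means)
    if higher_is_better:
        order = order[::-1]
    ranked = [groups[k] for k in order]

    letters = ["" for _ in range(n)]
    grades = [max_grades] * n
    for rank, g in enumerate(ranked):
        letter = chr(ord("a") + rank) if rank < 26 else f"g{rank}"
        grade = min(rank + 1, max_grades)
        for i in sorted(g):
            letters[i] += letter
            grades[i] = min(grades[i], grade)
    return TukeyGrouping(
        sample_ids=ids,
        means=means,
        letters=letters,
        grades=grades,
        f_statistic=float(f_stat),
        p_value=float(p_val),
        alpha=alpha,
    )
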