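"""PERCIST-adapted treatment-response classification for SPECT/CT.

Response is judged on the change in the summed SUVmax of up to five target
lesions between a baseline and a follow-up scan:

* CR — no uptake above the healthy-tissue background in any baseline target
  (and none in the follow-up targets) and no new lesions;
* PR — a decrease > 30% in the summed SUVmax;
* SD — a change < 30% in either direction;
* PD — new tumoral foci, or an increase > 30% in the summed SUVmax.

A change of exactly ±30% is classified SD: the PR/PD rules are strict
inequalities and the SD rule is itself stated as "< 30%".  A new-lesion
flag forces PD regardless of the summed change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .quantify import LesionMeasurement

CATEGORIES = ("CR", "PR", "SD", "PD")

#: Symmetric threshold (percent) on the summed-SUVmax change.
RESPONSE_THRESHOLD_PCT = 30.0

#: Maximum number of target lesions entering the summed SUVmax.
MAX_TARGET_LESIONS = 5


class ResponseError(ValueError):
    """Raised for invalid response-classification inputs."""


@dataclass(frozen=True)
class TargetLesionSet:
    """Selected target lesions of one scan and their summed SUVmax."""

    scan_id: str
    patient_id: str
    lesions: Tuple[LesionMeasurement, ...]
    new_lesion_flag: bool
    summed_suv_max: float

    def __post_init__(self) -> None:
        if len(self.lesions) > MAX_TARGET_LESIONS:
            raise ResponseError(f"at most {MAX_TARGET_LESIONS} target lesions allowed")
        expected = sum(m.suv_max for m in self.lesions)
        if abs(self.summed_suv_max - expected) > 1e-9 * max(1.0, expected):
            raise ResponseError("summed_suv_max inconsistent with target lesions")


def select_targets(lesions: Sequence[LesionMeasurement],
                   max_targets: int = MAX_TARGET_LESIONS,
                   scan_id: str = "", patient_id: str = "",
                   new_lesion_flag: bool = False,
                   per_organ_cap: Optional[int] = None) -> TargetLesionSet:
    """Pick the ``max_targets`` hottest lesions as response targets.

    Ordering is by descending SUVmax with ties broken by ascending
    lesion_id.  ``per_organ_cap`` optionally limits targets per site
    (off by default).  An empty input yields an empty set with sum 0.
    """
    ranked = sorted(lesions, key=lambda m: (-m.suv_max, m.lesion_id))
    selected: List[LesionMeasurement] = []
    per_site: dict = {}
    for m in ranked:
        if len(selected) >= max_targets:
            break
        if per_organ_cap is not None and per_site.get(m.site, 0) >= per_organ_cap:
            continue
        selected.append(m)
        per_site[m.site] = per_site.get(m.site, 0) + 1
    return TargetLesionSet(
        scan_id=scan_id, patient_id=patient_id, lesions=tuple(selected),
        new_lesion_flag=new_lesion_flag,
        summed_suv_max=sum(m.suv_max for m in selected),
    )


@dataclass(frozen=True)
class ResponseAssessment:
    patient_id: str
    baseline_scan: str
    followup_scan: str
    delta_pct: float
    category: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ResponseError(f"unknown category {self.category!r}")


def _followup_value(lesion_id: str, followup: TargetLesionSet) -> float:
    """Follow-up SUVmax of a baseline target; absent lesions count as 0."""
    for m in followup.lesions:
        if m.lesion_id == lesion_id:
            return m.suv_max
    return 0.0


def classify_response(baseline: TargetLesionSet, followup: TargetLesionSet,
                      background_suv: float) -> ResponseAssessment:
    """Classify one follow-up scan against a baseline scan.

    ``background_suv`` is the healthy-tissue reference (e.g. healthy-liver
    SUVmax) below which residual uptake counts as resolved for CR.
    Exactly one category is returned for every input pair.
    """
    if background_suv < 0:
        raise ResponseError("background_suv must be non-negative")

    no_new = not followup.new_lesion_flag
    baseline_cleared = all(
        _followup_value(m.lesion_id, followup) <= background_suv
        for m in baseline.lesions
    )
    followup_cleared = all(m.suv_max <= background_suv for m in followup.lesions)

    if no_new and baseline_cleared and followup_cleared:
        delta = (
            100.0 * (followup.summed_suv_max - baseline.summed_suv_max)
            / baseline.summed_suv_max
            if baseline.summed_suv_max > 0 else 0.0
        )
        return ResponseAssessment(baseline.patient_id, baseline.scan_id,
                                  followup.scan_id, delta, "CR")

    if baseline.summed_suv_max <= 0:
        # Re-appearance of uptake after a zero baseline: new focus -> PD.
        return ResponseAssessment(baseline.patient_id, baseline.scan_id,
                                  followup.scan_id, float("inf"), "PD",
                                  note="uptake re-appeared after zero-sum baseline")

    delta = (100.0 * (followup.summed_suv_max - baseline.summed_suv_max)
             / baseline.summed_suv_max)
    if followup.new_lesion_flag:
        category, note = "PD", "new lesions"
    elif delta > RESPONSE_THRESHOLD_PCT:
        category, note = "PD", ""
    elif delta < -RESPONSE_THRESHOLD_PCT:
        category, note = "PR", ""
    else:
        category, note = "SD", ""
    return ResponseAssessment(baseline.patient_id, baseline.scan_id,
                              followup.scan_id, delta, category, note)


def evaluate_patient(scans: Sequence[TargetLesionSet], background_suv: float,
                     comparison_mode: str = "vs_baseline",
                     ) -> Tuple[List[ResponseAssessment], str]:
    """Assess every follow-up of a chronologically ordered scan series.

    ``vs_baseline`` compares each follow-up with the first scan
    (PERCIST-style); ``vs_previous`` with the immediately preceding scan.
    The patient's final category is that of the last follow-up.
    """
    if comparison_mode not in ("vs_baseline", "vs_previous"):
        raise ResponseError(f"unknown comparison_mode {comparison_mode!r}")
    if len(scans) < 2:
        raise ResponseError("at least two consecutive scans are required")
    assessments = []
    for i in range(1, len(scans)):
        ref = scans[0] if comparison_mode == "vs_baseline" else scans[i - 1]
        assessments.append(classify_response(ref, scans[i], background_suv))
    return assessments, assessments[-1].category


def cohort_distribution(final_categories: Sequence[str]) -> dict:
    """Percentage of patients per final category, to two decimals."""
    if len(final_categories) == 0:
        raise ResponseError("at least one patient is required")
    for c in final_categories:
        if c not in CATEGORIES:
            raise ResponseError(f"unknown category {c!r}")
    n = len(final_categories)
    return {
        c: round(100.0 * sum(1 for x in final_categories if x == c) / n, 2)
        for c in CATEGORIES
    }
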