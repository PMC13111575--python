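"""Leakage-safe patient-level train/validation/test partitioning.

Mammography cohorts are heavily correlated within a case: the same breast is
imaged in CC and MLO views, both breasts belong to one patient, and patches
derive from one scan.  Splitting at any finer unit than the case id leaks
near-duplicate images across splits and inflates test performance.  The
splitter here assigns whole cases, stratifies by label with exact
largest-remainder apportionment, and the auditor verifies the property on
any assignment, hand-built or not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np

from .core import CaseRecord

__all__ = ["SplitPlan", "patient_level_split", "audit_leakage", "LeakageReport"]

SPLIT_NAMES = ("train", "val", "test")


@dataclass
class SplitPlan:
    """Fractions, stratification switch, seed, and the resulting assignment."""

    fractions: tuple[float, float, float] = (0.75, 0.12, 0.13)
    stratify_by_label: bool = True
    seed: int = 0
    assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.fractions) != 3 or any(f <= 0 for f in self.fractions):
            raise ValueError("fractions must be three positive reals")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(self.fractions)}")


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Apportion n units to fractions exactly, largest fractional part first.

    Ties between equal remainders keep the fraction order (train, val,
    test), which combined with the seeded shuffle makes the split
    deterministic.
    """
    raw = [n * f for f in fractions]
    base = [int(np.floor(x)) for x in raw]
    short = n - sum(base)
    remainders = sorted(range(len(fractions)),
                        key=lambda k: (-(raw[k] - base[k]), k))
    for k in remainders[:short]:
        base[k] += 1
    return base


def patient_level_split(cases: list[CaseRecord],
                        plan: SplitPlan | None = None) -> SplitPlan:
    """Assign every case id to exactly one of train/val/test.

    The unit of assignment is the case id — never a view or laterality — so
    all images of one case inherit a single split.  Within each label
    stratum, case ids are shuffled with the plan seed and cut at
    largest-remainder boundaries, making split sizes exact to the rounding
    of each stratum.
    """
    plan = plan or SplitPlan()
    case_labels: dict[str, str] = {}
    for c in cases:
        prior = case_labels.get(c.case_id)
        if prior is not None and prior != c.label:
            raise ValueError(f"case {c.case_id} has conflicting labels "
                             f"{prior!r} and {c.label!r}")
        case_labels[c.case_id] = c.label

    if plan.stratify_by_label:
        strata: dict[str, list[str]] = {}
        for cid, lab in case_labels.items():
            strata.setdefault(lab, []).append(cid)
    else:
        strata = {"all": list(case_labels)}

    rng = np.random.default_rng(plan.seed)
    assignment: dict[str, str] = {}
    for label in sorted(strata):
        ids = sorted(strata[label])  # stable base order before shuffling
        if len(ids) < 3:
            raise ValueError(
                f"stratum {label!r} has only {len(ids)} case(s); need at "
                "least 3, or disable stratification"
            )
        rng.shuffle(ids)
        counts = _largest_remainder(len(ids), plan.fractions)
        start = 0
        for split, cnt in zip(SPLIT_NAMES, counts):
            for cid in ids[start:start + cnt]:
                assignment[cid] = split
            start += cnt
    plan.assignment = assignment
    return plan


@dataclass
class LeakageReport:
    """Violations found by the auditor, grouped by type.

    ``case_multi_split`` — one case id assigned to more than one split;
    ``breast_views_split`` — CC/MLO views of one breast in different splits;
    ``lateralities_split`` — left/right breasts of one case split apart.
    """

    case_multi_split: list[str] = field(default_factory=list)
    breast_views_split: list[tuple[str, str]] = field(default_factory=list)
    lateralities_split: list[str] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not (self.case_multi_split or self.breast_views_split
                    or self.lateralities_split)

    def total(self) -> int:
        return (len(self.case_multi_split) + len(self.breast_views_split)
                + len(self.lateralities_split))


AssignmentLike = Union["SplitPlan", Mapping]


def audit_leakage(cases: list[CaseRecord],
                  assignment: AssignmentLike) -> LeakageReport:
    """Audit an assignment for patient-level leakage.

    ``assignment`` may be a :class:`SplitPlan` (case-level mapping) or any
    mapping keyed by case_id or by (case_id, laterality, view) — the latter
    lets hand-built per-image assignments be audited for planted defects.
    """
    if isinstance(assignment, SplitPlan):
        mapping: Mapping = assignment.assignment
    else:
        mapping = assignment

    def split_of(c: CaseRecord) -> str:
        key = (c.case_id, c.laterality, c.view)
        if key in mapping:
            return mapping[key]
        return mapping[c.case_id]

    per_case: dict[str, set[str]] = {}
    per_breast: dict[tuple[str, str], set[str]] = {}
    per_case_lat: dict[str, dict[str, set[str]]] = {}
    for c in cases:
        s = split_of(c)
        per_case.setdefault(c.case_id, set()).add(s)
        per_breast.setdefault((c.case_id, c.laterality), set()).add(s)
        per_case_lat.setdefault(c.case_id, {}).setdefault(c.laterality, set()).add(s)

    report = LeakageReport()
    # most specific violation first: inconsistent views within one breast
    for (cid, lat), splits in sorted(per_breast.items()):
        if len(splits) > 1:
            report.breast_views_split.append((cid, lat))
    flagged_b = {cid for cid, _ in report.breast_views_split}
    # then lateralities of one case landing in different splits
    for cid, lat_map in sorted(per_case_lat.items()):
        if cid in flagged_b or len(lat_map) < 2:
            continue
        sets = list(lat_map.values())
        if any(s != sets[0] for s in sets[1:]):
            report.lateralities_split.append(cid)
    flagged = flagged_b | set(report.lateralities_split)
    # catch-all: a case spanning splits not already explained above
    for cid, splits in sorted(per_case.items()):
        if len(splits) > 1 and cid not in flagged:
            report.case_multi_split.append(cid)
    return report
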