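"""Rule-based morphology categorization of microcalcification samples.

Mirrors the BIRADS vocabulary for suspicious calcifications: a sample is
flagged *fine linear* (fl) when its calcifications are small and rod-like,
*fine pleomorphic* (fp) when small with strongly varying shape, and *coarse
heterogeneous* (ch) when it contains a large object with strongly varying
shape; *no suspicious* (ns) means none of the above.  Flags are evaluated
independently and may co-occur.

Thresholds (defaults):

* fl: mean cube-equivalent diameter < 200 um (strict) and mean SMI in the
  closed interval [2.92, 3.08];
* fp: mean cube-equivalent diameter < 250 um (strict) and SD of SMI > 0.29
  (strict);
* ch: largest sphere-equivalent diameter > 500 um (strict) and SD of SMI
  > 0.5 (strict).

The ch size rule uses the sample's *largest* object because a single coarse
calcification drives that category; the mean diameter of a ch sample can be
well under 500 um.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometry import ObjectMorphometry, SampleMorphometry

GROUP_OF_B_CLASS = {
    "B1": "A",  # normal
    "B2": "A",  # benign
    "B3": "B",  # uncertain malignant potential
    "B4": "B",  # suspicious
    "B5": "C",  # malignant
}

GROUPS = ("A", "B", "C")
FLAG_NAMES = ("fl", "fp", "ch", "ns")


@dataclass
class ClassificationRules:
    """Thresholds of the morphology rule scheme (all overridable)."""

    fl_max_d_cube: float = 200.0
    fl_smi_range: tuple[float, float] = (2.92, 3.08)
    fp_max_d_cube: float = 250.0
    fp_min_sd_smi: float = 0.29
    ch_min_d: float = 500.0
    ch_min_sd_smi: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.fl_smi_range
        if lo > hi:
            raise ValueError("fl_smi_range lower bound exceeds upper bound")
        if not self.fl_max_d_cube < self.fp_max_d_cube < self.ch_min_d:
            raise ValueError(
                "size thresholds must be ordered fl_max_d_cube < fp_max_d_cube < ch_min_d"
            )


@dataclass
class MorphologyFlags:
    """fl/fp/ch booleans; ns is their joint negation (kept consistent)."""

    fl: bool
    fp: bool
    ch: bool
    ns: bool = field(init=False)

    def __post_init__(self) -> None:
        self.ns = not (self.fl or self.fp or self.ch)

    def as_dict(self) -> dict[str, int]:
        return {k: int(getattr(self, k)) for k in FLAG_NAMES}


@dataclass
class CohortRecord:
    """One biopsy sample: histology class, group, morphometry and flags."""

    sample_id: object
    b_class: str
    birads: int
    age: float
    group: str = ""
    morphometry: SampleMorphometry | None = None
    flags: MorphologyFlags | None = None

    def __post_init__(self) -> None:
        expected = assign_group(self.b_class)
        if not self.group:
            self.group = expected
        elif self.group != expected:
            raise ValueError(
                f"group {self.group!r} inconsistent with B-classification {self.b_class!r}"
            )


class ExcludedSampleError(ValueError):
    """Raised when a single-calcification sample reaches categorization."""


def assign_group(b_class: str) -> str:
    """Histologic group: A = B1/B2 (benign), B = B3/B4, C = B5 (malignant)."""
    try:
        return GROUP_OF_B_CLASS[b_class]
    except KeyError:
        raise ValueError(
            f"unknown B-classification {b_class!r}; expected B1..B5"
        ) from None


def classify_sample(
    sample: SampleMorphometry, rules: ClassificationRules | None = None
) -> MorphologyFlags:
    """Apply the sample-level morphology rules to aggregate statistics.

    The size and SMI statistics in the rules are sample-level quantities
    (means and the SD across objects), so this is the primary mode.
    """
    rules = rules or ClassificationRules()
    if sample.n_objects < 1:
        raise ValueError(f"sample {sample.sample_id} has no objects to classify")
    if sample.excluded:
        raise ExcludedSampleError(
            f"sample {sample.sample_id} contains a single calcification and is "
            "excluded from morphology categorization (non-representative)"
        )
    lo, hi = rules.fl_smi_range
    fl = sample.mean_d_cube < rules.fl_max_d_cube and lo <= sample.mean_SMI <= hi
    fp = sample.mean_d_cube < rules.fp_max_d_cube and sample.sd_SMI > rules.fp_min_sd_smi
    ch = sample.max_d_sphere > rules.ch_min_d and sample.sd_SMI > rules.ch_min_sd_smi
    return MorphologyFlags(fl=fl, fp=fp, ch=ch)


def classify_object(
    obj: ObjectMorphometry, rules: ClassificationRules | None = None
) -> MorphologyFlags:
    """Secondary per-object mode of the rule scheme.

    Uses the object's own d_cube and SMI for the fl rule.  The fp and ch
    rules depend on the SD of the SMI, which only exists across a sample's
    objects; per object they are undefined and evaluate to False.
    """
    rules = rules or ClassificationRules()
    lo, hi = rules.fl_smi_range
    fl = obj.d_cube < rules.fl_max_d_cube and lo <= obj.SMI <= hi
    return MorphologyFlags(fl=fl, fp=False, ch=False)


def presence_table(records: list[CohortRecord], flag: str) -> pd.DataFrame:
    """2x3 contingency table (present/absent x group A/B/C) for one flag.

    Excluded samples are dropped first; every group must remain non-empty.
    """
    if flag not in FLAG_NAMES:
        raise ValueError(f"flag must be one of {FLAG_NAMES}, got {flag!r}")
    usable = [
        r for r in records if r.morphometry is None or not r.morphometry.excluded
    ]
    table = pd.DataFrame(
        np.zeros((2, 3), dtype=int), index=["present", "absent"], columns=list(GROUPS)
    )
    for r in usable:
        if r.flags is None:
            raise ValueError(f"sample {r.sample_id} has no morphology flags")
        row = "present" if getattr(r.flags, flag) else "absent"
        table.loc[row, r.group] += 1
    empty = [g for g in GROUPS if table[g].sum() == 0]
    if empty:
        raise ValueError(f"no samples in group(s) {empty}")
    return table


def flags_to_dataframe(records: list[CohortRecord]) -> pd.DataFrame:
    """0/1 flag columns per sample, matching the fixture layout."""
    rows = []
    for r in records:
        entry = {"sample_id": r.sample_id, "group": r.group}
        if r.flags is not None:
            entry.update(r.flags.as_dict())
        rows.append(entry)
    return pd.DataFrame(rows)
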