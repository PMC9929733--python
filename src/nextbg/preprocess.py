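"""Reading-level exclusion cascade.

Three rules are applied in a fixed order to each admission's sorted
observation stream:

1. 5-minute block deduplication — readings are binned into wall-clock
   5-minute blocks (12:15, 12:20, ...); only the earliest reading per
   block is kept.
2. 90-minute adjacency exclusion — a deduplicated reading whose immediate
   predecessor AND successor both lie within 90 minutes is dropped
   (single simultaneous pass; neighbors are evaluated against original
   positions, not re-evaluated after removals).
3. 10-hour next-gap rule — a surviving reading whose next surviving
   reading occurs more than 10 hours later is ineligible as an index
   (prediction) row, but remains available as lookback history.

Index-eligible readings are paired with their successor's glucose as the
prediction target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from nextbg.errors import InclusionError, ValidationError
from nextbg.synthetic_cohort import Admission, BGObservation

BLOCK_MINUTES = 5.0
ADJACENCY_MINUTES = 90.0
MAX_TARGET_GAP_MINUTES = 600.0

EXCLUSION_NONE = "none"
EXCLUSION_DUPLICATE = "duplicate_block"
EXCLUSION_ADJACENCY = "adjacency_90min"
EXCLUSION_NO_TARGET = "no_target_gt_10h"

#: Exclusion values that remove a reading from the analysis stream.
#: ``no_target_gt_10h`` only bars a reading from being an index row; the
#: reading still serves as lookback history.
REMOVAL_EXCLUSIONS = frozenset({EXCLUSION_DUPLICATE, EXCLUSION_ADJACENCY})


@dataclass
class PredictionPair:
    """Index observation paired with its next-reading target.

    Positions refer to the retained (post-removal) sequence of the
    admission, with the target always the immediately following retained
    reading.
    """

    index_pos: int
    target_pos: int
    index_t_minutes: float
    target_t_minutes: float
    index_bg: float
    target_bg: float

    @property
    def gap_hours(self) -> float:
        return (self.target_t_minutes - self.index_t_minutes) / 60.0


@dataclass
class PreprocessReport:
    n_input: int = 0
    n_duplicate_block: int = 0
    n_adjacency: int = 0
    n_no_target: int = 0
    n_terminal: int = 0
    n_retained_index: int = 0

    def check(self) -> None:
        total = (
            self.n_retained_index
            + self.n_duplicate_block
            + self.n_adjacency
            + self.n_no_target
            + self.n_terminal
        )
        if total != self.n_input:
            raise ValidationError(
                f"preprocess count mismatch: {total} classified vs {self.n_input} input"
            )
        for name, value in vars(self).items():
            if value < 0:
                raise ValidationError(f"preprocess report: {name} negative")

    def __add__(self, other: "PreprocessReport") -> "PreprocessReport":
        return PreprocessReport(
            *(a + b for a, b in zip(vars(self).values(), vars(other).values()))
        )


def _check_sorted(observations: Sequence[BGObservation]) -> None:
    t_prev = -math.inf
    for obs in observations:
        if obs.t_minutes <= t_prev:
            raise ValidationError(
                f"observations not strictly sorted at t={obs.t_minutes}"
            )
        t_prev = obs.t_minutes


def assign_blocks(
    observations: Sequence[BGObservation], start_minutes: float = 0.0
) -> Sequence[BGObservation]:
    """Assign each observation the wall-clock 5-minute block containing it.

    ``start_minutes`` is the wall-clock offset of the admission's t=0, so
    blocks align to the clock (a reading at 12:16 or 12:18 falls in the
    12:15 block) rather than to admission-relative offsets.
    """
    _check_sorted(observations)
    for obs in observations:
        obs.block_index = int(math.floor((start_minutes + obs.t_minutes) / BLOCK_MINUTES))
    return observations


def dedup_blocks(observations: Sequence[BGObservation]) -> Sequence[BGObservation]:
    """Flag every non-earliest reading within each 5-minute block."""
    seen: int | None = None
    for obs in observations:
        if obs.block_index is None:
            raise ValidationError("dedup_blocks requires block_index (run assign_blocks)")
        if obs.block_index == seen:
            obs.exclusion = EXCLUSION_DUPLICATE
        else:
            seen = obs.block_index
    return observations


def exclude_adjacent(observations: Sequence[BGObservation]) -> Sequence[BGObservation]:
    """Flag readings whose original neighbors are both within 90 minutes.

    Operates on the deduplicated working sequence (readings not already
    flagged as block duplicates).  One simultaneous pass: all flags are
    decided from the pre-removal neighbor structure, so removing one
    reading never makes another eligible.  First and last readings are
    never flagged.
    """
    working = [o for o in observations if o.exclusion not in REMOVAL_EXCLUSIONS]
    if len(working) < 3:
        return observations
    t = np.array([o.t_minutes for o in working])
    gap_prev = np.diff(t)  # gap_prev[i-1] = t[i] - t[i-1]
    flag = (gap_prev[:-1] <= ADJACENCY_MINUTES) & (gap_prev[1:] <= ADJACENCY_MINUTES)
    for i in np.nonzero(flag)[0]:
        working[i + 1].exclusion = EXCLUSION_ADJACENCY
    return observations


def mark_index_eligibility(
    observations: Sequence[BGObservation],
) -> tuple[Sequence[BGObservation], list[PredictionPair]]:
    """Pair surviving readings with their next-reading targets.

    A surviving reading whose next surviving reading falls more than 10
    hours later is flagged ``no_target_gt_10h``; it is not an index row
    but remains in the retained sequence as lookback history, as does the
    terminal reading.
    """
    retained = [o for o in observations if o.exclusion not in REMOVAL_EXCLUSIONS]
    pairs: list[PredictionPair] = []
    for i in range(len(retained) - 1):
        cur, nxt = retained[i], retained[i + 1]
        if nxt.t_minutes - cur.t_minutes <= MAX_TARGET_GAP_MINUTES:
            pairs.append(
                PredictionPair(
                    index_pos=i,
                    target_pos=i + 1,
                    index_t_minutes=cur.t_minutes,
                    target_t_minutes=nxt.t_minutes,
                    index_bg=cur.glucose,
                    target_bg=nxt.glucose,
                )
            )
        else:
            cur.exclusion = EXCLUSION_NO_TARGET
    return observations, pairs


def preprocess_admission(
    admission: Admission,
) -> tuple[list[BGObservation], list[PredictionPair], PreprocessReport]:
    """Run the full cascade on one admission.

    Returns the retained observation sequence (analysis stream: everything
    not removed by deduplication or the adjacency rule), the index/target
    prediction pairs, and a reconciled count report.
    """
    observations = admission.observations
    if len(observations) < 4:
        raise InclusionError(
            f"admission {admission.admission_id}: fewer than 4 BG measurements"
        )
    assign_blocks(observations, start_minutes=admission.start_minutes)
    dedup_blocks(observations)
    exclude_adjacent(observations)
    _, pairs = mark_index_eligibility(observations)

    retained = [o for o in observations if o.exclusion not in REMOVAL_EXCLUSIONS]
    report = PreprocessReport(
        n_input=len(observations),
        n_duplicate_block=sum(o.exclusion == EXCLUSION_DUPLICATE for o in observations),
        n_adjacency=sum(o.exclusion == EXCLUSION_ADJACENCY for o in observations),
        n_no_target=sum(o.exclusion == EXCLUSION_NO_TARGET for o in observations),
        n_terminal=1 if retained else 0,
        n_retained_index=len(pairs),
    )
    report.check()
    return retained, pairs, report


def preprocess_cohort(
    admissions: Sequence[Admission],
) -> tuple[dict[str, list[BGObservation]], dict[str, list[PredictionPair]], PreprocessReport]:
    """Apply :func:`preprocess_admission` across a cohort, summing reports."""
    retained_by_adm: dict[str, list[BGObservation]] = {}
    pairs_by_adm: dict[str, list[PredictionPair]] = {}
    total = PreprocessReport()
    for adm in admissions:
        retained, pairs, report = preprocess_admission(adm)
        retained_by_adm[adm.admission_id] = retained
        pairs_by_adm[adm.admission_id] = pairs
        total = total + report
    return retained_by_adm, pairs_by_adm, total
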