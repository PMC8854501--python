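"""Donor selection for transfer learning by patient similarity.

A new patient under anaesthesia cannot wait for a model to be trained on
their own data, so a pre-trained model is borrowed from the most similar
previous patient and applied without any retraining.  Similarity is defined
on demographics available before induction: first restrict donors to those
within a 2-year age difference, then pick the one with the minimum absolute
BMI difference.  For group comparisons, a pair of patients counts as
"similar" when both |delta age| <= 2 years and |delta BMI| <= 3 kg/m^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .errors import ConfigError
from .synthetic_cohort import PatientRecord

__all__ = [
    "SimilarityRule",
    "find_most_similar",
    "is_similar_pair",
    "select_random_donor",
    "similarity_sort_key",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityRule:
    """Thresholds of the similarity rule.

    ``age_window`` gates donor selection; ``group_age_threshold`` and
    ``group_bmi_threshold`` define pairwise similarity-group membership.
    ``inclusive`` reads "within a 2-year difference" as <= (the default).
    """

    age_window: float = 2.0
    group_age_threshold: float = 2.0
    group_bmi_threshold: float = 3.0
    inclusive: bool = True

    def validate(self) -> None:
        if min(self.age_window, self.group_age_threshold, self.group_bmi_threshold) <= 0:
            raise ConfigError("all similarity thresholds must be > 0")

    def _within(self, diff: float, threshold: float) -> bool:
        return diff <= threshold if self.inclusive else diff < threshold


def similarity_sort_key(
    target: PatientRecord, candidate: PatientRecord, rule: SimilarityRule
) -> Tuple[int, float, float, str]:
    """Total-order key ranking donors for ``target``; smallest wins.

    Candidates inside the age window come first, ordered by |dBMI| then
    |dAge| then id; outside the window the fallback orders by |dAge| then
    |dBMI| then id.
    """
    d_age = abs(candidate.age - target.age)
    d_bmi = abs(candidate.bmi - target.bmi)
    if rule._within(d_age, rule.age_window):
        return (0, d_bmi, d_age, candidate.patient_id)
    return (1, d_age, d_bmi, candidate.patient_id)


def find_most_similar(
    target: PatientRecord, candidates: Sequence[PatientRecord], rule: SimilarityRule | None = None
) -> str:
    """Pick the donor patient whose model should be transferred to ``target``.

    Among candidates within the age window, returns the one with minimal
    |delta BMI| (ties: smaller |delta age|, then lexicographically smallest
    id).  If no candidate is inside the age window, falls back to the
    nearest-age candidate (ties: |delta BMI|, then id) with a logged
    warning — a hard failure would leave age-isolated patients without a
    donor in leave-one-out evaluation.
    """
    rule = rule or SimilarityRule()
    rule.validate()
    if not candidates:
        raise ConfigError("candidate list is empty")
    if any(c.patient_id == target.patient_id for c in candidates):
        raise ConfigError(f"target {target.patient_id!r} must not appear among candidates")
    best = min(candidates, key=lambda c: similarity_sort_key(target, c, rule))
    if not rule._within(abs(best.age - target.age), rule.age_window):
        logger.warning(
            "no candidate within %.1f years of patient %s (age %.1f); "
            "falling back to nearest-age donor %s",
            rule.age_window,
            target.patient_id,
            target.age,
            best.patient_id,
        )
    return best.patient_id


def is_similar_pair(
    p: PatientRecord, q: PatientRecord, rule: SimilarityRule | None = None
) -> bool:
    """True when the pair satisfies both group thresholds (age AND BMI).

    Symmetric in (p, q)."""
    rule = rule or SimilarityRule()
    rule.validate()
    return rule._within(abs(p.age - q.age), rule.group_age_threshold) and rule._within(
        abs(p.bmi - q.bmi), rule.group_bmi_threshold
    )


def select_random_donor(
    target: PatientRecord, candidates: Sequence[PatientRecord], seed: int
) -> str:
    """Uniform random donor choice — the baseline transfer strategy.

    Deterministic given ``seed``; the target must not be in the pool.
    """
    if not candidates:
        raise ConfigError("candidate list is empty")
    if any(c.patient_id == target.patient_id for c in candidates):
        raise ConfigError(f"target {target.patient_id!r} must not appear among candidates")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    return candidates[int(rng.integers(len(candidates)))].patient_id
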