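"""RMSE and the three evaluation experiments.

Experiments mirror the three questions the analysis asks of a cohort:

1. **Per-patient prediction** — train on each patient's first half, forecast
   their second half one step at a time, and summarise RMSE across patients.
2. **Pairwise transfer** — predict every patient's test half with every
   other patient's pre-trained model; split the ordered pairs into
   demographically similar and dissimilar groups and compare group RMSEs
   with a t-test.
3. **Leave-one-out transfer** — for each held-out patient, transfer the
   model of the most similar donor and of randomly chosen donors, and
   compare the two arms.

All RMSEs are on the unscaled 0-100 TOFR percent scale.  Group summaries
report mean +/- sample standard deviation (ddof=1; a single-member group
reports std 0).  Donor models are always trained on the donor's own first
half — the same predictors serve all three experiments, so the similarity
arm of the leave-one-out experiment reproduces the corresponding entries of
the pairwise table exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import ConfigError, TofcastError
from .preprocessing import (
    DEFAULT_WINDOW_SIZE,
    SplitSeries,
    WindowSet,
    make_windows,
    scale_series,
    split_half,
)
from .seeding import derive_seed
from .sequence_models import (
    ForecastRecord,
    ModelSpec,
    TrainedPredictor,
    baseline_persistence,
    forecast_test_half,
    train_predictor,
)
from .synthetic_cohort import PatientRecord
from .transfer import SimilarityRule, find_most_similar, is_similar_pair, select_random_donor

__all__ = [
    "ExperimentReport",
    "rmse",
    "rmse_of_records",
    "welch_t_test",
    "prepare_patient",
    "train_cohort_predictors",
    "run_per_patient",
    "run_persistence",
    "run_pairwise",
    "run_loocv_transfer",
]

logger = logging.getLogger(__name__)


@dataclass
class ExperimentReport:
    """Result bundle of one experiment run.

    ``group_stats`` maps a group label to (mean, std, count); ``comparison``
    holds (t_statistic, p_value, test_name) when a two-group test was run.
    ``pair_rmse`` (pairwise experiment only) maps (target_id, donor_id) to
    the RMSE of predicting the target's test half with the donor's model.
    """

    experiment: str
    model_kind: str
    per_patient_rmse: Dict[str, float] = field(default_factory=dict)
    group_stats: Dict[str, Tuple[float, float, int]] = field(default_factory=dict)
    comparison: Optional[Tuple[float, float, str]] = None
    config_echo: Dict[str, object] = field(default_factory=dict)
    seeds: Dict[str, int] = field(default_factory=dict)
    skipped: List[str] = field(default_factory=list)
    pair_rmse: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def to_dict(self) -> Dict[str, object]:
        """JSON-ready representation (tuple keys flattened to 'target|donor')."""
        d: Dict[str, object] = {
            "experiment": self.experiment,
            "model_kind": self.model_kind,
            "config_echo": self.config_echo,
            "seeds": self.seeds,
            "per_patient_rmse": self.per_patient_rmse,
            "group_stats": {
                k: {"mean": m, "std": s, "count": c} for k, (m, s, c) in self.group_stats.items()
            },
            "comparison": (
                None
                if self.comparison is None
                else {
                    "t_statistic": self.comparison[0],
                    "p_value": self.comparison[1],
                    "test_name": self.comparison[2],
                }
            ),
            "skipped": self.skipped,
        }
        if self.pair_rmse:
            d["pair_rmse"] = {f"{t}|{s}": v for (t, s), v in self.pair_rmse.items()}
        return d


def rmse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root mean square error, sqrt(mean((x_i - xhat_i)^2)).

    Zero iff the sequences are identical; multiplying both by c scales the
    result by |c|.
    """
    x = np.asarray(observed, dtype=float)
    xhat = np.asarray(predicted, dtype=float)
    if x.shape != xhat.shape or x.ndim != 1:
        raise ConfigError(f"observed and predicted must be equal-length 1-D, got {x.shape} vs {xhat.shape}")
    if x.size == 0:
        raise ConfigError("rmse needs at least one paired point")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(xhat))):
        raise ConfigError("rmse inputs must be finite")
    return float(np.sqrt(np.mean((x - xhat) ** 2)))


def rmse_of_records(records: Sequence[ForecastRecord]) -> float:
    """RMSE over a walk-forward forecast's (observed, predicted) pairs."""
    return rmse([r.observed for r in records], [r.predicted for r in records])


def welch_t_test(
    a: Sequence[float], b: Sequence[float], equal_var: bool = False
) -> Tuple[float, float]:
    """Two-sided t-test between two RMSE groups (Welch by default).

    Degenerate convention: if both groups have zero variance and equal
    means, returns (0.0, 1.0); zero variance with unequal means returns
    (+/-inf, 0.0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigError("each group needs at least 2 values for a t-test")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ConfigError("t-test inputs must be finite")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float(np.sign(np.mean(a) - np.mean(b)) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# pipeline helpers


def prepare_patient(
    record: PatientRecord, window_size: int = DEFAULT_WINDOW_SIZE
) -> Tuple[SplitSeries, WindowSet]:
    """Split a patient's series and build scaled training windows."""
    split = split_half(record.series)
    windows = make_windows(scale_series(split.train), window_size)
    return split, windows


def train_cohort_predictors(
    cohort: Sequence[PatientRecord],
    spec: ModelSpec,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> Dict[str, TrainedPredictor]:
    """Fit one predictor per patient on that patient's own first half.

    Each patient's training seed is derived from (spec.seed, kind, id), so
    no two patients share a weight-initialisation stream.
    """
    predictors: Dict[str, TrainedPredictor] = {}
    for record in cohort:
        _, windows = prepare_patient(record, window_size)
        patient_spec = ModelSpec(
            kind=spec.kind,
            hidden_units=spec.hidden_units,
            epochs=spec.epochs,
            learning_rate=spec.learning_rate,
            batch_size=spec.batch_size,
            seed=derive_seed(spec.seed, "train", spec.kind, record.patient_id),
        )
        predictors[record.patient_id] = train_predictor(
            windows, patient_spec, donor_id=record.patient_id
        )
    return predictors


def _group_stats(values: Sequence[float]) -> Tuple[float, float, int]:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return float("nan"), float("nan"), 0
    std = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return float(np.mean(v)), std, int(v.size)


# ---------------------------------------------------------------------------
# experiments


def run_per_patient(
    cohort: Sequence[PatientRecord],
    spec: ModelSpec,
    window_size: int = DEFAULT_WINDOW_SIZE,
    predictors: Optional[Dict[str, TrainedPredictor]] = None,
) -> ExperimentReport:
    """Per-patient one-step forecasting of each patient's own test half."""
    if len(cohort) < 1:
        raise ConfigError("cohort must contain at least one patient")
    spec.validate()
    report = ExperimentReport(
        experiment="per_patient",
        model_kind=spec.kind,
        config_echo={"model": spec.__dict__, "window_size": window_size},
        seeds={"model": spec.seed},
    )
    for record in cohort:
        try:
            split, windows = prepare_patient(record, window_size)
            predictor = (
                predictors[record.patient_id]
                if predictors is not None
                else train_predictor(
                    windows,
                    ModelSpec(
                        kind=spec.kind,
                        hidden_units=spec.hidden_units,
                        epochs=spec.epochs,
                        learning_rate=spec.learning_rate,
                        batch_size=spec.batch_size,
                        seed=derive_seed(spec.seed, "train", spec.kind, record.patient_id),
                    ),
                    donor_id=record.patient_id,
                )
            )
            records = forecast_test_half(predictor, split)
            report.per_patient_rmse[record.patient_id] = rmse_of_records(records)
        except TofcastError as exc:
            logger.warning("skipping patient %s: %s", record.patient_id, exc)
            report.skipped.append(record.patient_id)
    report.group_stats["all"] = _group_stats(list(report.per_patient_rmse.values()))
    return report


def run_persistence(
    cohort: Sequence[PatientRecord], window_size: int = DEFAULT_WINDOW_SIZE
) -> ExperimentReport:
    """Persistence (previous-value) baseline over each patient's test half."""
    report = ExperimentReport(experiment="persistence", model_kind="persistence")
    for record in cohort:
        try:
            split = split_half(record.series)
            report.per_patient_rmse[record.patient_id] = rmse_of_records(
                baseline_persistence(split)
            )
        except TofcastError as exc:
            logger.warning("skipping patient %s: %s", record.patient_id, exc)
            report.skipped.append(record.patient_id)
    report.group_stats["all"] = _group_stats(list(report.per_patient_rmse.values()))
    return report


def run_pairwise(
    cohort: Sequence[PatientRecord],
    spec: ModelSpec,
    rule: SimilarityRule | None = None,
    window_size: int = DEFAULT_WINDOW_SIZE,
    predictors: Optional[Dict[str, TrainedPredictor]] = None,
    ordered: bool = True,
) -> ExperimentReport:
    """Cross-patient transfer over all pairs, grouped by similarity.

    For every ordered pair (target, donor), the donor's pre-trained model
    forecasts the target's test half.  Pair RMSEs are grouped by
    :func:`is_similar_pair` and the groups compared with a Welch t-test.
    Set ``ordered=False`` to de-duplicate to unordered pairs (keeping both
    directions' RMSEs averaged is NOT done; the (i, j) direction with
    i < j is kept).
    """
    rule = rule or SimilarityRule()
    rule.validate()
    spec.validate()
    if len(cohort) < 3:
        raise ConfigError("pairwise experiment needs at least 3 patients")
    if predictors is None:
        predictors = train_cohort_predictors(cohort, spec, window_size)
    report = ExperimentReport(
        experiment="pairwise",
        model_kind=spec.kind,
        config_echo={
            "model": spec.__dict__,
            "similarity": rule.__dict__,
            "window_size": window_size,
            "ordered": ordered,
        },
        seeds={"model": spec.seed},
    )
    splits = {r.patient_id: split_half(r.series) for r in cohort}
    by_id = {r.patient_id: r for r in cohort}
    similar: List[float] = []
    dissimilar: List[float] = []
    for target in cohort:
        for donor in cohort:
            if donor.patient_id == target.patient_id:
                continue
            if not ordered and donor.patient_id < target.patient_id:
                continue
            try:
                records = forecast_test_half(predictors[donor.patient_id], splits[target.patient_id])
                value = rmse_of_records(records)
            except TofcastError as exc:
                logger.warning(
                    "skipping pair (%s <- %s): %s", target.patient_id, donor.patient_id, exc
                )
                report.skipped.append(f"{target.patient_id}|{donor.patient_id}")
                continue
            report.pair_rmse[(target.patient_id, donor.patient_id)] = value
            if is_similar_pair(by_id[target.patient_id], donor, rule):
                similar.append(value)
            else:
                dissimilar.append(value)
    report.group_stats["similar"] = _group_stats(similar)
    report.group_stats["dissimilar"] = _group_stats(dissimilar)
    if len(similar) >= 2 and len(dissimilar) >= 2:
        t, p = welch_t_test(similar, dissimilar)
        report.comparison = (t, p, "welch_t")
    else:
        logger.warning("one similarity group is too small; t-test omitted")
    return report


def run_loocv_transfer(
    cohort: Sequence[PatientRecord],
    spec: ModelSpec,
    rule: SimilarityRule | None = None,
    n_random_draws: int = 10,
    seed: int = 0,
    window_size: int = DEFAULT_WINDOW_SIZE,
    predictors: Optional[Dict[str, TrainedPredictor]] = None,
) -> ExperimentReport:
    """Leave-one-out transfer: similarity-selected vs random donors.

    Each patient in turn is held out; all others form the donor pool.  The
    similarity arm transfers the model of :func:`find_most_similar`; the
    random arm averages the RMSE of ``n_random_draws`` uniformly drawn
    donors (seeded per patient and draw).  Donor models are the shared
    first-half predictors, so the similarity arm agrees exactly with the
    pairwise experiment's corresponding entries.
    """
    rule = rule or SimilarityRule()
    rule.validate()
    spec.validate()
    if len(cohort) < 3:
        raise ConfigError("leave-one-out transfer needs at least 3 patients")
    if n_random_draws < 1:
        raise ConfigError("n_random_draws must be >= 1")
    if predictors is None:
        predictors = train_cohort_predictors(cohort, spec, window_size)
    report = ExperimentReport(
        experiment="loocv_transfer",
        model_kind=spec.kind,
        config_echo={
            "model": spec.__dict__,
            "similarity": rule.__dict__,
            "n_random_draws": n_random_draws,
            "window_size": window_size,
        },
        seeds={"model": spec.seed, "random_arm": seed},
    )
    splits = {r.patient_id: split_half(r.series) for r in cohort}
    similarity_arm: List[float] = []
    random_arm: List[float] = []
    random_per_patient: Dict[str, float] = {}
    for held_out in cohort:
        pool = [r for r in cohort if r.patient_id != held_out.patient_id]
        try:
            donor_id = find_most_similar(held_out, pool, rule)
            sim_rmse = rmse_of_records(
                forecast_test_half(predictors[donor_id], splits[held_out.patient_id])
            )
            draws = []
            for k in range(n_random_draws):
                rand_id = select_random_donor(
                    held_out, pool, derive_seed(seed, "random_donor", held_out.patient_id, k)
                )
                draws.append(
                    rmse_of_records(
                        forecast_test_half(predictors[rand_id], splits[held_out.patient_id])
                    )
                )
        except TofcastError as exc:
            logger.warning("skipping held-out patient %s: %s", held_out.patient_id, exc)
            report.skipped.append(held_out.patient_id)
            continue
        report.per_patient_rmse[held_out.patient_id] = sim_rmse
        random_per_patient[held_out.patient_id] = float(np.mean(draws))
        similarity_arm.append(sim_rmse)
        random_arm.append(float(np.mean(draws)))
    report.group_stats["similarity"] = _group_stats(similarity_arm)
    report.group_stats["random"] = _group_stats(random_arm)
    report.config_echo["random_arm_per_patient"] = random_per_patient
    return report
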