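"""Train/test protocols, confusion matrices and diagnostics.

The evaluation protocol splits dyads (never individual events) into a
training fraction (default 30%) used to fit the relation pdfs and a test
remainder, repeats the random split (default 50 times), and reports the mean
confusion matrix with per-cell standard errors across repetitions.

Three confusion-matrix flavours exist:

* by-event      — each (dyad, t) event counts once; cell (i, j) is the share
                  of ground-truth-i events whose per-event argmax is j;
* by-trajectory — each dyad counts once through the plurality vote of its
                  per-event winners;
* metric        — each dyad counts once through the functional-metric argmin.

Rows are ground truth, columns assigned classes, entries row-normalized
percentages.  The hierarchical protocol first separates work-oriented
(colleagues) from leisure-oriented dyads (stage 1, reported as a 2x2 and a
4x2 table), then distinguishes families/couples/friends among leisure dyads
only (stage 2, 3x3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bayes import (
    PosteriorTrace,
    classify_events,
    event_votes,
    representation_prior,
    uniform_prior,
    vote_trajectory,
)
from .distributions import (
    DEFAULT_GEOMETRY,
    RelationModel,
    fit_relation_models,
    meta_category_model,
)
from .io import LEISURE_RELATIONS, RELATIONS, WORK_LEISURE, DyadRecord, ValidationError
from .metrics import build_dyad_pdf, classify_trajectory_metric
from .observables import extract_observations

logger = logging.getLogger(__name__)

MODES = ("flat", "hierarchical_stage1", "hierarchical_stage2")
CLASSIFIERS = ("bayes", "emd", "kl", "js")


def to_meta(relation: str) -> str:
    """Map a relation to its work/leisure meta-category."""
    return "work" if relation == "colleagues" else "leisure"


@dataclass
class ConfusionMatrix:
    """Row-normalized percentage confusion matrix with optional cell SEs."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    values: np.ndarray                       # (n_rows, n_cols), percentages
    sem: np.ndarray | None = None            # standard errors, same shape

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        rows = self.values.sum(axis=1)
        if np.any(np.abs(rows - 100.0) > 0.01):
            raise ValidationError(f"confusion rows must sum to 100%, got {rows}")

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        row_labels: Sequence[str],
        col_labels: Sequence[str],
    ) -> "ConfusionMatrix":
        counts = np.asarray(counts, dtype=float)
        totals = counts.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            empty = [row_labels[i] for i in np.flatnonzero(totals[:, 0] == 0)]
            raise ValidationError(f"no test items for ground-truth classes {empty}")
        return cls(tuple(row_labels), tuple(col_labels), 100.0 * counts / totals)

    def accuracy(self, gt_weights: np.ndarray | None = None) -> float:
        """Overall correct-recognition rate in percent.

        Diagonal cells (matched by label, so the 4x2 stage-1 table scores
        detailed rows against their meta-category) weighted by the ground
        truth composition; unweighted rows average if weights are omitted.
        """
        diag = np.array(
            [
                self.values[i, self.col_labels.index(to_meta(r))]
                if r not in self.col_labels and to_meta(r) in self.col_labels
                else self.values[i, self.col_labels.index(r)]
                for i, r in enumerate(self.row_labels)
            ]
        )
        if gt_weights is None:
            return float(diag.mean())
        w = np.asarray(gt_weights, dtype=float)
        return float((diag * w).sum() / w.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.row_labels),
                            columns=list(self.col_labels))

    def pretty(self, title: str = "") -> str:
        """Plain-text table: GT rows, assigned columns, percentages."""
        lines = [title] if title else []
        header = "GT \\ assigned".ljust(16) + "".join(
            c[:12].rjust(13) for c in self.col_labels)
        lines.append(header)
        for i, r in enumerate(self.row_labels):
            cells = "".join(f"{v:13.2f}" for v in self.values[i])
            lines.append(r[:16].ljust(16) + cells)
        return "\n".join(lines)


@dataclass
class ExperimentConfig:
    """Full specification of one evaluation run."""

    mode: str = "flat"
    classifier: str = "bayes"
    alpha: float = 1.0
    training_fraction: float = 0.30
    repetitions: int = 50
    seed: int = 0
    median_filter: bool = False
    children_only_families: bool = False
    prior: str = "uniform"                  # "uniform" | "representation"
    geometry: Mapping[str, tuple[float, float, int]] = field(
        default_factory=lambda: dict(DEFAULT_GEOMETRY))
    freeze_prior_on_invalid: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")
        if not 0.0 < self.training_fraction < 1.0:
            raise ValueError("training_fraction must lie in (0, 1)")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


def split_dyads(
    dyads: Sequence[DyadRecord], fraction: float, rng: np.random.Generator
) -> tuple[list[DyadRecord], list[DyadRecord]]:
    """Random disjoint, exhaustive train/test split at the dyad level."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    idx = rng.permutation(len(dyads))
    n_train = int(round(fraction * len(dyads)))
    n_train = min(max(n_train, 1), len(dyads) - 1)
    train = [dyads[i] for i in idx[:n_train]]
    test = [dyads[i] for i in idx[n_train:]]
    return train, test


def filter_by_median_length(items: Sequence, lengths: Sequence[int]) -> list:
    """Keep items whose event count strictly exceeds the median count."""
    med = float(np.median(np.asarray(lengths)))
    return [item for item, n in zip(items, lengths) if n > med]


def families_with_children_filter(dyads: Sequence[DyadRecord]) -> list[DyadRecord]:
    """Restrict family dyads to those with a member aged <= 15.

    Other relations pass through untouched.  Family dyads must carry ages.
    """
    kept = []
    for d in dyads:
        if d.relation != "families":
            kept.append(d)
            continue
        if d.age_a is None or d.age_b is None:
            raise ValidationError(f"family dyad {d.dyad_id!r} lacks age annotations")
        if min(d.age_a, d.age_b) <= 15:
            kept.append(d)
    return kept


# ---------------------------------------------------------------------------
# confusion-matrix constructors


def _count_matrix(
    pairs: Sequence[tuple[str, str]],
    row_labels: Sequence[str],
    col_labels: Sequence[str],
) -> ConfusionMatrix:
    counts = np.zeros((len(row_labels), len(col_labels)))
    ri = {r: i for i, r in enumerate(row_labels)}
    ci = {c: j for j, c in enumerate(col_labels)}
    for gt, assigned in pairs:
        counts[ri[gt], ci[assigned]] += 1
    return ConfusionMatrix.from_counts(counts, row_labels, col_labels)


def confusion_by_event(
    traces: Sequence[PosteriorTrace],
    ground_truth: Sequence[str],
    rng: np.random.Generator,
    row_labels: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Event-level confusion: every (dyad, t) pair counts once."""
    col_labels = traces[0].relations
    row_labels = tuple(row_labels or col_labels)
    pairs = [
        (gt, vote)
        for trace, gt in zip(traces, ground_truth)
        for vote in event_votes(trace, rng)
    ]
    return _count_matrix(pairs, row_labels, col_labels)


def confusion_by_trajectory_voting(
    traces: Sequence[PosteriorTrace],
    ground_truth: Sequence[str],
    rng: np.random.Generator,
    row_labels: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Trajectory-level confusion from the per-dyad plurality vote."""
    col_labels = traces[0].relations
    row_labels = tuple(row_labels or col_labels)
    pairs = [
        (gt, vote_trajectory(trace, rng))
        for trace, gt in zip(traces, ground_truth)
    ]
    return _count_matrix(pairs, row_labels, col_labels)


def confusion_metric(
    assignments: Sequence[str],
    ground_truth: Sequence[str],
    col_labels: Sequence[str],
    row_labels: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Dyad-level confusion for the functional-metric classifier."""
    row_labels = tuple(row_labels or col_labels)
    return _count_matrix(list(zip(ground_truth, assignments)), row_labels, col_labels)


# ---------------------------------------------------------------------------
# the experiment driver


def _dyad_class_counts(dyads: Sequence[DyadRecord], labels: Sequence[str],
                       label_of: Callable[[DyadRecord], str]) -> dict[str, int]:
    counts = {lab: 0 for lab in labels}
    for d in dyads:
        counts[label_of(d)] += 1
    return counts


@dataclass
class ExperimentResult:
    """Mean confusion matrices over repetitions, plus the per-rep matrices."""

    config: ExperimentConfig
    matrices: dict[str, ConfusionMatrix]
    per_rep: dict[str, list[ConfusionMatrix]]


def run_experiment(
    config: ExperimentConfig,
    dyads: Sequence[DyadRecord],
    observations: Mapping[str, Sequence] | None = None,
) -> ExperimentResult:
    """Run the repeated-split protocol and average confusion matrices.

    ``observations`` maps dyad_id to a precomputed observation sequence;
    missing entries are extracted on the fly (and cached for later reps).
    Repetitions whose training (or test) split misses a class in play are
    resampled with a logged warning.  With a fixed seed the whole run is
    reproducible bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    obs_cache = dict(observations or {})

    def obs_of(d: DyadRecord):
        if d.dyad_id not in obs_cache:
            obs_cache[d.dyad_id] = extract_observations(d)
        return obs_cache[d.dyad_id]

    dyads = list(dyads)
    if config.children_only_families:
        dyads = families_with_children_filter(dyads)
    if config.mode == "hierarchical_stage2":
        dyads = [d for d in dyads if d.relation in LEISURE_RELATIONS]
        relations_in_play: tuple[str, ...] = LEISURE_RELATIONS
        label_of = lambda d: d.relation
    elif config.mode == "hierarchical_stage1":
        relations_in_play = WORK_LEISURE
        label_of = lambda d: to_meta(d.relation)
    else:
        relations_in_play = RELATIONS
        label_of = lambda d: d.relation

    per_rep: dict[str, list[ConfusionMatrix]] = {}
    for _ in range(config.repetitions):
        for _attempt in range(100):
            train, test = split_dyads(dyads, config.training_fraction, rng)
            train_counts = _dyad_class_counts(train, relations_in_play, label_of)
            test_counts = _dyad_class_counts(test, relations_in_play, label_of)
            if min(train_counts.values()) > 0 and min(test_counts.values()) > 0:
                break
            logger.warning("degenerate split (class missing); resampling")
        else:
            raise ValidationError("could not draw a split covering every class")

        model = _fit_for_mode(config, train, obs_of)
        rep = _classify_and_score(config, model, train, test, obs_of, label_of, rng)
        for key, cm in rep.items():
            per_rep.setdefault(key, []).append(cm)

    matrices = {}
    for key, cms in per_rep.items():
        stack = np.stack([cm.values for cm in cms])
        mean = stack.mean(axis=0)
        mean = 100.0 * mean / mean.sum(axis=1, keepdims=True)
        sem = (stack.std(axis=0, ddof=1) / np.sqrt(len(cms))
               if len(cms) > 1 else np.zeros_like(mean))
        matrices[key] = ConfusionMatrix(cms[0].row_labels, cms[0].col_labels,
                                        mean, sem)
    return ExperimentResult(config=config, matrices=matrices, per_rep=per_rep)


def _fit_for_mode(config: ExperimentConfig, train, obs_of) -> RelationModel:
    if config.mode == "hierarchical_stage2":
        relations = LEISURE_RELATIONS
    else:
        relations = RELATIONS
    model = fit_relation_models(
        [(d, obs_of(d)) for d in train],
        geometry=config.geometry,
        relations=relations,
    )
    if config.mode == "hierarchical_stage1":
        counts = _dyad_class_counts(
            [d for d in train if d.relation in LEISURE_RELATIONS],
            LEISURE_RELATIONS, lambda d: d.relation)
        total = sum(counts.values())
        weights = {rel: counts[rel] / total for rel in LEISURE_RELATIONS}
        model = meta_category_model(model, weights)
    return model


def _classify_and_score(
    config: ExperimentConfig, model: RelationModel, train, test, obs_of,
    label_of, rng: np.random.Generator,
) -> dict[str, ConfusionMatrix]:
    gt_meta = [label_of(d) for d in test]
    out: dict[str, ConfusionMatrix] = {}

    if config.classifier == "bayes":
        if config.prior == "representation":
            counts = _dyad_class_counts(train, model.relations,
                                        label_of if config.mode == "hierarchical_stage1"
                                        else (lambda d: d.relation))
            p0 = representation_prior(model.relations, counts)
        else:
            p0 = uniform_prior(model.relations)
        traces = [
            classify_events(obs_of(d), model, alpha=config.alpha, p0=p0,
                            dyad_id=d.dyad_id,
                            freeze_prior_on_invalid=config.freeze_prior_on_invalid)
            for d in test
        ]
        lengths = [tr.n_events for tr in traces]
        out["by_event"] = confusion_by_event(traces, gt_meta, rng)
        out["by_trajectory"] = confusion_by_trajectory_voting(traces, gt_meta, rng)
        if config.mode == "hierarchical_stage1":
            detailed_gt = [d.relation for d in test]
            out["by_event_detailed"] = confusion_by_event(
                traces, detailed_gt, rng, row_labels=RELATIONS)
        if config.median_filter:
            sel = filter_by_median_length(list(range(len(traces))), lengths)
            out["by_trajectory_median_filtered"] = confusion_by_trajectory_voting(
                [traces[i] for i in sel], [gt_meta[i] for i in sel], rng)
    else:
        pdfs, kept = [], []
        for i, d in enumerate(test):
            try:
                pdfs.append(build_dyad_pdf(obs_of(d), config.geometry))
                kept.append(i)
            except ValidationError:
                logger.warning("dyad %s has no in-range events; dropped", d.dyad_id)
        assignments = [
            classify_trajectory_metric(p, model, metric=config.classifier, rng=rng)
            for p in pdfs
        ]
        gt_kept = [gt_meta[i] for i in kept]
        out["metric"] = confusion_metric(assignments, gt_kept, model.relations)
        if config.mode == "hierarchical_stage1":
            out["metric_detailed"] = confusion_metric(
                assignments, [test[i].relation for i in kept], model.relations,
                row_labels=RELATIONS)
        if config.median_filter:
            lengths = [p.n_events for p in pdfs]
            sel = filter_by_median_length(list(range(len(pdfs))), lengths)
            out["metric_median_filtered"] = confusion_metric(
                [assignments[i] for i in sel], [gt_kept[i] for i in sel],
                model.relations)
    return out


# ---------------------------------------------------------------------------
# conditional-independence diagnostic


def normalized_entropy_distance(
    x: np.ndarray, y: np.ndarray, n_bins: int = 20
) -> float:
    """Normalized entropy distance ``1 - I(X;Y) / H(X,Y)`` of a paired sample.

    Estimated from the joint 2-D histogram: 1 means independent, 0 a
    deterministic relation.  Degenerate (constant) inputs carry no mutual
    information and return 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size == 0:
        raise ValueError("x and y must be paired, non-empty samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("degenerate (constant) sample; entropy distance set to 1")
        return 1.0
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)

    def _h(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    h_joint = _h(p.ravel())
    if h_joint == 0.0:
        return 1.0
    mi = _h(px) + _h(py) - h_joint
    return float(np.clip(1.0 - mi / h_joint, 0.0, 1.0))
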