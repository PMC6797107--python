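"""Event-based Bayesian relation classifier with sequential prior updating.

For each observation vector S of a dyad the posterior over relations is

    P_t(r | S)  ∝  P_t(S | r) P_t(r),

with the likelihood factorized over the four observables on the binned
empirical pdfs.  The marginal P_t(S) never needs computing — normalization
absorbs it.  The prior evolves along the trajectory as the convex blend

    P_t(r) = (1 - alpha) P_0(r) + alpha P_{t-1}(r | S),

so ``alpha = 0`` keeps the initial prior fixed, ``alpha = 1`` chains each
posterior into the next prior, and intermediate values mix the two.

Degenerate events are absorbed rather than raised:

* a zero likelihood for *some* relations simply zeroes those posterior
  entries — the observed S has never occurred in those categories;
* a zero likelihood for *all* relations, or an event outside the valid
  observable ranges, carries no information ("zero knowledge") and yields the
  uniform posterior over the categories in play.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distributions import RelationModel, is_in_range
from .io import ValidationError
from .observables import OBSERVABLES, ObservationVector


def uniform_prior(relations: Sequence[str]) -> np.ndarray:
    """The unbiased initial prior: equal probability per category in play."""
    n = len(relations)
    return np.full(n, 1.0 / n)


def representation_prior(
    relations: Sequence[str], class_counts: Mapping[str, int]
) -> np.ndarray:
    """Initial prior proportional to each category's training representation."""
    counts = np.array([class_counts[rel] for rel in relations], dtype=float)
    if counts.sum() <= 0:
        raise ValidationError("class counts must be positive")
    return counts / counts.sum()


def likelihood(s: ObservationVector, model: RelationModel, relation: str) -> float:
    """Factorized likelihood: product of the four per-observable bin masses."""
    p = 1.0
    for obs in OBSERVABLES:
        p *= model.pdfs[relation][obs].prob(getattr(s, obs))
        if p == 0.0:
            return 0.0
    return p


def posterior(
    s: ObservationVector, model: RelationModel, prior: np.ndarray
) -> np.ndarray:
    """Normalized posterior for one in-range event given the running prior."""
    prior = np.asarray(prior, dtype=float)
    like = np.array([likelihood(s, model, rel) for rel in model.relations])
    unnorm = like * prior
    total = unnorm.sum()
    if total == 0.0:
        return uniform_prior(model.relations)
    return unnorm / total


def update_prior(p0: np.ndarray, prev_posterior: np.ndarray, alpha: float) -> np.ndarray:
    """Convex blend of the initial prior and the previous posterior."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return (1.0 - alpha) * np.asarray(p0, float) + alpha * np.asarray(prev_posterior, float)


@dataclass
class PosteriorTrace:
    """Per-event posteriors over the categories in play for one dyad."""

    dyad_id: str
    relations: tuple[str, ...]
    times: np.ndarray                     # (n_events,)
    posteriors: np.ndarray                # (n_events, n_relations)
    valid: np.ndarray                     # (n_events,) bool, in-range flags
    alpha: float
    p0: np.ndarray

    def __post_init__(self) -> None:
        sums = self.posteriors.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-12) or np.any(self.posteriors < 0):
            raise ValidationError("posterior rows must be probability vectors")

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: dyad_id, t, valid, one probability column per relation."""
        df = pd.DataFrame({"dyad_id": self.dyad_id, "t": self.times, "valid": self.valid})
        for k, rel in enumerate(self.relations):
            df[f"p_{rel}"] = self.posteriors[:, k]
        return df


def classify_events(
    observations: Sequence[ObservationVector],
    model: RelationModel,
    alpha: float = 1.0,
    p0: np.ndarray | None = None,
    dyad_id: str = "",
    freeze_prior_on_invalid: bool = False,
) -> PosteriorTrace:
    """Run the sequential Bayes filter along one dyad's observation sequence.

    The prior starts at ``p0`` (uniform by default) and is refreshed after
    every event by the alpha blend.  Out-of-range events emit the uniform
    zero-knowledge posterior; by default that posterior also feeds the prior
    update, while ``freeze_prior_on_invalid=True`` leaves the running prior
    untouched across such events.
    """
    if len(observations) == 0:
        raise ValidationError("empty observation sequence")
    relations = model.relations
    p0 = uniform_prior(relations) if p0 is None else np.asarray(p0, dtype=float)
    if abs(p0.sum() - 1.0) > 1e-9 or np.any(p0 < 0):
        raise ValidationError("p0 must be a probability vector over the relations")

    geometry = model.geometry
    n = len(observations)
    post = np.empty((n, len(relations)))
    valid = np.empty(n, dtype=bool)
    prior = p0.copy()
    for k, s in enumerate(observations):
        valid[k] = is_in_range(s, geometry)
        if valid[k]:
            post[k] = posterior(s, model, prior)
        else:
            post[k] = uniform_prior(relations)
        if valid[k] or not freeze_prior_on_invalid:
            prior = update_prior(p0, post[k], alpha)
    return PosteriorTrace(
        dyad_id=dyad_id,
        relations=tuple(relations),
        times=np.array([s.t for s in observations]),
        posteriors=post,
        valid=valid,
        alpha=alpha,
        p0=p0,
    )


def argmax_relation(
    probabilities: np.ndarray, relations: Sequence[str], rng: np.random.Generator
) -> str:
    """Category of maximal probability; exact ties broken uniformly at random."""
    probabilities = np.asarray(probabilities, dtype=float)
    winners = np.flatnonzero(probabilities == probabilities.max())
    pick = winners[0] if winners.size == 1 else rng.choice(winners)
    return relations[pick]


def event_votes(trace: PosteriorTrace, rng: np.random.Generator) -> list[str]:
    """Per-event argmax decisions along the trace (ties randomized)."""
    return [
        argmax_relation(trace.posteriors[k], trace.relations, rng)
        for k in range(trace.n_events)
    ]


def vote_trajectory(trace: PosteriorTrace, rng: np.random.Generator) -> str:
    """Plurality vote of the per-event winners over the whole trajectory."""
    votes = event_votes(trace, rng)
    counts = np.array([votes.count(rel) for rel in trace.relations])
    return argmax_relation(counts.astype(float), trace.relations, rng)
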