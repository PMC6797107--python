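"""Binned empirical observable distributions conditioned on social relation.

The likelihood of an observation vector is factorized over the four
observables under a conditional-independence assumption,

    P(S | r) = P(delta | r) P(vg | r) P(omega | r) P(eta | r),

so only four 1-D histograms per relation are ever built.  A joint 4-D
histogram at the default resolution would hold ~10^8 bins — far beyond what
any realistic observation set can populate — and is deliberately never
materialized.

Each observable has a fixed validity range: interpersonal distances above 2 m
are no longer "group behavior", and group velocities below 0.5 m/s indicate
standing rather than walking (the walking/standing speed mixture separates
there).  An event that is out of range on *any* observable is excluded from
*all four* histograms, keeping the factorized likelihood consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import LEISURE_RELATIONS, RELATIONS, ValidationError
from .observables import OBSERVABLES, ObservationVector

#: Default histogram geometry per observable: (lower bound, upper bound, bins).
#: delta and eta in meters, vg and omega in m/s.
DEFAULT_GEOMETRY: dict[str, tuple[float, float, int]] = {
    "delta": (0.0, 2.0, 80),
    "vg": (0.5, 2.0, 90),
    "omega": (0.0, 0.5, 60),
    "eta": (0.0, 1.125, 150),
}

_MASS_TOL = 1e-9


@dataclass
class BinnedPDF:
    """A normalized 1-D histogram on ``n_bins`` equal bins over ``[lo, hi]``.

    Bins are half-open ``[edge_k, edge_{k+1})`` with the last bin closed.
    ``mass`` may be all-zero only before fitting.
    """

    lo: float
    hi: float
    n_bins: int
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if self.hi <= self.lo:
            raise ValidationError("BinnedPDF requires hi > lo")
        if self.n_bins < 1 or self.mass.shape != (self.n_bins,):
            raise ValidationError("mass array does not match n_bins")
        if np.any(self.mass < 0):
            raise ValidationError("negative bin mass")
        total = self.mass.sum()
        if total != 0.0 and abs(total - 1.0) > _MASS_TOL:
            raise ValidationError(f"bin masses sum to {total!r}, expected 1")

    @property
    def width(self) -> float:
        return (self.hi - self.lo) / self.n_bins

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.lo + self.width * (np.arange(self.n_bins) + 0.5)

    def bin_index(self, value: float | np.ndarray) -> np.ndarray:
        """Bin index of in-range values (last bin closed at ``hi``).

        A 1e-9-bin nudge keeps values that sit exactly on a bin edge in the
        upper bin even when floating-point division lands just below it.
        """
        rel = (np.asarray(value, dtype=float) - self.lo) / self.width
        idx = np.floor(rel + 1e-9)
        return np.clip(idx, 0, self.n_bins - 1).astype(int)

    def prob(self, value: float) -> float:
        """Mass of the bin containing ``value``; 0 outside ``[lo, hi]``."""
        if value < self.lo or value > self.hi:
            return 0.0
        return float(self.mass[self.bin_index(value)])

    def same_geometry(self, other: "BinnedPDF") -> bool:
        return (self.lo, self.hi, self.n_bins) == (other.lo, other.hi, other.n_bins)


def make_histogram(values, lo: float, hi: float, n_bins: int) -> BinnedPDF:
    """Bin a 1-D sample into a normalized :class:`BinnedPDF`.

    Values outside the range are excluded before normalization; at least one
    in-range value is required.
    """
    values = np.asarray(values, dtype=float)
    sel = (values >= lo) & (values <= hi)
    if not sel.any():
        raise ValidationError(f"no values inside [{lo}, {hi}]")
    pdf = BinnedPDF(lo=lo, hi=hi, n_bins=n_bins, mass=np.zeros(n_bins))
    # the same floor-index rule used for likelihood lookups, so boundary
    # values bin identically when fitting and when evaluating
    idx = pdf.bin_index(values[sel])
    pdf.mass = np.bincount(idx, minlength=n_bins) / idx.size
    return pdf


def is_in_range(
    s: ObservationVector,
    geometry: Mapping[str, tuple[float, float, int]] = DEFAULT_GEOMETRY,
) -> bool:
    """True iff every observable of ``s`` lies inside ``[lo, hi)`` of its range."""
    for obs in OBSERVABLES:
        lo, hi = geometry[obs][0], geometry[obs][1]
        v = getattr(s, obs)
        if not (lo <= v < hi):
            return False
    return True


@dataclass
class RelationModel:
    """Per-relation binned observable pdfs with shared bin geometry.

    ``pdfs[relation][observable]`` is a :class:`BinnedPDF`; the geometry of a
    given observable is identical across relations so likelihoods and
    functional distances are comparable.
    """

    relations: tuple[str, ...]
    pdfs: dict[str, dict[str, BinnedPDF]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.relations = tuple(self.relations)
        if set(self.pdfs) != set(self.relations):
            raise ValidationError("pdfs keys do not match relations")
        ref = self.pdfs[self.relations[0]]
        for rel in self.relations:
            per_obs = self.pdfs[rel]
            if set(per_obs) != set(OBSERVABLES):
                raise ValidationError(f"relation {rel!r}: missing observables")
            for obs in OBSERVABLES:
                if not per_obs[obs].same_geometry(ref[obs]):
                    raise ValidationError(
                        f"bin geometry of {obs!r} differs between relations"
                    )

    @property
    def geometry(self) -> dict[str, tuple[float, float, int]]:
        ref = self.pdfs[self.relations[0]]
        return {obs: (ref[obs].lo, ref[obs].hi, ref[obs].n_bins) for obs in OBSERVABLES}


def pool_in_range_events(
    observation_sets: Iterable[Sequence[ObservationVector]],
    geometry: Mapping[str, tuple[float, float, int]],
) -> dict[str, np.ndarray]:
    """Pool events from several dyads, jointly excluding out-of-range events."""
    cols: dict[str, list[float]] = {obs: [] for obs in OBSERVABLES}
    for obs_seq in observation_sets:
        for s in obs_seq:
            if is_in_range(s, geometry):
                for obs in OBSERVABLES:
                    cols[obs].append(getattr(s, obs))
    return {obs: np.asarray(v) for obs, v in cols.items()}


def fit_relation_models(
    dyads_with_observations: Sequence[tuple],
    geometry: Mapping[str, tuple[float, float, int]] = DEFAULT_GEOMETRY,
    relations: Sequence[str] = RELATIONS,
    metadata: Mapping | None = None,
) -> RelationModel:
    """Fit the per-relation observable pdfs from labeled training dyads.

    Parameters
    ----------
    dyads_with_observations
        Pairs ``(DyadRecord, sequence of ObservationVector)``.  Events are
        pooled across all dyads of a relation (long trajectories contribute
        more events); an event out of range on any observable is dropped from
        all four histograms.
    geometry
        Per-observable ``(lo, hi, n_bins)``.
    relations
        The categories in play (4 flat, 3 for the leisure-only stage).

    Raises
    ------
    ValidationError
        If any relation in play has no in-range event.
    """
    relations = tuple(relations)
    by_rel: dict[str, list] = {rel: [] for rel in relations}
    for dyad, obs_seq in dyads_with_observations:
        if dyad.relation in by_rel:
            by_rel[dyad.relation].append(obs_seq)

    pdfs: dict[str, dict[str, BinnedPDF]] = {}
    for rel in relations:
        pooled = pool_in_range_events(by_rel[rel], geometry)
        if pooled[OBSERVABLES[0]].size == 0:
            raise ValidationError(f"relation class {rel!r} has no in-range events")
        pdfs[rel] = {
            obs: make_histogram(pooled[obs], *geometry[obs]) for obs in OBSERVABLES
        }
    meta = dict(metadata or {})
    meta.setdefault("n_dyads", sum(len(v) for v in by_rel.values()))
    return RelationModel(relations=relations, pdfs=pdfs, metadata=meta)


def meta_category_model(
    model: RelationModel, weights: Mapping[str, float]
) -> RelationModel:
    """Collapse the four relations into {work, leisure} meta-categories.

    The work pdf is the colleagues pdf unchanged; the leisure pdf per
    observable is the convex mixture of the families/couples/friends pdfs with
    the given ``weights`` (nonnegative, summing to 1).
    """
    w = np.array([weights[rel] for rel in LEISURE_RELATIONS], dtype=float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError("leisure weights must be nonnegative and sum to 1")
    missing = set(LEISURE_RELATIONS + ("colleagues",)) - set(model.relations)
    if missing:
        raise ValidationError(f"model lacks relations {sorted(missing)}")

    pdfs: dict[str, dict[str, BinnedPDF]] = {"work": dict(model.pdfs["colleagues"])}
    leisure: dict[str, BinnedPDF] = {}
    for obs in OBSERVABLES:
        ref = model.pdfs["colleagues"][obs]
        mix = np.zeros(ref.n_bins)
        for wk, rel in zip(w, LEISURE_RELATIONS):
            mix += wk * model.pdfs[rel][obs].mass
        leisure[obs] = BinnedPDF(lo=ref.lo, hi=ref.hi, n_bins=ref.n_bins, mass=mix)
    pdfs["leisure"] = leisure
    meta = dict(model.metadata)
    meta["leisure_weights"] = {rel: float(wk) for rel, wk in zip(LEISURE_RELATIONS, w)}
    return RelationModel(relations=("work", "leisure"), pdfs=pdfs, metadata=meta)
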