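"""Permutation test for social contagion of escape responses.

The statistic is the mean time gap between successive individual escape (or
flight) latencies within a predator presentation event.  Events are matched
in pairs sharing the trial and the presentation side but coming from the two
different flocks; pooled latencies are randomly redistributed between the
two events of a pair (preserving group sizes), and the p-value is the
proportion of permuted mean gaps at or below the observed one — small gaps
mean temporally clustered escapes.

A distance-overlap control restricts each pair to individuals whose distance
to the active monitor lies inside the overlap of the two flocks' distance
ranges, removing a spatial confound on escape latency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_N_PERMUTATIONS = 10_000


@dataclass
class EventLatencySet:
    """Latencies of the responding pigeons in one predator event."""

    trial_id: str
    side: str
    flock_id: str
    latencies: np.ndarray
    distances: np.ndarray | None = None

    def __post_init__(self) -> None:
        order = np.argsort(np.asarray(self.latencies, dtype=float))
        self.latencies = np.asarray(self.latencies, dtype=float)[order]
        if self.distances is not None:
            d = np.asarray(self.distances, dtype=float)
            if len(d) != len(self.latencies):
                raise ValueError("distances must align with latencies")
            self.distances = d[order]

    @property
    def n(self) -> int:
        return len(self.latencies)


@dataclass
class EventPair:
    """Two same-trial, same-side events from the two different flocks."""

    a: EventLatencySet
    b: EventLatencySet

    def __post_init__(self) -> None:
        if self.a.flock_id == self.b.flock_id:
            raise ValueError("a pair must combine two different flocks")
        if self.a.trial_id != self.b.trial_id or self.a.side != self.b.side:
            raise ValueError("paired events must share trial and side")


@dataclass
class PermutationResult:
    """Outcome of one (possibly aggregated) permutation test."""

    observed_mean_gap: float
    null_gaps: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None = None
    n_pairs: int = 1
    smoothed: bool = False


def event_time_gaps(latencies: np.ndarray) -> np.ndarray:
    """Successive differences of the sorted latencies (needs >= 2)."""
    lat = np.sort(np.asarray(latencies, dtype=float))
    if len(lat) < 2:
        raise ValueError("need at least two responding individuals to form gaps")
    return np.diff(lat)


def _pair_stat(a: np.ndarray, b: np.ndarray) -> float:
    """Gap-count-weighted mean gap over the two events of a pair."""
    ga = event_time_gaps(a)
    gb = event_time_gaps(b)
    return float((ga.sum() + gb.sum()) / (len(ga) + len(gb)))


def _null_gap_sums(
    pair: EventPair, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Per-permutation summed gaps and total gap count for one pair.

    Pooled latencies are reassigned uniformly at random to the two events,
    preserving group sizes; within each permuted event the gaps are the
    successive differences of the sorted latencies.
    """
    pooled = np.concatenate([pair.a.latencies, pair.b.latencies])
    na = pair.a.n
    n = len(pooled)
    # random permutations via argsort of uniforms, rows independent
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    shuffled = pooled[idx]
    ga = np.sort(shuffled[:, :na], axis=1)
    gb = np.sort(shuffled[:, na:], axis=1)
    sums = (ga[:, -1] - ga[:, 0]) + (gb[:, -1] - gb[:, 0])
    return sums, n - 2


def permutation_test(
    pair: EventPair,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    rng_seed: int | None = None,
    smoothed: bool = False,
) -> PermutationResult:
    """Within-pair permutation test of escape-latency clustering.

    p is the raw proportion of permuted mean gaps <= the observed mean gap
    (ties counted as extreme); ``smoothed`` adds the +1 correction on both
    numerator and denominator.
    """
    if pair.a.n < 2 or pair.b.n < 2:
        raise ValueError("both events need at least two latencies")
    rng = np.random.default_rng(rng_seed)
    observed = _pair_stat(pair.a.latencies, pair.b.latencies)
    pooled = np.concatenate([pair.a.latencies, pair.b.latencies])
    if np.allclose(pooled, pooled[0]):
        warnings.warn("all pooled latencies identical; permutation test is degenerate")
    sums, count = _null_gap_sums(pair, n_perm, rng)
    null = sums / count
    hits = int(np.sum(null <= observed + 1e-12))
    p = (hits + 1) / (n_perm + 1) if smoothed else hits / n_perm
    return PermutationResult(
        observed_mean_gap=observed,
        null_gaps=null,
        p_value=float(p),
        n_perm=n_perm,
        seed=rng_seed,
        n_pairs=1,
        smoothed=smoothed,
    )


def pair_events(
    events: list[EventLatencySet],
) -> tuple[list[EventPair], list[EventLatencySet]]:
    """Match events sharing trial and side across the two flocks.

    Returns the pairs plus any events left unpaired (e.g. a side missing
    for one flock); each event enters exactly one pair.
    """
    by_key: dict[tuple[str, str], list[EventLatencySet]] = {}
    for ev in events:
        by_key.setdefault((ev.trial_id, ev.side), []).append(ev)
    pairs: list[EventPair] = []
    unpaired: list[EventLatencySet] = []
    for key in sorted(by_key):
        group = by_key[key]
        flocks = {ev.flock_id for ev in group}
        if len(group) == 2 and len(flocks) == 2:
            pairs.append(EventPair(a=group[0], b=group[1]))
        else:
            unpaired.extend(group)
    return pairs, unpaired


def distance_overlap_filter(pair: EventPair) -> EventPair | None:
    """Restrict a pair to individuals inside the flocks' distance overlap.

    The overlap is [max of the two minima, min of the two maxima] of the
    per-flock distance-to-monitor ranges (inclusive).  Returns None when the
    ranges are disjoint or either filtered event keeps fewer than two
    individuals.
    """
    if pair.a.distances is None or pair.b.distances is None:
        raise ValueError("distance control requested but distances are missing")
    lo = max(pair.a.distances.min(), pair.b.distances.min())
    hi = min(pair.a.distances.max(), pair.b.distances.max())
    if lo > hi:
        return None

    def cut(ev: EventLatencySet) -> EventLatencySet:
        keep = (ev.distances >= lo) & (ev.distances <= hi)
        return EventLatencySet(
            trial_id=ev.trial_id,
            side=ev.side,
            flock_id=ev.flock_id,
            latencies=ev.latencies[keep],
            distances=ev.distances[keep],
        )

    a, b = cut(pair.a), cut(pair.b)
    if a.n < 2 or b.n < 2:
        return None
    return EventPair(a=a, b=b)


def aggregate_contagion(
    pairs: list[EventPair],
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    rng_seed: int | None = None,
    control_distance: bool = False,
    smoothed: bool = False,
) -> PermutationResult:
    """Pooled permutation test over all matched event pairs.

    The observed statistic is the gap-count-weighted mean gap over every
    event; under the null, each pair is permuted independently (one seeded
    stream) and the same pooled mean is recomputed per permutation.
    """
    if control_distance:
        pairs = [p for p in (distance_overlap_filter(pr) for pr in pairs) if p is not None]
    pairs = [p for p in pairs if p.a.n >= 2 and p.b.n >= 2]
    if not pairs:
        raise ValueError("no valid pairs to aggregate")
    rng = np.random.default_rng(rng_seed)

    obs_sum = 0.0
    obs_count = 0
    null_sums = np.zeros(n_perm)
    total_count = 0
    for pr in pairs:
        obs_sum += event_time_gaps(pr.a.latencies).sum() + event_time_gaps(pr.b.latencies).sum()
        obs_count += pr.a.n + pr.b.n - 2
        sums, count = _null_gap_sums(pr, n_perm, rng)
        null_sums += sums
        total_count += count
    observed = obs_sum / obs_count
    null = null_sums / total_count
    hits = int(np.sum(null <= observed + 1e-12))
    p = (hits + 1) / (n_perm + 1) if smoothed else hits / n_perm
    return PermutationResult(
        observed_mean_gap=float(observed),
        null_gaps=null,
        p_value=float(p),
        n_perm=n_perm,
        seed=rng_seed,
        n_pairs=len(pairs),
        smoothed=smoothed,
    )
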