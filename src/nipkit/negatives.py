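"""Construction of non-interacting protein pair (negative) sets.

Supervised PPI prediction needs a 0-class, but no gold standard of
non-interacting pairs exists.  This module implements four strategies:

* **NIP-SS** — rank all candidate pairs by ascending symmetrized sequence
  similarity, pre-select the top-m most dissimilar ones, then pick the
  final set under degree-distribution control so the negative network's
  degree profile mirrors the positive network's.
* **NIP-RW** — compute within-k-step random-walk reachability on the
  positive network; pairs unreachable within k steps inside a p-protein
  sub-matrix are candidate negatives.
* **random pairing** — uniform non-positive pairs (the common baseline,
  prone to false negatives).
* **subcellular localization** — pairs of proteins annotated to different
  compartments (the other common baseline, prone to bias).

Degree structure is summarized by a :class:`DegreeProfile`: the average
repeatability r = sum_i (d(i) - 1) / n, the maximum degree, and the
per-bin proportions of proteins and of pair-endpoints over nine degree
intervals.  A low r means broad protein coverage and hence better
generalization of the resulting training set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .data_io import InteractionSet, ProteinSet, canonical_pair
from .similarity import SimilarityTable

logger = logging.getLogger(__name__)

#: Upper edges of the degree bins (0,10], (10,20], ..., (150, inf).
BIN_UPPER_EDGES = (10, 20, 30, 50, 70, 80, 100, 150, math.inf)

BIN_LABELS = tuple(
    f"({lo},{up}]" if up != math.inf else f"({lo},inf)"
    for lo, up in zip((0,) + BIN_UPPER_EDGES[:-1], BIN_UPPER_EDGES)
)


class NegativeSamplingError(RuntimeError):
    """Raised when a strategy cannot produce the requested number of pairs."""


def _degree_bin(degree: int) -> int:
    for i, upper in enumerate(BIN_UPPER_EDGES):
        if degree <= upper:
            return i
    raise AssertionError("unreachable: last bin is unbounded")


@dataclass
class DegreeProfile:
    """Degree statistics of a pair set, used for distribution matching."""

    n_proteins: int
    degrees: dict[str, int]
    r: float
    max_degree: int
    protein_prop: np.ndarray
    pair_prop: np.ndarray
    bin_labels: tuple[str, ...] = BIN_LABELS

    def pair_prop_deviation(self, other: "DegreeProfile") -> np.ndarray:
        """Absolute per-bin difference of pair-endpoint proportions."""
        return np.abs(self.pair_prop - other.pair_prop)

    def as_dict(self) -> dict:
        return {
            "n_proteins": self.n_proteins,
            "r": self.r,
            "max_degree": self.max_degree,
            "protein_prop": [float(v) for v in self.protein_prop],
            "pair_prop": [float(v) for v in self.pair_prop],
            "bin_labels": list(self.bin_labels),
        }


def degree_profile(pairs: InteractionSet) -> DegreeProfile:
    """Compute the :class:`DegreeProfile` of a pair set."""
    if len(pairs) == 0:
        raise ValueError("cannot profile an empty pair set")
    degrees: dict[str, int] = {}
    for a, b in pairs:
        degrees[a] = degrees.get(a, 0) + 1
        degrees[b] = degrees.get(b, 0) + 1
    n = len(degrees)
    r = sum(d - 1 for d in degrees.values()) / n
    max_degree = max(degrees.values())
    protein_counts = np.zeros(len(BIN_UPPER_EDGES))
    endpoint_counts = np.zeros(len(BIN_UPPER_EDGES))
    for d in degrees.values():
        protein_counts[_degree_bin(d)] += 1
    for a, b in pairs:
        endpoint_counts[_degree_bin(degrees[a])] += 1
        endpoint_counts[_degree_bin(degrees[b])] += 1
    return DegreeProfile(
        n_proteins=n,
        degrees=degrees,
        r=r,
        max_degree=max_degree,
        protein_prop=protein_counts / n,
        pair_prop=endpoint_counts / (2 * len(pairs)),
    )


class NegativeSet(InteractionSet):
    """An :class:`InteractionSet` of negatives with sampling provenance.

    ``ordered_pairs`` preserves the strategy's selection order (for NIP-SS,
    ascending similarity); set semantics come from the parent class.
    """

    def __init__(
        self,
        ordered_pairs: Sequence[tuple[str, str]],
        provenance: dict,
        profile: DegreeProfile | None = None,
        deviations: list[str] | None = None,
    ) -> None:
        super().__init__(ordered_pairs, label="negative")
        self.ordered_pairs = [canonical_pair(a, b) for a, b in ordered_pairs]
        if len(set(self.ordered_pairs)) != len(self.ordered_pairs):
            raise ValueError("duplicate pairs in negative set")
        self.provenance = provenance
        self.profile = profile
        self.deviations = deviations or []


def _universe_ids(proteins: ProteinSet | Sequence[str]) -> list[str]:
    if isinstance(proteins, ProteinSet):
        return proteins.ids
    return list(proteins)


def _candidate_pairs(
    ids: Sequence[str], positives: InteractionSet
) -> list[tuple[str, str]]:
    return [
        pair
        for pair in combinations(sorted(ids), 2)
        if pair not in positives
    ]


# ---------------------------------------------------------------------------
# NIP-SS
# ---------------------------------------------------------------------------

def _assign_quotas(
    pos_profile: DegreeProfile,
    cand_proteins: Sequence[str],
    incidence: Mapping[str, int],
    target_count: int,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Per-protein degree quotas mirroring the positive degree multiset.

    The positive degree sequence is rescaled so quotas sum to about
    ``2 * target_count`` and assigned largest-first to the proteins with
    the most low-similarity candidate pairs (so the quota is realizable);
    equal-incidence groups are shuffled by the seed.  Quotas never exceed
    the positive maximum degree.
    """
    cap = pos_profile.max_degree
    # degree sum of the positive set is 2 * |positive pairs|
    factor = 2 * target_count / sum(pos_profile.degrees.values())
    quotas = sorted(
        (min(max(1, round(d * factor)), cap)
         for d in pos_profile.degrees.values()),
        reverse=True,
    )
    quotas = (quotas + [1] * len(cand_proteins))[: len(cand_proteins)]
    order = sorted(cand_proteins, key=lambda pid: (-incidence[pid], pid))
    # shuffle ties in incidence so the assignment is seed-dependent
    out: dict[str, int] = {}
    start = 0
    while start < len(order):
        end = start
        while (
            end + 1 < len(order)
            and incidence[order[end + 1]] == incidence[order[start]]
        ):
            end += 1
        group = order[start : end + 1]
        rng.shuffle(group)
        for pid, q in zip(group, quotas[start : end + 1]):
            out[pid] = q
        start = end + 1
    return out


def _scan_select(
    candidates: Sequence[tuple[str, str]],
    quota: dict[str, int],
    cap: int,
    target_count: int,
) -> list[tuple[str, str]] | None:
    """Ascending-similarity scan accepting pairs under per-protein quotas.

    On shortfall all quotas are incremented (capped) and the rejects are
    rescanned.  Returns None if the cap makes the target unreachable.
    """
    quota = dict(quota)
    degree = {pid: 0 for pid in quota}
    selected: list[tuple[str, str]] = []
    remaining = list(candidates)
    while len(selected) < target_count:
        rejected: list[tuple[str, str]] = []
        for pair in remaining:
            if len(selected) >= target_count:
                break
            a, b = pair
            if degree[a] < quota[a] and degree[b] < quota[b]:
                selected.append(pair)
                degree[a] += 1
                degree[b] += 1
            else:
                rejected.append(pair)
        if len(selected) >= target_count:
            break
        if all(q >= cap for q in quota.values()):
            return None
        quota = {pid: min(q + 1, cap) for pid, q in quota.items()}
        remaining = rejected
    return selected


def _quota_fill_select(
    candidates: Sequence[tuple[str, str]],
    neighbors: Mapping[str, Sequence[str]],
    quota: dict[str, int],
    cap: int,
    target_count: int,
) -> list[tuple[str, str]] | None:
    """Quota-first selection: repeatedly serve the protein with the largest
    remaining quota, pairing it with its lowest-similarity unused partner.

    Realizes the prescribed degree sequence much more closely than the
    ascending scan when hub quotas are present; any shortfall is filled by
    an ascending-similarity sweep under the maximum-degree cap.
    """
    import heapq

    degree = {pid: 0 for pid in quota}
    selected: set[tuple[str, str]] = set()
    heap = [(-q, pid) for pid, q in quota.items() if q > 0]
    heapq.heapify(heap)
    while len(selected) < target_count and heap:
        neg_rem, pid = heapq.heappop(heap)
        rem = quota[pid] - degree[pid]
        if rem <= 0:
            continue
        if rem != -neg_rem:  # stale entry
            heapq.heappush(heap, (-rem, pid))
            continue
        for partner in neighbors[pid]:
            pair = canonical_pair(pid, partner)
            if pair in selected or degree[partner] >= quota[partner]:
                continue
            selected.add(pair)
            degree[pid] += 1
            degree[partner] += 1
            break
        else:
            continue  # no partner available; retire this protein
        if quota[pid] - degree[pid] > 0:
            heapq.heappush(heap, (-(quota[pid] - degree[pid]), pid))
    if len(selected) < target_count:
        for pair in candidates:
            if len(selected) >= target_count:
                break
            a, b = pair
            if pair in selected or degree[a] >= cap or degree[b] >= cap:
                continue
            selected.add(pair)
            degree[a] += 1
            degree[b] += 1
    if len(selected) < target_count:
        return None
    return sorted(selected)


def _bin_repair(
    selected: Sequence[tuple[str, str]],
    candidates: Sequence[tuple[str, str]],
    sim: SimilarityTable,
    pos_profile: DegreeProfile,
    cap: int,
    tolerance: float,
    target_count: int,
) -> list[tuple[str, str]]:
    """Local swap repair of the binned endpoint-count error.

    Repeatedly exchanges one selected pair for one unused candidate pair
    when the exchange strictly reduces the L1 distance between the
    realized per-bin endpoint counts and the positive profile's expected
    counts.  Swap candidates are ranked by their individual error
    reduction; the loop stops once every bin is within ``tolerance``, no
    improving swap exists, or ``2 * target_count`` swaps were made.
    """
    n_bins = len(BIN_UPPER_EDGES)
    expected = pos_profile.pair_prop * 2 * target_count
    sel: set[tuple[str, str]] = set(selected)
    deg: dict[str, int] = {}
    for a, b in sel:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    counts = np.zeros(n_bins)
    for pid, d in deg.items():
        counts[_degree_bin(d)] += d

    def degree_change(d: int, delta: int) -> dict[int, float]:
        """Bin endpoint-count changes when one protein's degree moves."""
        out: dict[int, float] = {}
        if d > 0:
            out[_degree_bin(d)] = out.get(_degree_bin(d), 0) - d
        if d + delta > 0:
            out[_degree_bin(d + delta)] = out.get(_degree_bin(d + delta), 0) + (
                d + delta
            )
        return out

    def move_change(pair: tuple[str, str], delta: int,
                    degrees: dict[str, int]) -> dict[int, float]:
        out = degree_change(degrees.get(pair[0], 0), delta)
        for b, v in degree_change(degrees.get(pair[1], 0), delta).items():
            out[b] = out.get(b, 0) + v
        return out

    def l1_delta(changes: dict[int, float]) -> float:
        return sum(
            abs(counts[b] - expected[b] + v) - abs(counts[b] - expected[b])
            for b, v in changes.items()
        )

    for _ in range(2 * target_count):
        if np.abs(counts - expected).max() / (2 * target_count) <= tolerance:
            break
        removals = sorted(
            (l1_delta(move_change(pair, -1, deg)), -sim.s(*pair), pair)
            for pair in sel
        )
        additions = sorted(
            (l1_delta(move_change(pair, +1, deg)), sim.s(*pair), pair)
            for pair in candidates
            if pair not in sel
            and deg.get(pair[0], 0) < cap
            and deg.get(pair[1], 0) < cap
        )
        improved = False
        for _, _, rem in removals[:20]:
            for _, _, add in additions[:20]:
                if set(rem) & set(add):
                    continue
                combined = move_change(rem, -1, deg)
                after_removal = dict(deg)
                after_removal[rem[0]] -= 1
                after_removal[rem[1]] -= 1
                for b, v in move_change(add, +1, after_removal).items():
                    combined[b] = combined.get(b, 0) + v
                if l1_delta(combined) < -1e-9:
                    sel.remove(rem)
                    sel.add(add)
                    deg[rem[0]] -= 1
                    deg[rem[1]] -= 1
                    deg[add[0]] = deg.get(add[0], 0) + 1
                    deg[add[1]] = deg.get(add[1], 0) + 1
                    for b, v in combined.items():
                        counts[b] += v
                    improved = True
                    break
            if improved:
                break
        if not improved:
            break
    return sorted(sel)


def nip_ss(
    proteins: ProteinSet | Sequence[str],
    positives: InteractionSet,
    sim: SimilarityTable,
    target_count: int | None = None,
    m: int | None = None,
    tolerance: float = 0.05,
    seed: int = 0,
) -> NegativeSet:
    """Sequence-similarity negatives with degree-distribution control.

    Candidate pairs (positives excluded) are ranked by ascending
    symmetrized similarity s and the m lowest form the pre-selection.
    Per-protein degree quotas mirroring the positive degree multiset are
    then realized over the pre-selection, so that the negatives reproduce
    the positive degree profile instead of concentrating on a few
    extremely dissimilar hub proteins.  Two construction passes are tried
    — an ascending-similarity scan under quotas and, if its per-bin
    deviation exceeds ``tolerance``, a quota-first fill — and the result
    whose pair-endpoint bin proportions match the positive profile best is
    kept.  Selected degrees never exceed the positive maximum degree.
    Residual deviations above ``tolerance`` are logged, not fatal.

    Passing ``tolerance=math.inf`` disables degree control entirely: the
    result is simply the ``target_count`` lowest-similarity candidate
    pairs (the uncontrolled variant).

    Parameters
    ----------
    proteins : universe of candidate proteins (typically those appearing in
        the positive set)
    positives : the positive interaction set
    sim : similarity table covering the universe
    target_count : number of negatives to produce; defaults to |positives|
    m : size of the low-similarity pre-selection; defaults to
        ``5 * target_count``
    tolerance : maximum acceptable absolute per-bin deviation of the
        pair-endpoint proportions from the positive profile
    seed : RNG seed for the quota assignment
    """
    ids = [pid for pid in _universe_ids(proteins) if pid in set(sim.ids)]
    if target_count is None:
        target_count = len(positives)
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    if m is None:
        m = 5 * target_count
    if m < target_count:
        raise ValueError("m must be at least target_count")

    pos_profile = degree_profile(positives)
    max_degree_cap = pos_profile.max_degree

    candidates = _candidate_pairs(ids, positives)
    if not candidates:
        raise NegativeSamplingError("no candidate pairs outside the positive set")
    if len(candidates) < target_count:
        raise NegativeSamplingError(
            f"only {len(candidates)} candidate pairs outside the positive "
            f"set, need {target_count}"
        )
    # ascending similarity, ties broken by canonical pair order
    candidates.sort(key=lambda pair: (sim.s(*pair), pair))
    candidates = candidates[:m]

    if math.isinf(tolerance):
        selected = list(candidates[:target_count])
    else:
        neighbors: dict[str, list[str]] = {}
        incidence: dict[str, int] = {}
        for a, b in candidates:
            neighbors.setdefault(a, []).append(b)
            neighbors.setdefault(b, []).append(a)
            incidence[a] = incidence.get(a, 0) + 1
            incidence[b] = incidence.get(b, 0) + 1
        for pid in neighbors:
            neighbors[pid].sort(key=lambda q: (sim.s(pid, q), q))
        cand_proteins = sorted(neighbors)
        rng = np.random.default_rng(seed)
        quota = _assign_quotas(
            pos_profile, cand_proteins, incidence, target_count, rng
        )
        attempts: list[list[tuple[str, str]]] = []
        scan = _scan_select(candidates, quota, max_degree_cap, target_count)
        if scan is not None:
            attempts.append(scan)
        scan_dev = (
            degree_profile(InteractionSet(scan, label="negative"))
            .pair_prop_deviation(pos_profile)
            .max()
            if scan is not None
            else math.inf
        )
        if scan is None or scan_dev > tolerance:
            fill = _quota_fill_select(
                candidates, neighbors, quota, max_degree_cap, target_count
            )
            if fill is not None:
                fill_dev = (
                    degree_profile(InteractionSet(fill, label="negative"))
                    .pair_prop_deviation(pos_profile)
                    .max()
                )
                if fill_dev < scan_dev:
                    attempts.insert(0, fill)
        if not attempts:
            raise NegativeSamplingError(
                f"cannot reach {target_count} negatives from "
                f"{len(candidates)} low-similarity candidates under the "
                f"positive maximum-degree cap {max_degree_cap}"
            )
        selected = attempts[0]
        best_dev = (
            degree_profile(InteractionSet(selected, label="negative"))
            .pair_prop_deviation(pos_profile)
            .max()
        )
        if best_dev > tolerance:
            selected = _bin_repair(
                selected, candidates, sim, pos_profile, max_degree_cap,
                tolerance, target_count,
            )

    selected.sort(key=lambda pair: (sim.s(*pair), pair))
    profile = degree_profile(InteractionSet(selected, label="negative"))
    deviations: list[str] = []
    devs = profile.pair_prop_deviation(pos_profile)
    for label, dev in zip(BIN_LABELS, devs):
        if dev > tolerance:
            msg = (
                f"bin {label}: pair proportion deviates by {dev:.4f} "
                f"(> tolerance {tolerance})"
            )
            deviations.append(msg)
            logger.warning("nip_ss: %s", msg)

    provenance = {
        "strategy": "nip-ss",
        "target_count": target_count,
        "m": m,
        "tolerance": tolerance,
        "seed": int(seed),
        "n_candidates": len(candidates),
        "positive_profile": pos_profile.as_dict(),
        "achieved_profile": profile.as_dict(),
        "bin_deviations": [float(v) for v in devs],
    }
    return NegativeSet(selected, provenance, profile, deviations)


# ---------------------------------------------------------------------------
# NIP-RW
# ---------------------------------------------------------------------------

@dataclass
class ReachabilityMatrix:
    """Boolean within-k-step reachability on a positive network.

    ``matrix[i, j]`` is True iff some walk of length 1..k connects proteins
    ``ids[i]`` and ``ids[j]``.  Computed with boolean matrix products, so
    walk counts cannot overflow however large k is.
    """

    ids: list[str]
    matrix: np.ndarray
    k: int
    adjacency: np.ndarray

    def index(self, pid: str) -> int:
        return self.ids.index(pid)


def nip_rw_reachability(positives: InteractionSet, k: int) -> ReachabilityMatrix:
    """Within-k-step reachability of the positive network."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ids = positives.protein_ids()
    index = {pid: i for i, pid in enumerate(ids)}
    n = len(ids)
    adjacency = np.zeros((n, n), dtype=bool)
    for a, b in positives:
        adjacency[index[a], index[b]] = True
        adjacency[index[b], index[a]] = True
    reach = adjacency.copy()
    walk = adjacency.copy()
    for _ in range(k - 1):
        # boolean product: walks one step longer
        walk = (walk.astype(np.uint8) @ adjacency.astype(np.uint8)) > 0
        reach |= walk
    return ReachabilityMatrix(ids=ids, matrix=reach, k=k, adjacency=adjacency)


def select_submatrix_proteins(positives: InteractionSet, p: int) -> list[str]:
    """The p highest-degree proteins of the positive network.

    Ties are broken lexicographically so the selection is deterministic.
    The high-degree choice counteracts the low-degree bias of sparse
    reachability matrices.
    """
    profile = degree_profile(positives)
    ids = sorted(profile.degrees, key=lambda pid: (-profile.degrees[pid], pid))
    if p > len(ids):
        raise ValueError(
            f"p={p} exceeds the {len(ids)} proteins in the positive set"
        )
    if p < 2:
        raise ValueError("p must be >= 2")
    return ids[:p]


def nip_rw(
    proteins: ProteinSet | Sequence[str],
    positives: InteractionSet,
    k: int = 3,
    p: int | None = None,
    target_count: int | None = None,
    seed: int = 0,
) -> NegativeSet:
    """Random-walk negatives: pairs unreachable within k steps.

    Reachability is computed on the full positive network; candidates are
    the zero entries of the p x p sub-matrix restricted to the p
    highest-degree proteins, sampled uniformly without replacement.
    Positives are never candidates (they are reachable in one step).
    Defaults follow the tuning conclusions: ``k=3`` and ``p = ceil(n/2)``.
    """
    del proteins  # the candidate universe is the positive network itself
    if target_count is None:
        target_count = len(positives)
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    reach = nip_rw_reachability(positives, k)
    n = len(reach.ids)
    if p is None:
        p = math.ceil(n / 2)
    if not 2 <= p <= n:
        raise ValueError(f"p must be in [2, {n}], got {p}")
    sub_ids = select_submatrix_proteins(positives, p)
    index = {pid: i for i, pid in enumerate(reach.ids)}
    rows = np.array([index[pid] for pid in sub_ids])
    sub = reach.matrix[np.ix_(rows, rows)]
    sub_sorted = sorted(range(p), key=lambda i: sub_ids[i])
    candidates = [
        (sub_ids[sub_sorted[i]], sub_ids[sub_sorted[j]])
        for i in range(p)
        for j in range(i + 1, p)
        if not sub[sub_sorted[i], sub_sorted[j]]
    ]
    if len(candidates) < target_count:
        raise NegativeSamplingError(
            f"insufficient candidates: only {len(candidates)} pairs are "
            f"unreachable within k={k} steps in the {p}x{p} sub-matrix, "
            f"need {target_count}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=target_count, replace=False)
    selected = [candidates[i] for i in sorted(chosen)]
    profile = degree_profile(InteractionSet(selected, label="negative"))
    provenance = {
        "strategy": "nip-rw",
        "k": k,
        "p": p,
        "target_count": target_count,
        "seed": int(seed),
        "n_candidates": len(candidates),
        "achieved_profile": profile.as_dict(),
    }
    return NegativeSet(selected, provenance, profile)


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

def random_pairing(
    proteins: ProteinSet | Sequence[str],
    positives: InteractionSet,
    target_count: int | None = None,
    seed: int = 0,
) -> NegativeSet:
    """Uniform random non-positive pairs (the classical baseline)."""
    ids = _universe_ids(proteins)
    if target_count is None:
        target_count = len(positives)
    candidates = _candidate_pairs(ids, positives)
    if len(candidates) < target_count:
        raise NegativeSamplingError(
            f"candidate space has only {len(candidates)} non-positive pairs, "
            f"need {target_count}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=target_count, replace=False)
    selected = [candidates[i] for i in sorted(chosen)]
    profile = degree_profile(InteractionSet(selected, label="negative"))
    provenance = {
        "strategy": "random",
        "target_count": target_count,
        "seed": int(seed),
        "n_candidates": len(candidates),
        "achieved_profile": profile.as_dict(),
    }
    return NegativeSet(selected, provenance, profile)


def subcellular_negatives(
    localization: Mapping[str, str],
    positives: InteractionSet,
    target_count: int | None = None,
    seed: int = 0,
) -> NegativeSet:
    """Pairs of proteins annotated to different subcellular compartments.

    Implements the localization baseline: under the hypothesis that
    proteins in different compartments do not interact, sample uniform
    cross-compartment pairs, excluding positives.
    """
    if target_count is None:
        target_count = len(positives)
    compartments = set(localization.values())
    if len(compartments) < 2:
        raise NegativeSamplingError(
            "need at least 2 distinct compartments for localization negatives"
        )
    ids = sorted(localization)
    candidates = [
        (a, b)
        for a, b in combinations(ids, 2)
        if localization[a] != localization[b] and (a, b) not in positives
    ]
    if len(candidates) < target_count:
        raise NegativeSamplingError(
            f"only {len(candidates)} cross-compartment non-positive pairs, "
            f"need {target_count}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=target_count, replace=False)
    selected = [candidates[i] for i in sorted(chosen)]
    profile = degree_profile(InteractionSet(selected, label="negative"))
    provenance = {
        "strategy": "subloc",
        "target_count": target_count,
        "seed": int(seed),
        "n_candidates": len(candidates),
        "achieved_profile": profile.as_dict(),
    }
    return NegativeSet(selected, provenance, profile)
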