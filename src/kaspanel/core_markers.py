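"""Minimal discriminating-marker selection (maximum-coverage set cover).

A marker *resolves* a pair of samples when both calls are non-missing and
their genotype classes differ; a missing call is never evidence of
difference.  The goal — distinguish the largest number of sample pairs with
the fewest markers — is the set-cover objective, solved greedily with
deterministic tie-breaking (higher PIC, then (chrom, pos)).  A brute-force
enumerator over all subsets serves as the exact oracle on small instances;
the greedy solution always achieves the maximum attainable pair coverage on
such instances and its size obeys the classic (1 + ln pairs) bound.

Samples with identical call vectors over *all* markers are unresolvable by
any subset; they surface in ``unresolved_groups``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .io import GenotypeMatrix, MISSING
from .diversity import marker_stats


class CoreMarkerError(ValueError):
    pass


@dataclass
class DiscriminationState:
    """Greedy selection outcome: chosen markers and what they resolve."""

    chosen: list[str]
    unresolved_groups: list[list[str]]
    pairs_resolved: int
    pairs_total: int
    per_step_resolved: list[int] = field(default_factory=list)


def pair_discriminated(call_a: int, call_b: int) -> bool:
    """True iff both dosage calls are non-missing and differ."""
    return call_a != MISSING and call_b != MISSING and call_a != call_b


def _pair_masks(matrix: GenotypeMatrix) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Boolean (L × n_pairs) discrimination table over all sample pairs."""
    n = matrix.n_samples
    pairs = list(combinations(range(n), 2))
    d = matrix.dosage
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    a, b = d[ii, :], d[jj, :]
    disc = (a != b) & (a != MISSING) & (b != MISSING)  # n_pairs × L
    return disc.T.copy(), pairs


def _unresolved_groups_from(matrix: GenotypeMatrix,
                            marker_idx: list[int]) -> list[list[str]]:
    """Partition samples sharing a fingerprint over the chosen markers.

    Grouping is by the conservative pair rule: two samples stay together
    when no chosen marker discriminates them (missing never separates).
    Transitivity can chain near-identical samples through missing calls;
    groups are the connected components of the 'not discriminated' relation.
    """
    n = matrix.n_samples
    if not marker_idx:
        return [[s for s in matrix.samples]] if n >= 2 else []
    d = matrix.dosage[:, marker_idx]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in combinations(range(n), 2):
        a, b = d[i], d[j]
        if not np.any((a != b) & (a != MISSING) & (b != MISSING)):
            parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [[matrix.samples[i] for i in g]
            for g in groups.values() if len(g) >= 2]


def greedy_min_marker_set(matrix: GenotypeMatrix) -> DiscriminationState:
    """Greedy maximum-coverage selection of discriminating markers.

    Repeatedly adds the marker resolving the most currently-unresolved pairs
    (ties: higher PIC, then (chrom, pos)), stopping when no marker adds a
    pair.  Reports the resolution curve and the residual unresolved groups.
    """
    if matrix.n_samples < 2:
        raise CoreMarkerError("need >= 2 samples")
    disc, pairs = _pair_masks(matrix)
    L = matrix.n_markers
    pics = np.array([marker_stats(matrix, j).pic
                     if (matrix.dosage[:, j] != MISSING).any() else 0.0
                     for j in range(L)])
    order_key = [(matrix.markers[j].chrom, matrix.markers[j].pos) for j in range(L)]

    unresolved = np.ones(len(pairs), dtype=bool)
    chosen: list[int] = []
    per_step = []
    while True:
        gains = disc[:, unresolved].sum(axis=1) if unresolved.any() else np.zeros(L)
        for j in chosen:
            gains[j] = -1
        best_gain = gains.max() if L else 0
        if best_gain <= 0:
            break
        tied = np.flatnonzero(gains == best_gain)
        j = min(tied, key=lambda j: (-pics[j], order_key[j]))
        chosen.append(int(j))
        unresolved &= ~disc[j]
        per_step.append(int(len(pairs) - unresolved.sum()))

    return DiscriminationState(
        chosen=[matrix.markers[j].id for j in chosen],
        unresolved_groups=_unresolved_groups_from(matrix, chosen),
        pairs_resolved=int(len(pairs) - unresolved.sum()),
        pairs_total=len(pairs),
        per_step_resolved=per_step,
    )


def brute_force_min_set(matrix: GenotypeMatrix, max_markers: int = 20
                        ) -> tuple[list[str], int]:
    """Exact minimal marker subset by exhaustive enumeration (oracle).

    Returns the lexicographically-first smallest subset achieving the
    maximum attainable ``pairs_resolved``.  Guarded to ≤ ``max_markers``
    (and hard-capped at 20) markers — the search is exponential.
    """
    L = matrix.n_markers
    if L > min(max_markers, 20):
        raise CoreMarkerError(f"brute force refused for L={L} > {min(max_markers, 20)}")
    disc, pairs = _pair_masks(matrix)
    cover = [
        int.from_bytes(np.packbits(disc[j], bitorder="little").tobytes(), "little")
        for j in range(L)
    ]
    full = 0
    for c in cover:
        full |= c
    max_resolved = bin(full).count("1")
    for size in range(0, L + 1):
        for subset in combinations(range(L), size):
            u = 0
            for j in subset:
                u |= cover[j]
            if bin(u).count("1") == max_resolved:
                return [matrix.markers[j].id for j in subset], max_resolved
    raise AssertionError("unreachable")  # pragma: no cover


def duplicate_groups(matrix: GenotypeMatrix,
                     markers: list[str] | None = None) -> list[list[str]]:
    """Groups of ≥2 samples with *identical* call vectors over the markers.

    Strict equality — a missing call is a distinct symbol, exactly as two
    identical rows read off a plate report.  (Contrast with pair resolution,
    where missing is conservative.)
    """
    if markers is None:
        idx = list(range(matrix.n_markers))
    else:
        by_id = {m.id: j for j, m in enumerate(matrix.markers)}
        unknown = [m for m in markers if m not in by_id]
        if unknown:
            raise CoreMarkerError(f"unknown marker(s): {unknown}")
        idx = [by_id[m] for m in markers]
    seen: dict[bytes, list[int]] = {}
    for i in range(matrix.n_samples):
        seen.setdefault(matrix.dosage[i, idx].tobytes(), []).append(i)
    return [[matrix.samples[i] for i in g]
            for g in seen.values() if len(g) >= 2]
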