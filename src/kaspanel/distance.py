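"""Genetic distances between accessions and neighbor-joining tree building.

Distances operate on per-individual "allele frequency" vectors: at one locus
a diploid genotype contributes (1, 0) for a ref homozygote, (0.5, 0.5) for a
heterozygote and (0, 1) for an alt homozygote — the individual-level
convention used when a distance matrix is computed directly between single
accessions rather than between populations.  Loci missing in either member
of a pair are skipped (pairwise deletion) and the averaging denominator is
the count of shared non-missing loci.

Three distances are provided, with L' shared loci and allele index a:

    Nei DA (1983):          DA = 1 − (1/L') Σ_l Σ_a √(p_xa · p_ya)
    modified Rogers (MR):   MR = √( (1/(2L')) Σ_l Σ_a (p_xa − p_ya)² )
    Cavalli-Sforza–Edwards: CE = √( (1/(2L')) Σ_l Σ_a (√p_xa − √p_ya)² )

Neighbor joining follows Saitou & Nei's agglomeration with the standard
Q-criterion; ties pick the lowest index pair, negative branch-length
estimates are clamped to zero with the deficit logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import GenotypeMatrix, MISSING

logger = logging.getLogger(__name__)


class DistanceError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise DistanceError(f"shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise DistanceError("matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise DistanceError("diagonal not zero")
        if not np.isfinite(self.d).all():
            raise DistanceError("non-finite distances")

    def to_phylip(self) -> str:
        lines = [str(len(self.ids))]
        for i, name in enumerate(self.ids):
            lines.append(name + "\t" + "\t".join(f"{x:.6f}" for x in self.d[i]))
        return "\n".join(lines) + "\n"


def _individual_freqs(matrix: GenotypeMatrix) -> np.ndarray:
    """N×L alt-allele 'frequencies' per individual (1/0.5/0), NaN for missing."""
    p = matrix.dosage.astype(float) / 2.0
    p[matrix.dosage == MISSING] = np.nan
    return p


def _pairwise(matrix: GenotypeMatrix, kernel) -> DistanceMatrix:
    """Build an N×N distance matrix from a per-pair, per-locus kernel.

    ``kernel(px, py)`` receives the two samples' alt-frequency vectors (with
    NaNs at missing loci) and must return (per-locus contributions, L').
    """
    p = _individual_freqs(matrix)
    n = matrix.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~np.isnan(p[i]) & ~np.isnan(p[j])
            L = int(shared.sum())
            if L == 0:
                raise DistanceError(
                    f"samples {matrix.samples[i]!r} and {matrix.samples[j]!r} "
                    "share no non-missing loci")
            d[i, j] = d[j, i] = kernel(p[i, shared], p[j, shared])
    return DistanceMatrix(list(matrix.samples), d)


def da_pair(px: np.ndarray, py: np.ndarray) -> float:
    """Nei DA between two alt-frequency vectors over shared loci."""
    s = np.sqrt(px * py) + np.sqrt((1 - px) * (1 - py))
    return float(1.0 - s.mean())


def mrd_pair(px: np.ndarray, py: np.ndarray) -> float:
    """Modified Rogers distance between two alt-frequency vectors."""
    sq = (px - py) ** 2 + ((1 - px) - (1 - py)) ** 2
    return float(np.sqrt(sq.sum() / (2 * len(px))))


def ce_pair(px: np.ndarray, py: np.ndarray) -> float:
    """Cavalli-Sforza–Edwards distance between two alt-frequency vectors."""
    sq = (np.sqrt(px) - np.sqrt(py)) ** 2 + (np.sqrt(1 - px) - np.sqrt(1 - py)) ** 2
    return float(np.sqrt(sq.sum() / (2 * len(px))))


def mrd_distance(px: np.ndarray, py: np.ndarray) -> float:
    """MR distance from two alt-frequency vectors, skipping loci missing in either."""
    px, py = np.asarray(px, float), np.asarray(py, float)
    shared = ~np.isnan(px) & ~np.isnan(py)
    if not shared.any():
        raise DistanceError("no shared non-missing loci")
    return mrd_pair(px[shared], py[shared])


def ce_distance(px: np.ndarray, py: np.ndarray) -> float:
    """CE distance from two alt-frequency vectors, skipping loci missing in either."""
    px, py = np.asarray(px, float), np.asarray(py, float)
    shared = ~np.isnan(px) & ~np.isnan(py)
    if not shared.any():
        raise DistanceError("no shared non-missing loci")
    return ce_pair(px[shared], py[shared])


def nei_da_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise Nei (1983) DA distances between all samples."""
    if matrix.n_samples < 2:
        raise DistanceError("need >= 2 samples")
    return _pairwise(matrix, da_pair)


def mrd_matrix(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise modified Rogers distances between all samples."""
    if matrix.n_samples < 2:
        raise DistanceError("need >= 2 samples")
    return _pairwise(matrix, mrd_pair)


def ce_matrix(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise Cavalli-Sforza–Edwards distances between all samples."""
    if matrix.n_samples < 2:
        raise DistanceError("need >= 2 samples")
    return _pairwise(matrix, ce_pair)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix):
    """Saitou–Nei neighbor joining; returns an unrooted scikit-bio ``TreeNode``.

    Deterministic: among Q-criterion ties the lowest (i, j) index pair is
    joined.  Additive matrices are recovered exactly; negative branch-length
    estimates are clamped to zero and the clamped deficit logged.
    """
    from skbio import TreeNode

    n = len(dm.ids)
    if n < 3:
        raise DistanceError("neighbor joining requires >= 3 taxa")
    d = dm.d.astype(float).copy()
    nodes = [TreeNode(name=name) for name in dm.ids]
    active = list(range(n))
    clamped = 0.0

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: argmin over row-major order
        flat = np.argmin(q)
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        for node, length in ((nodes[i], li), (nodes[j], lj)):
            if length < 0:
                clamped += -length
                length = 0.0
            node.length = float(length)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to every other active node
        dnew = 0.5 * (d[i, active] + d[j, active] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        d[k, active] = dnew
        d[active, k] = dnew
        d[k, k] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [k]

    # join the last three nodes in a trifurcating root
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    children = []
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        if length < 0:
            clamped += -length
            length = 0.0
        node.length = float(length)
        children.append(node)
    if clamped > 0:
        logger.warning("neighbor_joining clamped %.3g of negative branch length",
                       clamped)
    return TreeNode(children=children)


def path_length_matrix(tree, ids: list[str]) -> np.ndarray:
    """Leaf-to-leaf path lengths in ``ids`` order (for additivity checks)."""
    tips = {t.name: t for t in tree.tips()}
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = tips[ids[i]].distance(tips[ids[j]])
    return out
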