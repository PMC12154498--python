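"""Model-based population structure: admixture EM, Evanno ΔK, genotype PCA.

The admixture model treats each of a diploid sample's two allele copies at
locus j as drawn from ancestral population k with probability Q_ik, and as
the alternate allele with probability P_kj.  With dosage g_ij ∈ {0, 1, 2}
the log-likelihood is

    LL = Σ_ij  g_ij ln f_ij + (2 − g_ij) ln(1 − f_ij),   f_ij = Σ_k Q_ik P_kj

(missing calls excluded).  It is maximized by EM block updates of Q and P
from random initialization, with multiple restarts; the per-restart maxima
double as the replicate log-likelihoods the Evanno ΔK table consumes.
ΔK(K) = |L''(K)| / sd(L(K)) peaks at the supported number of clusters.

PCA uses the Patterson scaling: dosages are mean-imputed per column,
centered and divided by √(p(1−p)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, MISSING

logger = logging.getLogger(__name__)

_P_CLIP = 1e-6


class StructureError(ValueError):
    pass


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray          # N×K ancestry proportions, rows sum to 1
    P: np.ndarray          # K×L alt-allele frequencies in (0, 1)
    loglik: float
    n_iter: int
    converged: bool
    seed: int
    replicate_logliks: list[float] = field(default_factory=list)


def _dosage_matrix(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    for m in matrix.markers:
        # MarkerMeta is biallelic by construction; guard retained for clarity
        if m.ref == m.alt:  # pragma: no cover
            raise StructureError(f"marker {m.id} is not biallelic")
    g = matrix.dosage.astype(float)
    mask = matrix.dosage != MISSING
    g[~mask] = 0.0
    return g, mask.astype(float)


def _loglik(g: np.ndarray, mask: np.ndarray, Q: np.ndarray, P: np.ndarray) -> float:
    f = np.clip(Q @ P, _P_CLIP, 1 - _P_CLIP)
    return float(np.sum(mask * (g * np.log(f) + (2 * mask - g) * np.log(1 - f))))


def _em_step(g, mask, Q, P, n_nonmiss):
    F = np.clip(Q @ P, _P_CLIP, 1 - _P_CLIP)
    A = mask * g / F                      # alt-copy responsibilities / (Q P)
    B = mask * (2 - g) / (1 - F)          # ref copies
    Q_new = Q * (A @ P.T + B @ (1 - P).T)
    Q_new /= np.maximum(2 * n_nonmiss, 1)[:, None]
    Q_new /= Q_new.sum(axis=1, keepdims=True)  # renormalize vs numerical drift
    alt = P * (Q.T @ A)
    ref = (1 - P) * (Q.T @ B)
    with np.errstate(invalid="ignore"):
        P_new = np.where(alt + ref > 0, alt / np.maximum(alt + ref, 1e-300), P)
    return Q_new, np.clip(P_new, _P_CLIP, 1 - _P_CLIP)


def _spread_anchors(g, mask, K, rng) -> np.ndarray:
    """k-means++-style sample anchors: spread across genotype space."""
    N = g.shape[0]
    X = np.where(mask > 0, g, np.nan)
    anchors = [int(rng.integers(N))]
    for _ in range(K - 1):
        d2 = np.full(N, np.inf)
        for a in anchors:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                diff = np.nanmean((X - X[a]) ** 2, axis=1)
            d2 = np.minimum(d2, np.nan_to_num(diff, nan=0.0))
        total = d2.sum()
        probs = d2 / total if total > 0 else np.full(N, 1.0 / N)
        anchors.append(int(rng.choice(N, p=probs)))
    return np.asarray(anchors)


def _em_once(g, mask, K, max_iter, tol, rng,
             n_init: int = 12, burn: int = 40
             ) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """One replicate fit: short-run init selection, then EM to convergence.

    Each of ``n_init`` candidate starts anchors P on the genotypes of K
    spread-out samples and runs ``burn`` EM iterations; the best candidate
    continues to convergence.  This keeps single replicates reliably near
    the global mode even for large K, where a single uninformative start
    routinely loses clusters.
    """
    N, L = g.shape
    n_nonmiss = mask.sum(axis=1)  # loci observed per sample
    best = None
    for _ in range(n_init):
        Q = rng.dirichlet(np.ones(K), size=N)
        P = np.clip((g[_spread_anchors(g, mask, K, rng)] + 0.5) / 3.0, 0.05, 0.95)
        for _ in range(burn):
            Q, P = _em_step(g, mask, Q, P, n_nonmiss)
        ll = _loglik(g, mask, Q, P)
        if best is None or ll > best[0]:
            best = (ll, Q, P)
    ll_prev, Q, P = best
    converged = False
    for it in range(1, max_iter + 1):
        Q, P = _em_step(g, mask, Q, P, n_nonmiss)
        ll = _loglik(g, mask, Q, P)
        if ll < ll_prev - 1e-6:
            raise StructureError(
                f"EM log-likelihood decreased ({ll_prev:.6f} -> {ll:.6f})")
        if abs(ll - ll_prev) < tol:
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    return Q, P, ll_prev, it, converged


def fit_admixture(
    matrix: GenotypeMatrix,
    K: int,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-4,
    seed: int = 0,
) -> AdmixtureFit:
    """Maximum-likelihood admixture fit for one K; best of ``n_restarts``.

    Q rows are initialized Dirichlet(1, ..., 1), P uniform(0.2, 0.8).  The
    log-likelihood is monotonically non-decreasing over EM iterations
    (asserted).  All restart maxima are kept in ``replicate_logliks`` for the
    Evanno calculation.
    """
    if K < 1:
        raise StructureError("K must be >= 1")
    if K > matrix.n_samples:
        raise StructureError(f"K={K} exceeds sample count {matrix.n_samples}")
    g, mask = _dosage_matrix(matrix)
    if K == 1:
        # closed form: P_1j is the alt frequency among observed calls
        denom = np.maximum(mask.sum(axis=0) * 2, 1)
        P = np.clip((g.sum(axis=0) / denom)[None, :], _P_CLIP, 1 - _P_CLIP)
        Q = np.ones((matrix.n_samples, 1))
        ll = _loglik(g, mask, Q, P)
        return AdmixtureFit(1, Q, P, ll, 1, True, seed, [ll] * max(n_restarts, 1))

    rngs = [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n_restarts)]
    best = None
    replicates = []
    for r, rng in enumerate(rngs):
        Q, P, ll, n_iter, conv = _em_once(g, mask, K, max_iter, tol, rng)
        replicates.append(ll)
        if best is None or ll > best.loglik:
            best = AdmixtureFit(K, Q, P, ll, n_iter, conv, seed)
    best.replicate_logliks = replicates
    return best


# ---------------------------------------------------------------------------
# Evanno ΔK
# ---------------------------------------------------------------------------

@dataclass
class EvannoTable:
    """ΔK statistics over interior K values; ``best_k`` is the argmax of ΔK."""

    table: pd.DataFrame   # index K; columns mean_L, sd_L, L1, L2_abs, delta_k
    best_k: int


def evanno_delta_k(logliks_by_k: dict[int, list[float]],
                   sd_floor: float = 1.0) -> EvannoTable:
    """Evanno ΔK from replicate log-likelihoods over a consecutive K range.

    For interior K: L'(K) = mean_L(K) − mean_L(K−1); |L''(K)| =
    |mean_L(K+1) − 2 mean_L(K) + mean_L(K−1)|; ΔK = |L''(K)| / sd_L(K).
    K values with zero replicate standard deviation are flagged (ΔK = NaN)
    and excluded from the argmax; ties prefer the smaller K.

    ``sd_floor`` (log-likelihood units) guards the denominator: replicate
    fits that all terminate at the same optimum differ only by
    convergence-tolerance noise, and dividing true curvature by that noise
    would make ΔK a ratio of numerical artifacts.  Deviations below the
    floor are treated as "replicates agree"; set ``sd_floor=0`` for the raw
    statistic.
    """
    ks = sorted(logliks_by_k)
    if len(ks) < 3:
        raise StructureError("Evanno needs >= 3 consecutive K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise StructureError(f"K values must be consecutive, got {ks}")
    if any(len(logliks_by_k[k]) < 2 for k in ks):
        raise StructureError("each K needs >= 2 replicate log-likelihoods")

    mean_L = {k: float(np.mean(logliks_by_k[k])) for k in ks}
    sd_L = {k: float(np.std(logliks_by_k[k], ddof=1)) for k in ks}
    rows = []
    for k in ks[1:-1]:
        l2 = abs(mean_L[k + 1] - 2 * mean_L[k] + mean_L[k - 1])
        dk = l2 / max(sd_L[k], sd_floor) if sd_L[k] > 0 else np.nan
        if sd_L[k] == 0:
            logger.warning("Evanno: sd_L(K=%d) = 0; K flagged and excluded", k)
        rows.append({"K": k, "mean_L": mean_L[k], "sd_L": sd_L[k],
                     "L1": mean_L[k] - mean_L[k - 1], "L2_abs": l2,
                     "delta_k": dk})
    df = pd.DataFrame(rows).set_index("K")
    valid = df["delta_k"].dropna()
    if valid.empty:
        raise StructureError("no K has a finite delta-K (all sd zero)")
    best = int(valid[valid == valid.max()].index.min())  # ties -> smaller K
    return EvannoTable(df, best)


def structure_scan(
    matrix: GenotypeMatrix,
    k_range: tuple[int, int] = (2, 10),
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-4,
    seed: int = 0,
) -> tuple[dict[int, AdmixtureFit], EvannoTable]:
    """Fit the admixture model over a K range and compute the Evanno table."""
    kmin, kmax = k_range
    fits = {}
    child = iter(np.random.SeedSequence(seed).generate_state(kmax - kmin + 1))
    for K in range(kmin, kmax + 1):
        fits[K] = fit_admixture(matrix, K, n_restarts=n_restarts,
                                max_iter=max_iter, tol=tol,
                                seed=int(next(child) % (2**31)))
    table = evanno_delta_k({K: f.replicate_logliks for K, f in fits.items()})
    return fits, table


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: np.ndarray            # N×n_components
    explained_fraction: np.ndarray
    dropped_markers: list[str]


def genotype_pca(matrix: GenotypeMatrix, n_components: int = 3) -> PcaResult:
    """Genotype PCA with Patterson scaling.

    Dosage columns are mean-imputed at missing entries, centered, and scaled
    by √(p(1−p)) with p the alt-allele frequency; zero-variance columns are
    dropped with a warning.  Column signs are fixed so the largest-magnitude
    loading of each component is positive (deterministic up to data).
    """
    if matrix.n_samples < 2 or matrix.n_markers < 2:
        raise StructureError("PCA needs >= 2 samples and >= 2 markers")
    g = matrix.dosage.astype(float)
    g[matrix.dosage == MISSING] = np.nan
    col_mean = np.nanmean(g, axis=0)
    inds = np.where(np.isnan(g))
    g[inds] = np.take(col_mean, inds[1])
    p = col_mean / 2.0
    scale = np.sqrt(p * (1 - p))
    keep = scale > 0
    dropped = [matrix.markers[j].id for j in np.flatnonzero(~keep)]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance marker(s): {dropped}",
                      stacklevel=2)
    x = (g[:, keep] - col_mean[keep]) / scale[keep]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    n_components = min(n_components, len(s))
    # sign convention: largest |loading| positive per component
    for c in range(n_components):
        k = np.argmax(np.abs(vt[c]))
        if vt[c, k] < 0:
            vt[c] *= -1
            u[:, c] *= -1
    scores = u[:, :n_components] * s[:n_components]
    ev = (s ** 2) / np.sum(s ** 2)
    return PcaResult(scores, ev[:n_components], dropped)
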