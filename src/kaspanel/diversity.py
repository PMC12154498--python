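"""Per-marker diversity statistics: allele frequencies, MAF, gene diversity,
observed heterozygosity and PIC, following PowerMarker's genotype-count
conventions (no Hardy–Weinberg assumption; observed heterozygosity is
reported separately from gene diversity).

For a biallelic marker with allele frequencies p and q = 1 − p:

    GD  = 1 − p² − q²                      (expected heterozygosity)
    He  = fraction of non-missing calls that are heterozygous
    PIC = 1 − p² − q² − 2 p² q²            (Botstein et al.)
    MAF = min(p, q)

Because marker panels are sometimes summarized by the *major* or the
*alternate* allele frequency under the "MAF" label, the panel summary emits
``maf``, ``major_freq`` and ``alt_freq`` as separate columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, MISSING


class StatsError(ValueError):
    pass


@dataclass
class MarkerStats:
    marker_id: str
    allele_freqs: dict[str, float]
    maf: float
    major_freq: float
    alt_freq: float
    gene_diversity: float
    het_obs: float
    pic: float
    n_nonmissing: int


def _freqs_from_dosage(col: np.ndarray) -> tuple[float, int]:
    """(alt frequency, n non-missing calls) from a dosage column."""
    nonmiss = col[col != MISSING]
    n = int(nonmiss.size)
    if n == 0:
        raise StatsError("all calls missing at marker")
    return float(nonmiss.sum()) / (2 * n), n


def allele_frequencies(matrix: GenotypeMatrix, j: int) -> dict[str, float]:
    """Allele frequencies at marker ``j``; each diploid call contributes two
    allele observations, missing calls are excluded."""
    m = matrix.markers[j]
    p_alt, _ = _freqs_from_dosage(matrix.dosage[:, j])
    return {m.ref: 1.0 - p_alt, m.alt: p_alt}


def stats_from_frequency(p_alt: float, het_obs: float = 0.0,
                         n: int = 0, marker_id: str = "",
                         ref: str = "A", alt: str = "G") -> MarkerStats:
    """Marker statistics from an alt-allele frequency (biallelic closed forms)."""
    p, q = 1.0 - p_alt, p_alt
    gd = 1.0 - p * p - q * q
    pic = gd - 2.0 * p * p * q * q
    return MarkerStats(
        marker_id=marker_id,
        allele_freqs={ref: p, alt: q},
        maf=min(p, q),
        major_freq=max(p, q),
        alt_freq=q,
        gene_diversity=gd,
        het_obs=het_obs,
        pic=pic,
        n_nonmissing=n,
    )


def marker_stats(matrix: GenotypeMatrix, j: int) -> MarkerStats:
    """Diversity statistics for marker ``j``."""
    m = matrix.markers[j]
    col = matrix.dosage[:, j]
    p_alt, n = _freqs_from_dosage(col)
    het = float(np.mean(col[col != MISSING] == 1))
    return stats_from_frequency(p_alt, het, n, m.id, m.ref, m.alt)


def panel_summary(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker statistics plus ``mean``/``min``/``max`` summary rows."""
    if matrix.n_markers == 0:
        raise StatsError("panel_summary requires >= 1 marker")
    rows = []
    for j, m in enumerate(matrix.markers):
        s = marker_stats(matrix, j)
        rows.append({
            "marker": m.id, "chrom": m.chrom, "pos": m.pos,
            "maf": s.maf, "major_freq": s.major_freq, "alt_freq": s.alt_freq,
            "gene_diversity": s.gene_diversity, "het_obs": s.het_obs,
            "pic": s.pic, "n_nonmissing": s.n_nonmissing,
        })
    df = pd.DataFrame(rows).set_index("marker")
    numeric = df[["maf", "major_freq", "alt_freq", "gene_diversity",
                  "het_obs", "pic"]]
    for name, agg in (("mean", numeric.mean()), ("min", numeric.min()),
                      ("max", numeric.max())):
        df.loc[name] = {**agg.to_dict(), "chrom": "", "pos": 0,
                        "n_nonmissing": 0}
    return df
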