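"""Synthetic genotype panels, VCFs and flanking-sequence templates.

Emulates the statistical structure of a diploid germplasm collection built
from K ancestral populations under the admixture model: each sample i has an
ancestry vector Q_i ~ Dirichlet(alpha, ..., alpha); each population k has a
per-locus allele frequency P_kj ~ Beta(a, b); the two allele copies at locus
j are independent Bernoulli draws with success probability sum_k Q_ik P_kj.
Small alpha gives near-pure samples (strong structure); Beta(0.2, 0.2) gives
strongly diverged population frequencies.  Missing calls are masked i.i.d.

All randomness flows from one master seed; each sub-stage derives its own
child generator, so any stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import BASES, MISSING, GenotypeMatrix, MarkerMeta, VariantRecord

#: the 12 ordered ref/alt base pairs a biallelic SNP can take
ORDERED_PAIRS: list[tuple[str, str]] = [
    (r, a) for r in BASES for a in BASES if r != a
]


class ParameterError(ValueError):
    """Invalid simulation parameters."""


@dataclass(frozen=True)
class PopulationModel:
    """Admixture-model parameters for a simulated germplasm panel.

    Parameters
    ----------
    n_pops : int
        Number of ancestral populations K.
    n_loci, n_samples : int
        Panel dimensions.
    freq_prior : (float, float)
        Beta(a, b) prior for per-population allele frequencies. Beta(0.2, 0.2)
        pushes frequencies toward 0/1, i.e. strongly diverged populations.
    admix_alpha : float
        Symmetric Dirichlet concentration for ancestry; 0.05 gives near-pure
        samples, 1.0 fully admixed.
    missing_rate : float
        Per-call i.i.d. probability of a missing genotype.
    freq_bounds : (float, float) or None
        If set, population allele frequencies are drawn from the prior
        truncated to this interval (e.g. (0.3, 0.7) for mid-frequency panels).
    """

    n_pops: int
    n_loci: int
    n_samples: int
    freq_prior: tuple[float, float] = (0.2, 0.2)
    admix_alpha: float = 0.05
    missing_rate: float = 0.0
    seed: int = 0
    freq_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_pops < 1 or self.n_loci < 1 or self.n_samples < 1:
            raise ParameterError("n_pops, n_loci, n_samples must all be >= 1")
        if not (0 <= self.missing_rate < 1):
            raise ParameterError("missing_rate must be in [0, 1)")
        if self.admix_alpha <= 0:
            raise ParameterError("admix_alpha must be > 0")
        if min(self.freq_prior) <= 0:
            raise ParameterError("freq_prior parameters must be > 0")
        if self.freq_bounds is not None:
            lo, hi = self.freq_bounds
            if not (0 <= lo < hi <= 1):
                raise ParameterError("freq_bounds must satisfy 0 <= lo < hi <= 1")


@dataclass
class SimulatedPanel:
    """A simulated panel plus the ground truth that generated it."""

    genotypes: GenotypeMatrix
    true_Q: np.ndarray  # N×K ancestry proportions, rows sum to 1
    true_P: np.ndarray  # K×L population allele frequencies in (0,1)
    duplicate_groups: list[set[int]] = field(default_factory=list)


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


def _truncated_beta(rng: np.random.Generator, a: float, b: float,
                    shape: tuple[int, ...],
                    bounds: tuple[float, float] | None) -> np.ndarray:
    draw = rng.beta(a, b, size=shape)
    if bounds is None:
        return draw
    lo, hi = bounds
    bad = (draw < lo) | (draw > hi)
    # rejection sampling; Beta mass in any nondegenerate interval is positive
    for _ in range(10_000):
        if not bad.any():
            break
        draw[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = (draw < lo) | (draw > hi)
    else:  # pragma: no cover
        draw = np.clip(draw, lo, hi)
    return draw


def simulate_panel(model: PopulationModel) -> SimulatedPanel:
    """Draw a diploid genotype panel under the admixture model.

    Genotypes at locus j for sample i are two independent Bernoulli(alt)
    draws with success probability ``(Q @ P)[i, j]``; ref/alt bases per locus
    are drawn uniformly from the 12 ordered base pairs; missingness is then
    masked i.i.d. at ``model.missing_rate``.
    """
    rng_P, rng_Q, rng_g, rng_pairs, rng_miss = _child_rngs(model.seed, 5)
    K, L, N = model.n_pops, model.n_loci, model.n_samples

    a, b = model.freq_prior
    P = _truncated_beta(rng_P, a, b, (K, L), model.freq_bounds)
    P = np.clip(P, 1e-6, 1 - 1e-6)
    Q = rng_Q.dirichlet(np.full(K, model.admix_alpha), size=N)

    f = Q @ P  # N×L per-call alt-allele probability
    dosage = (rng_g.random((N, L)) < f).astype(np.int8)
    dosage += (rng_g.random((N, L)) < f).astype(np.int8)

    pair_idx = rng_pairs.integers(0, len(ORDERED_PAIRS), size=L)
    markers = []
    for j in range(L):
        ref, alt = ORDERED_PAIRS[pair_idx[j]]
        markers.append(MarkerMeta(f"chr{j % 12 + 1:02d}_{(j // 12 + 1) * 1_000_000}",
                                  f"chr{j % 12 + 1:02d}", (j // 12 + 1) * 1_000_000,
                                  ref, alt))

    if model.missing_rate > 0:
        mask = rng_miss.random((N, L)) < model.missing_rate
        dosage[mask] = MISSING

    samples = [f"S{i + 1:03d}" for i in range(N)]
    return SimulatedPanel(GenotypeMatrix(samples, markers, dosage), Q, P, [])


def plant_duplicates(panel: SimulatedPanel,
                     groups: Iterable[Iterable[int]]) -> SimulatedPanel:
    """Copy each group's first member's calls onto the rest of the group.

    Emulates collections in which the same cultivar enters under several
    names: the planted samples are genuinely identical genotypes, so any
    fingerprint over any marker subset cannot separate them.
    Groups must be disjoint.
    """
    groups = [set(g) for g in groups]
    seen: set[int] = set()
    for g in groups:
        if g & seen:
            raise ParameterError(f"duplicate groups overlap at sample(s) {g & seen}")
        bad = [i for i in g if not (0 <= i < panel.genotypes.n_samples)]
        if bad:
            raise ParameterError(f"sample indices out of range: {bad}")
        seen |= g
    dosage = panel.genotypes.dosage.copy()
    for g in groups:
        members = sorted(g)
        dosage[members[1:], :] = dosage[members[0], :]
    gm = GenotypeMatrix(panel.genotypes.samples, panel.genotypes.markers, dosage)
    return SimulatedPanel(gm, panel.true_Q, panel.true_P,
                          panel.duplicate_groups + [g for g in groups if len(g) >= 2])


# ---------------------------------------------------------------------------
# toy VCFs for the screening filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationModel:
    """Samplers for the VCF INFO annotations the hard filter consumes.

    Passing values are drawn from normal distributions comfortably inside
    the GATK thresholds; ``violate_fraction[key]`` sites are instead given a
    value just past the corresponding threshold so tests can count them.
    """

    passing_mean: Mapping[str, float] = field(default_factory=lambda: {
        "QD": 20.0, "MQ": 58.0, "MQRankSum": 0.0, "ReadPosRankSum": 0.0,
        "QUAL": 500.0, "DP": 20.0,
    })
    passing_sd: Mapping[str, float] = field(default_factory=lambda: {
        "QD": 4.0, "MQ": 3.0, "MQRankSum": 1.0, "ReadPosRankSum": 1.0,
        "QUAL": 100.0, "DP": 4.0,
    })
    violating_value: Mapping[str, float] = field(default_factory=lambda: {
        "QD": 1.0, "MQ": 30.0, "MQRankSum": -15.0, "ReadPosRankSum": -10.0,
        "QUAL": 10.0, "DP": 1.0,
    })
    violate_fraction: Mapping[str, float] = field(default_factory=dict)


@dataclass
class SimulatedVcf:
    """Simulated sites plus the per-annotation plants, for exact bookkeeping."""

    records: list[VariantRecord]
    planted_violations: dict[str, list[int]]  # annotation key → record indices
    clustered_indices: list[int]              # records placed near a neighbor


def simulate_vcf(
    n_sites: int,
    n_samples: int,
    chrom_lengths: Mapping[str, int],
    annotation_model: AnnotationModel | None = None,
    clustered_fraction: float = 0.0,
    seed: int = 0,
    min_spacing: int = 300,
) -> SimulatedVcf:
    """Simulate biallelic SNP records with controllable filter violations.

    Sites are spaced at least ``min_spacing`` bp apart except for a
    ``clustered_fraction`` of them, each planted within 100 bp of another
    site to exercise flank-isolation.  Genotypes are Hardy–Weinberg draws at
    a uniform(0.1, 0.9) alt frequency; per-sample depth is Poisson(mean DP).
    """
    if not chrom_lengths:
        raise ParameterError("chrom_lengths must be non-empty")
    if not (0 <= clustered_fraction <= 1):
        raise ParameterError("clustered_fraction must be in [0, 1]")
    model = annotation_model or AnnotationModel()
    rng = np.random.Generator(np.random.PCG64(seed))

    chroms = sorted(chrom_lengths)
    n_clustered = int(round(n_sites * clustered_fraction))
    n_iso = n_sites - n_clustered

    # isolated sites: per-chromosome evenly spread jittered grid
    sites: list[tuple[str, int]] = []
    per_chrom = np.array_split(np.arange(n_iso), len(chroms))
    for chrom, idx in zip(chroms, per_chrom):
        k = len(idx)
        if k == 0:
            continue
        length = chrom_lengths[chrom]
        step = max(length // (k + 1), min_spacing)
        base = (np.arange(k) + 1) * step
        jitter = rng.integers(0, max(min_spacing // 3, 1), size=k)
        pos = np.minimum(base + jitter, length)
        sites.extend((chrom, int(p)) for p in pos)
    # clustered sites: planted 10..100 bp from an existing site
    clustered: list[tuple[str, int]] = []
    for _ in range(n_clustered):
        chrom, anchor = sites[int(rng.integers(0, len(sites)))]
        offset = int(rng.integers(10, 101)) * (1 if rng.random() < 0.5 else -1)
        clustered.append((chrom, max(1, anchor + offset)))
    all_sites = sorted(sites + clustered)
    clustered_set = set(clustered)

    # assign planted annotation violations (disjoint across keys)
    order = rng.permutation(len(all_sites))
    planted: dict[str, list[int]] = {}
    cursor = 0
    for key, frac in model.violate_fraction.items():
        m = int(round(frac * len(all_sites)))
        planted[key] = sorted(int(i) for i in order[cursor:cursor + m])
        cursor += m

    records = []
    clustered_indices = []
    for i, (chrom, pos) in enumerate(all_sites):
        ref, alt = ORDERED_PAIRS[int(rng.integers(0, len(ORDERED_PAIRS)))]
        ann = {k: float(rng.normal(model.passing_mean[k], model.passing_sd[k]))
               for k in ("QD", "MQ", "MQRankSum", "ReadPosRankSum")}
        ann["QD"] = max(ann["QD"], 2.5)
        ann["MQ"] = max(ann["MQ"], 41.0)
        ann["MQRankSum"] = max(ann["MQRankSum"], -12.0)
        ann["ReadPosRankSum"] = max(ann["ReadPosRankSum"], -7.5)
        qual = max(float(rng.normal(model.passing_mean["QUAL"],
                                    model.passing_sd["QUAL"])), 31.0)
        mean_dp = max(float(rng.normal(model.passing_mean["DP"],
                                       model.passing_sd["DP"])), 5.0)
        for key, idxs in planted.items():
            if i in idxs:
                if key == "QUAL":
                    qual = model.violating_value[key]
                elif key == "DP":
                    mean_dp = model.violating_value[key]
                else:
                    ann[key] = model.violating_value[key]
        p_alt = float(rng.uniform(0.1, 0.9))
        g = rng.binomial(1, p_alt, size=(n_samples, 2))
        calls = [(int(min(a, b)), int(max(a, b))) for a, b in g]
        depths = [int(d) for d in rng.poisson(mean_dp, size=n_samples)]
        info = dict(ann)
        info["DP"] = float(sum(depths))
        records.append(VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alts=[alt], qual=qual, info=info,
            sample_calls=calls, sample_depths=depths,
            id=f"snp_{chrom}_{pos}",
        ))
        if (chrom, pos) in clustered_set:
            clustered_indices.append(i)
    return SimulatedVcf(records, planted, clustered_indices)


# ---------------------------------------------------------------------------
# flanking-sequence templates for assay design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlankTemplate:
    """A SNP centered in its flanking genomic sequence."""

    seq: str          # length 2*flank_len + 1, SNP at index flank_len
    snp_index: int
    ref: str
    alt: str
    marker_id: str = ""

    @property
    def flank_len(self) -> int:
        return self.snp_index


def simulate_flank_template(
    snp_pos: int = 0,
    flank_len: int = 100,
    gc_target: float = 0.5,
    seed: int = 0,
    ref: str | None = None,
    alt: str | None = None,
) -> FlankTemplate:
    """Random flanking template of length ``2*flank_len + 1``, SNP centered.

    Bases are drawn i.i.d. with P(G or C) = ``gc_target``.  ``snp_pos`` only
    names the locus (it seeds the marker id), the SNP sits at the center.
    """
    if flank_len < 20:
        raise ParameterError("flank_len must be >= 20")
    if not (0 <= gc_target <= 1):
        raise ParameterError("gc_target must be in [0, 1]")
    rng = np.random.Generator(np.random.PCG64(seed))
    n = 2 * flank_len + 1
    is_gc = rng.random(n) < gc_target
    pick = rng.integers(0, 2, size=n)
    gc = np.where(pick == 0, "G", "C")
    at = np.where(pick == 0, "A", "T")
    seq = np.where(is_gc, gc, at)
    if ref is None or alt is None:
        # draw SNP alleles with the same base composition as the flanks
        w = np.array([(1 - gc_target) / 2, gc_target / 2,
                      gc_target / 2, (1 - gc_target) / 2])
        if ref is None:
            ref = str(rng.choice(list(BASES), p=w))
        w2 = np.array([0.0 if b == ref else w[k] for k, b in enumerate(BASES)])
        w2 /= w2.sum()
        alt = str(rng.choice(list(BASES), p=w2))
    seq[flank_len] = ref
    return FlankTemplate("".join(seq), flank_len, ref, alt,
                         marker_id=f"tpl_{snp_pos}")


def write_fasta(templates: Sequence[FlankTemplate], path) -> None:
    """Write templates to FASTA; headers carry SNP index and alleles."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    recs = [
        SeqRecord(Seq(t.seq), id=t.marker_id or f"tpl{i}",
                  description=f"snp_index={t.snp_index} ref={t.ref} alt={t.alt}")
        for i, t in enumerate(templates)
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta_templates(path) -> list[FlankTemplate]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        kv = dict(part.split("=") for part in rec.description.split()
                  if "=" in part)
        out.append(FlankTemplate(str(rec.seq).upper(), int(kv["snp_index"]),
                                 kv["ref"], kv["alt"], marker_id=rec.id))
    return out
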