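"""Candidate-SNP screening: the funnel from raw variant calls to assay-ready sites.

The funnel mirrors a standard resequencing marker-development workflow:

1. ``hard_filter``     — GATK-style annotation thresholds (QD, MQ, rank sums);
2. ``site_filter``     — vcftools-style site criteria (biallelic, MAC, MAF,
   mean depth, QUAL, missingness);
3. ``flank_isolation`` — no other variant of any kind within ``flank_bp``
   of the candidate, so primer-binding context is clean;
4. ``frequency_window``— keep mid-frequency sites (alt frequency 0.30–0.70);
5. ``distribute_evenly``— apportion a target count across chromosomes and
   spread picks by greedy farthest-point selection.

Each stage returns a subset of its input, so survivor counts are
monotonically non-increasing; :class:`FilterReport` records the funnel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import BASES, VariantRecord


class ScreeningError(ValueError):
    pass


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter and site-filter thresholds.

    Defaults follow common GATK hard-filter recommendations and a vcftools
    invocation of ``--mac 3 --maf 0.05 --max-alleles 2 --min-alleles 2
    --min-meanDP 4 --minQ 30 --max-missing 0.5``;  ``max_missing`` is the
    *minimum non-missing fraction* (vcftools semantics, boundary inclusive).
    """

    qd_min: float = 2.0
    mq_min: float = 40.0
    mqranksum_min: float = -12.5
    readpos_min: float = -8.0
    mac_min: int = 3
    maf_min: float = 0.05
    alleles_exact: int = 2
    mean_dp_min: float = 4.0
    qual_min: float = 30.0
    max_missing: float = 0.5
    flank_bp: int = 100
    freq_window: tuple[float, float] = (0.30, 0.70)

    def __post_init__(self) -> None:
        if not (0 <= self.max_missing <= 1):
            raise ScreeningError("max_missing must be in [0, 1]")
        if self.flank_bp < 0:
            raise ScreeningError("flank_bp must be >= 0")
        lo, hi = self.freq_window
        if not (0 <= lo < hi <= 1):
            raise ScreeningError("freq_window must satisfy 0 <= lo < hi <= 1")


@dataclass
class FilterReport:
    """Survivor counts per funnel stage and per-site removal reasons."""

    stage_counts: dict[str, int] = field(default_factory=dict)
    removals: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)

    def record_stage(self, name: str, survivors: Sequence[VariantRecord],
                     removed: Iterable[tuple[VariantRecord, str]] = ()) -> None:
        counts = list(self.stage_counts.values())
        n = len(survivors)
        if counts and n > counts[-1]:
            raise ScreeningError(
                f"stage {name!r} increased the site count ({counts[-1]} -> {n})")
        self.stage_counts[name] = n
        self.removals[name] = [(r.chrom, r.pos, reason) for r, reason in removed]

    def to_dict(self) -> dict:
        return {"stage_counts": dict(self.stage_counts),
                "removals": {k: [list(t) for t in v]
                             for k, v in self.removals.items()}}


# ---------------------------------------------------------------------------
# stage 1: annotation hard filter
# ---------------------------------------------------------------------------

def hard_filter(record: VariantRecord,
                t: FilterThresholds = FilterThresholds()) -> tuple[bool, str | None]:
    """GATK-style hard filter: fail iff a *present* annotation violates its bound.

    A record fails when QD < qd_min, MQ < mq_min, MQRankSum < mqranksum_min or
    ReadPosRankSum < readpos_min (all strict).  Absent annotations never fail
    their clause.  Returns ``(passed, reason)``.
    """
    if not record.is_snp:
        raise ScreeningError(f"{record.chrom}:{record.pos}: hard_filter requires an SNP")
    for key, bound in (("QD", t.qd_min), ("MQ", t.mq_min),
                       ("MQRankSum", t.mqranksum_min),
                       ("ReadPosRankSum", t.readpos_min)):
        val = record.info.get(key)
        if val is not None and val < bound:
            return False, key
    return True, None


# ---------------------------------------------------------------------------
# stage 2: vcftools-style site filter
# ---------------------------------------------------------------------------

def site_filter(record: VariantRecord,
                t: FilterThresholds = FilterThresholds()) -> tuple[bool, str | None]:
    """Biallelic / MAC / MAF / mean-depth / QUAL / missingness site filter."""
    if not record.is_snp:
        raise ScreeningError(f"{record.chrom}:{record.pos}: site_filter requires an SNP")
    if len(record.alts) != t.alleles_exact - 1:
        return False, "alleles"
    n_total = len(record.sample_calls)
    nonmissing = [c for c in record.sample_calls if c is not None]
    if not nonmissing:
        return False, "all-missing"
    if n_total and len(nonmissing) / n_total < t.max_missing:
        return False, "missing"
    counts = record.allele_counts()
    total_alleles = sum(counts.values())
    mac = min(counts.get(0, 0), counts.get(1, 0))
    if mac < t.mac_min:
        return False, "mac"
    if mac / total_alleles < t.maf_min:
        return False, "maf"
    depths = [d for d in record.sample_depths if d is not None]
    if depths and float(np.mean(depths)) < t.mean_dp_min:
        return False, "mean-dp"
    if record.qual is not None and record.qual < t.qual_min:
        return False, "qual"
    return True, None


# ---------------------------------------------------------------------------
# stage 3: flank isolation
# ---------------------------------------------------------------------------

def _check_sorted(records: Sequence[VariantRecord]) -> None:
    keys = [(r.chrom, r.pos) for r in records]
    if keys != sorted(keys):
        raise ScreeningError("records must be sorted by (chrom, pos)")


def flank_isolation(
    records: Sequence[VariantRecord],
    flank_bp: int = 100,
    context: Sequence[VariantRecord] | None = None,
) -> list[VariantRecord]:
    """Keep sites with no other variant within ``flank_bp`` on the same chromosome.

    The neighbor set defaults to ``records`` itself but may be the full raw
    variant list (``context``): a candidate must be devoid of *any* other
    variant in its window, including sites already removed by earlier stages.
    A distance of exactly ``flank_bp`` violates; survival requires strict
    ``> flank_bp`` separation.  Clustered sites remove each other.
    """
    _check_sorted(records)
    neighbors = records if context is None else context
    _check_sorted(neighbors)
    positions: dict[str, np.ndarray] = {}
    for r in neighbors:
        positions.setdefault(r.chrom, [])
    for r in neighbors:
        positions[r.chrom].append(r.pos)  # type: ignore[attr-defined]
    positions = {c: np.asarray(p) for c, p in positions.items()}

    kept = []
    for r in records:
        pos = positions[r.chrom]
        near = np.abs(pos - r.pos) <= flank_bp
        # the site itself contributes exactly one zero-distance hit
        n_self = int(np.sum(pos == r.pos))
        if int(near.sum()) - n_self == 0 and n_self == 1:
            kept.append(r)
        elif n_self > 1:  # another variant at the same coordinate
            continue
    return kept


# ---------------------------------------------------------------------------
# stage 4: mid-frequency window
# ---------------------------------------------------------------------------

def frequency_window(
    records: Sequence[VariantRecord],
    window: tuple[float, float] = (0.30, 0.70),
) -> list[VariantRecord]:
    """Keep biallelic sites whose alt-allele frequency lies in ``window`` (inclusive).

    Stated as a "minor allele frequency from 30% to 70%" in marker-development
    practice; since a minor frequency cannot exceed 0.5 the operative quantity
    is the alternate-allele frequency.
    """
    lo, hi = window
    return [r for r in records if lo <= r.alt_frequency() <= hi]


# ---------------------------------------------------------------------------
# stage 5: even chromosomal distribution
# ---------------------------------------------------------------------------

def _largest_remainder_quotas(counts: Mapping[str, int], n_target: int) -> dict[str, int]:
    total = sum(counts.values())
    chroms = sorted(counts)
    ideal = {c: n_target * counts[c] / total for c in chroms}
    quota = {c: int(ideal[c]) for c in chroms}
    # minimum 1 per chromosome with candidates, when the target allows it
    if n_target >= len(chroms):
        for c in chroms:
            if counts[c] > 0:
                quota[c] = max(quota[c], 1)
    quota = {c: min(quota[c], counts[c]) for c in chroms}
    while sum(quota.values()) > n_target:  # over-allocation from the min-1 floor
        c = max(chroms, key=lambda c: (quota[c] - ideal[c], c))
        quota[c] -= 1
    remainders = sorted(chroms, key=lambda c: (-(ideal[c] - quota[c]), c))
    i = 0
    while sum(quota.values()) < n_target:
        c = remainders[i % len(remainders)]
        if quota[c] < counts[c]:
            quota[c] += 1
        i += 1
        if i > 10 * len(chroms) * (n_target + 1):  # pragma: no cover
            raise ScreeningError("quota apportionment failed to converge")
    return quota


def _farthest_point(positions: Sequence[int], k: int) -> list[int]:
    """Greedy farthest-point subset of size k; ties broken toward lower position."""
    pos = sorted(positions)
    if k >= len(pos):
        return pos
    chosen = [pos[0]]  # first pick: all tie on the (empty) pairwise criterion
    while len(chosen) < k:
        best = max((min(abs(p - c) for c in chosen), -p)
                   for p in pos if p not in chosen)
        chosen.append(-best[1])
    return sorted(chosen)


def distribute_evenly(
    candidates: Sequence[VariantRecord],
    n_target: int,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[VariantRecord]:
    """Select ``n_target`` sites spread across chromosomes.

    Per-chromosome quotas come from largest-remainder apportionment of
    ``n_target`` proportional to candidate counts (minimum 1 where candidates
    exist and the target allows); within a chromosome sites are picked by
    greedy farthest-point selection on position.  Fully deterministic.
    """
    if n_target > len(candidates):
        raise ScreeningError(
            f"n_target={n_target} exceeds candidate count {len(candidates)}")
    by_chrom: dict[str, list[VariantRecord]] = {}
    for r in candidates:
        by_chrom.setdefault(r.chrom, []).append(r)
    quotas = _largest_remainder_quotas(
        {c: len(v) for c, v in by_chrom.items()}, n_target)
    selected = []
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: r.pos)
        picks = set(_farthest_point([r.pos for r in recs], quotas[chrom]))
        chosen = [r for r in recs if r.pos in picks]
        selected.extend(chosen[: quotas[chrom]])  # guard vs duplicated positions
    return sorted(selected, key=lambda r: (r.chrom, r.pos))


# ---------------------------------------------------------------------------
# variant-type census
# ---------------------------------------------------------------------------

#: all possible ordered ref/alt labels for a biallelic SNP (4 bases × 3 alternates)
VARIANT_TYPES: list[str] = [f"{r}/{a}" for r in BASES for a in BASES if r != a]


def classify_variant_type(ref: str, alt: str) -> str:
    """Ordered ``"REF/ALT"`` label of a biallelic SNP; 12 labels are possible."""
    if ref not in BASES or alt not in BASES:
        raise ScreeningError(f"bases must be in {BASES}: got {ref!r}/{alt!r}")
    if ref == alt:
        raise ScreeningError(f"ref == alt ({ref})")
    return f"{ref}/{alt}"


def variant_type_census(
    pairs: Iterable[tuple[str, str]]
) -> tuple[dict[str, int], dict[str, float]]:
    """Counts and proportions of each ordered ref/alt category."""
    counts = {t: 0 for t in VARIANT_TYPES}
    n = 0
    for ref, alt in pairs:
        counts[classify_variant_type(ref, alt)] += 1
        n += 1
    props = {t: (c / n if n else 0.0) for t, c in counts.items()}
    return counts, props


# ---------------------------------------------------------------------------
# the full funnel
# ---------------------------------------------------------------------------

def run_screen(
    records: Sequence[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
    n_target: int | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> tuple[list[VariantRecord], FilterReport]:
    """Run the full screening funnel and return survivors plus the report.

    Non-SNP records participate as flank-isolation neighbors but are removed
    at the input stage.  ``n_target`` of ``None`` skips the distribution step.
    """
    records = sorted(records, key=lambda r: (r.chrom, r.pos))
    report = FilterReport()
    snps = [r for r in records if r.is_snp]
    report.record_stage("input", records)
    report.record_stage("snp_only", snps,
                        [(r, "non-snp") for r in records if not r.is_snp])

    survivors, removed = [], []
    for r in snps:
        ok, reason = hard_filter(r, thresholds)
        if ok:
            survivors.append(r)
        else:
            removed.append((r, reason))
    report.record_stage("hard_filter", survivors, removed)

    prev = survivors
    survivors = [r for r in prev if site_filter(r, thresholds)[0]]
    removed = [(r, site_filter(r, thresholds)[1]) for r in prev
               if not site_filter(r, thresholds)[0]]
    report.record_stage("site_filter", survivors, removed)

    prev = survivors
    survivors = flank_isolation(prev, thresholds.flank_bp, context=records)
    kept_keys = {(r.chrom, r.pos) for r in survivors}
    report.record_stage("flank_isolation", survivors,
                        [(r, "flank") for r in prev
                         if (r.chrom, r.pos) not in kept_keys])

    prev = survivors
    survivors = frequency_window(prev, thresholds.freq_window)
    kept_keys = {(r.chrom, r.pos) for r in survivors}
    report.record_stage("frequency_window", survivors,
                        [(r, "frequency") for r in prev
                         if (r.chrom, r.pos) not in kept_keys])

    if n_target is not None and n_target < len(survivors):
        prev = survivors
        survivors = distribute_evenly(prev, n_target, chrom_lengths)
        kept_keys = {(r.chrom, r.pos) for r in survivors}
        report.record_stage("distribute_evenly", survivors,
                            [(r, "quota") for r in prev
                             if (r.chrom, r.pos) not in kept_keys])
    return survivors, report
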