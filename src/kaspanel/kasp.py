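"""KASP assay design and marker-level genotyping QC.

A KASP assay genotypes one biallelic SNP with three primers: two
allele-specific forward primers whose 3'-terminal base is the SNP allele,
each carrying a universal 5' tail (FAM- or HEX-coupled in the master mix),
plus one common reverse primer.  Design constraints follow standard practice
for the chemistry: amplicon of at most 120 bp, primer GC content under 60%,
and annealing temperature between 55 and 62 °C — all evaluated on the
gene-specific portion only, since the tails are universal.

Melting temperatures use nearest-neighbor thermodynamics
(Bio.SeqUtils.MeltingTemp.Tm_NN) at the declared salt/primer concentrations
in :data:`TM_CONDITIONS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix, MISSING
from .simulate import FlankTemplate

#: universal 5' tails recognized by the FAM- and HEX-labelled FRET cassettes
FAM_TAIL = "GAAGGTGACCAAGTTCATGCT"
HEX_TAIL = "GAAGGTCGGAGTCAACGGATT"

#: nearest-neighbor Tm conditions (mM for salts, nM for strand concentrations)
TM_CONDITIONS = {
    "Na": 50.0,
    "Mg": 1.8,
    "dNTPs": 0.2,
    "dnac1": 250.0,
    "dnac2": 250.0,
    "saltcorr": 7,  # Owczarzy et al. (2008) divalent correction
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class DesignError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_bases(seq: str) -> None:
    bad = set(seq) - set("ACGT")
    if bad:
        raise DesignError(f"ambiguous/invalid base(s) {sorted(bad)} in primer")


def primer_gc(seq: str) -> float:
    """GC fraction of a primer's gene-specific sequence."""
    seq = seq.upper()
    _check_bases(seq)
    if len(seq) < 8:
        raise DesignError(f"primer too short for GC/Tm evaluation ({len(seq)} nt)")
    return (seq.count("G") + seq.count("C")) / len(seq)


def primer_tm(seq: str) -> float:
    """Nearest-neighbor melting temperature (°C) under :data:`TM_CONDITIONS`."""
    from Bio.SeqUtils import MeltingTemp as mt

    seq = seq.upper()
    _check_bases(seq)
    if len(seq) < 8:
        raise DesignError(f"primer too short for GC/Tm evaluation ({len(seq)} nt)")
    return float(mt.Tm_NN(seq, **TM_CONDITIONS))


@dataclass(frozen=True)
class DesignConstraints:
    """Assay design constraints (defaults: product ≤120 bp, GC <60%, Tm 55–62 °C)."""

    max_product: int = 120
    gc_max: float = 0.60
    tm_range: tuple[float, float] = (55.0, 62.0)
    primer_len: tuple[int, int] = (18, 30)


@dataclass
class KaspAssay:
    """A designed primer triple; allele-specific primers carry the tails."""

    marker_id: str
    fam_primer: str      # tail + gene-specific, 3' base = ref allele
    hex_primer: str      # tail + gene-specific, 3' base = alt allele
    common_primer: str   # reverse strand, no tail
    product_size: int
    fam_gc: float
    hex_gc: float
    common_gc: float
    fam_tm: float
    hex_tm: float
    common_tm: float

    @property
    def fam_core(self) -> str:
        return self.fam_primer[len(FAM_TAIL):]

    @property
    def hex_core(self) -> str:
        return self.hex_primer[len(HEX_TAIL):]


@dataclass
class DesignFailure:
    """Why no primer triple satisfied the constraints for a template."""

    marker_id: str
    reason: str                      # dominant excluding constraint
    excluded_by: dict[str, int] = field(default_factory=dict)


def _passes(seq: str, c: DesignConstraints) -> str | None:
    """None if the gene-specific primer passes GC and Tm; else the failed constraint."""
    if primer_gc(seq) >= c.gc_max:
        return "gc"
    tm = primer_tm(seq)
    if not (c.tm_range[0] <= tm <= c.tm_range[1]):
        return "tm"
    return None


def design_assay(
    template: FlankTemplate,
    constraints: DesignConstraints = DesignConstraints(),
) -> KaspAssay | DesignFailure:
    """Design the KASP primer triple for one SNP template.

    Allele-specific primers are laid on the forward strand ending exactly at
    the SNP (3' base = allele); the common primer is enumerated on the
    reverse strand downstream.  Candidate triples are scanned in order of
    smallest product size, then longest primers, and the first triple whose
    three gene-specific primers all satisfy GC < ``gc_max`` and Tm within
    ``tm_range`` with product ≤ ``max_product`` is returned.  If no triple
    qualifies, a :class:`DesignFailure` reports the dominant excluding
    constraint.
    """
    seq = template.seq.upper()
    snp = template.snp_index
    lmin, lmax = constraints.primer_len
    if snp < max(lmin, 40) or len(seq) - snp - 1 < 40:
        raise DesignError(
            f"template {template.marker_id or '?'}: need >= 40 bp each side of the SNP")

    excluded: dict[str, int] = {"gc": 0, "tm": 0, "product": 0}

    # allele-specific candidates by length, prevalidated once
    as_ok: dict[int, bool] = {}
    as_reason: dict[int, str] = {}
    for L in range(lmin, lmax + 1):
        if L > snp + 1:
            continue
        stem = seq[snp - L + 1: snp]
        fam = stem + template.ref
        hex_ = stem + template.alt
        r = _passes(fam, constraints) or _passes(hex_, constraints)
        as_ok[L] = r is None
        if r is not None:
            as_reason[L] = r

    # enumerate (product, AS length, common length, common start) candidates
    candidates = []
    for L in as_ok:
        amp_start = snp - L + 1
        for L2 in range(lmin, lmax + 1):
            for start in range(snp + 1, len(seq) - L2 + 1):
                product = start + L2 - amp_start
                candidates.append((product, -(L + L2), L, L2, start))
    candidates.sort()

    for product, _, L, L2, start in candidates:
        if product > constraints.max_product:
            excluded["product"] += 1
            continue
        if not as_ok[L]:
            excluded[as_reason[L]] += 1
            continue
        common = revcomp(seq[start: start + L2])
        r = _passes(common, constraints)
        if r is not None:
            excluded[r] += 1
            continue
        stem = seq[snp - L + 1: snp]
        fam_core, hex_core = stem + template.ref, stem + template.alt
        return KaspAssay(
            marker_id=template.marker_id,
            fam_primer=FAM_TAIL + fam_core,
            hex_primer=HEX_TAIL + hex_core,
            common_primer=common,
            product_size=product,
            fam_gc=primer_gc(fam_core), hex_gc=primer_gc(hex_core),
            common_gc=primer_gc(common),
            fam_tm=primer_tm(fam_core), hex_tm=primer_tm(hex_core),
            common_tm=primer_tm(common),
        )

    reason_names = {"gc": "GC content", "tm": "annealing temperature",
                    "product": "product size"}
    dominant = max(excluded, key=lambda k: excluded[k])
    return DesignFailure(template.marker_id, reason_names[dominant], dict(excluded))


# ---------------------------------------------------------------------------
# marker / sample genotyping QC
# ---------------------------------------------------------------------------

@dataclass
class MarkerQCResult:
    marker_id: str
    missing_rate: float
    n_genotype_classes: int
    verdict: str  # retain | drop_missing | drop_monomorphic | drop_both


@dataclass
class PanelQCResult:
    markers: list[MarkerQCResult]
    dropped_samples: list[str]
    retained: "GenotypeMatrix"


def marker_qc(
    matrix: GenotypeMatrix,
    missing_threshold: float = 0.20,
    sample_missing_threshold: float = 0.50,
) -> PanelQCResult:
    """Marker- and sample-level genotyping QC.

    Samples whose own missing rate exceeds ``sample_missing_threshold`` are
    dropped first (poorly genotyped individuals).  Each marker is then judged
    over the retained samples: ``drop_missing`` if its missing rate exceeds
    ``missing_threshold``, ``drop_monomorphic`` if all non-missing calls fall
    in one genotype class, ``drop_both`` if both, ``retain`` otherwise.
    """
    if matrix.n_samples == 0 or matrix.n_markers == 0:
        raise DesignError("marker_qc requires a non-empty matrix")
    miss = matrix.missing_mask()
    sample_rates = miss.mean(axis=1)
    keep_samples = np.flatnonzero(sample_rates <= sample_missing_threshold)
    dropped_samples = [matrix.samples[i]
                       for i in np.flatnonzero(sample_rates > sample_missing_threshold)]
    sub = matrix.subset(samples=keep_samples)

    results = []
    retain_idx = []
    for j, m in enumerate(sub.markers):
        col = sub.dosage[:, j]
        nonmiss = col[col != MISSING]
        rate = float(np.mean(col == MISSING))
        classes = int(len(np.unique(nonmiss)))
        high_missing = rate > missing_threshold
        mono = classes <= 1
        if high_missing and mono:
            verdict = "drop_both"
        elif high_missing:
            verdict = "drop_missing"
        elif mono:
            verdict = "drop_monomorphic"
        else:
            verdict = "retain"
            retain_idx.append(j)
        results.append(MarkerQCResult(m.id, rate, classes, verdict))
    return PanelQCResult(results, dropped_samples, sub.subset(markers=retain_idx))
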