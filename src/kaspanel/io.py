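"""Genotype data model and readers/writers for the pipeline's interchange formats.

The central object is :class:`GenotypeMatrix`: an N-sample × L-marker table of
unordered diploid base-pair calls at biallelic SNPs.  Internally calls are
stored as alternate-allele dosage (0/1/2, with -1 = missing), which every
downstream statistic consumes directly; the base-pair view ("AA", "AG", "NN")
is reconstructed from each marker's ref/alt on demand.

Supported formats: VCF v4.2 (read via cyvcf2, written as plain text), the
genotype CSV/TSV dialect (sample rows × marker columns, two-letter calls,
"NN"/empty = missing, marker metadata in a ``<path>.markers.tsv`` sidecar),
STRUCTURE's two-rows-per-sample text, and Newick.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
MISSING = -1
MISSING_CALL = "NN"

# STRUCTURE integer recoding of nucleotide alleles
STRUCTURE_CODES = {"A": 1, "C": 2, "G": 3, "T": 4}
STRUCTURE_MISSING = -9


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Semantically invalid data (e.g. a call outside a marker's alleles)."""


@dataclass(frozen=True)
class MarkerMeta:
    """Identity and location of one biallelic SNP marker (1-based coords)."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValidationError(f"marker {self.id}: alleles must be in {BASES}")
        if self.ref == self.alt:
            raise ValidationError(f"marker {self.id}: ref == alt ({self.ref})")
        if self.pos < 1:
            raise ValidationError(f"marker {self.id}: pos must be >= 1 (got {self.pos})")

    def call_string(self, dosage: int) -> str:
        """Base-pair string for an alt-allele dosage; heterozygotes alphabetical."""
        if dosage == MISSING:
            return MISSING_CALL
        if dosage == 0:
            return self.ref + self.ref
        if dosage == 2:
            return self.alt + self.alt
        if dosage == 1:
            return "".join(sorted((self.ref, self.alt)))
        raise ValueError(f"invalid dosage {dosage}")

    def dosage_of(self, call: str) -> int:
        """Alt-allele dosage of a two-letter call (order-insensitive)."""
        call = call.strip().upper()
        if call in ("", MISSING_CALL, "--", "N"):
            return MISSING
        if len(call) != 2:
            raise ValidationError(f"marker {self.id}: malformed call {call!r}")
        bad = set(call) - {self.ref, self.alt}
        if bad:
            raise ValidationError(
                f"marker {self.id} ({self.ref}/{self.alt}): call {call!r} uses "
                f"base(s) {sorted(bad)} outside the marker's alleles"
            )
        return sum(1 for b in call if b == self.alt)


class GenotypeMatrix:
    """Sample × marker diploid calls with marker metadata.

    Parameters
    ----------
    samples : sequence of str
        Unique sample identifiers (row order preserved).
    markers : sequence of MarkerMeta
        Unique marker identifiers (column order preserved).
    dosage : array-like of shape (n_samples, n_markers)
        Alternate-allele dosage per call: 0, 1, 2, or -1 for missing.
    """

    def __init__(
        self,
        samples: Sequence[str],
        markers: Sequence[MarkerMeta],
        dosage: np.ndarray,
    ) -> None:
        self.samples = list(samples)
        self.markers = list(markers)
        self.dosage = np.asarray(dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)}, {len(self.markers)})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("sample IDs are not unique")
        ids = [m.id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValidationError("marker IDs are not unique")
        bad = ~np.isin(self.dosage, (-1, 0, 1, 2))
        if bad.any():
            raise ValidationError(f"invalid dosage values at {np.argwhere(bad)[:5].tolist()}")

    # -- basic shape --------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def call(self, i: int, j: int) -> str:
        return self.markers[j].call_string(int(self.dosage[i, j]))

    def call_frame(self) -> pd.DataFrame:
        """Calls as a DataFrame of two-letter strings (samples × markers)."""
        cols = {}
        for j, m in enumerate(self.markers):
            lut = {0: m.call_string(0), 1: m.call_string(1), 2: m.call_string(2),
                   MISSING: MISSING_CALL}
            cols[m.id] = [lut[int(d)] for d in self.dosage[:, j]]
        return pd.DataFrame(cols, index=pd.Index(self.samples, name="sample"))

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def subset(
        self,
        samples: Sequence[int] | None = None,
        markers: Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if samples is None else np.asarray(list(samples))
        mi = np.arange(self.n_markers) if markers is None else np.asarray(list(markers))
        return GenotypeMatrix(
            [self.samples[i] for i in si],
            [self.markers[j] for j in mi],
            self.dosage[np.ix_(si, mi)],
        )

    def sorted_by_position(self) -> "GenotypeMatrix":
        order = sorted(range(self.n_markers),
                       key=lambda j: (self.markers[j].chrom, self.markers[j].pos))
        return self.subset(markers=order)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeMatrix({self.n_samples} samples × {self.n_markers} markers)"


@dataclass
class VariantRecord:
    """One VCF site: alleles, annotations, and per-sample diploid calls.

    ``sample_calls`` holds allele-index pairs (0=ref) with ``None`` for a
    missing genotype; phasing is ignored.  INFO keys that are absent in the
    file are absent from ``info`` (never defaulted to zero).
    """

    chrom: str
    pos: int
    ref: str
    alts: list[str]
    qual: float | None = None
    info: dict[str, float] = field(default_factory=dict)
    sample_calls: list[tuple[int, int] | None] = field(default_factory=list)
    sample_depths: list[int | None] = field(default_factory=list)
    id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"{self.chrom}:{self.pos}: pos must be >= 1")
        if not self.alts:
            raise ValidationError(f"{self.chrom}:{self.pos}: no alternate allele")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    def allele_counts(self) -> dict[int, int]:
        """Counts of each allele index over non-missing genotypes."""
        counts: dict[int, int] = {}
        for call in self.sample_calls:
            if call is None:
                continue
            for a in call:
                counts[a] = counts.get(a, 0) + 1
        return counts

    def alt_frequency(self) -> float:
        """Alternate-allele frequency over non-missing calls (biallelic)."""
        counts = self.allele_counts()
        total = sum(counts.values())
        if total == 0:
            raise ValidationError(f"{self.chrom}:{self.pos}: all genotypes missing")
        return counts.get(1, 0) / total


_INFO_FLOAT_KEYS = ("QD", "MQ", "MQRankSum", "ReadPosRankSum", "DP")


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF v4.x file into :class:`VariantRecord` objects, in file order."""
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError on malformed headers
        raise FormatError(f"{path}: cannot parse VCF header ({exc})") from exc
    records: list[VariantRecord] = []
    try:
        for lineno, v in enumerate(vcf, start=1):
            info = {}
            for key in _INFO_FLOAT_KEYS:
                val = v.INFO.get(key)
                if val is not None:
                    info[key] = float(val)
            calls: list[tuple[int, int] | None] = []
            for g in v.genotypes:  # [allele1, allele2, phased]
                a, b = g[0], g[1]
                calls.append(None if a < 0 or b < 0 else (min(a, b), max(a, b)))
            depths: list[int | None] = [None] * len(calls)
            try:
                dp = v.format("DP")
            except KeyError:
                dp = None
            if dp is not None:
                depths = [None if d < 0 else int(d) for d in dp[:, 0]]
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alts=list(v.ALT),
                    qual=None if v.QUAL is None else float(v.QUAL),
                    info=info,
                    sample_calls=calls,
                    sample_depths=depths,
                    id=v.ID or ".",
                )
            )
    except Exception as exc:
        if isinstance(exc, (FormatError, ValidationError)):
            raise
        raise FormatError(
            f"{path}: malformed record near data line {len(records) + 1} ({exc})"
        ) from exc
    return records


def write_vcf(records: Iterable[VariantRecord], path: str | Path,
              sample_names: Sequence[str]) -> None:
    """Write records as plain-text VCF v4.2 with the annotation fields used here."""
    records = list(records)
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">',
        '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Sample depth">',
    ]
    for chrom in dict.fromkeys(r.chrom for r in records):
        maxpos = max(r.pos for r in records if r.chrom == chrom)
        lines.append(f"##contig=<ID={chrom},length={maxpos + 1000}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names))
    for r in records:
        if len(r.sample_calls) != len(sample_names):
            raise ValidationError(
                f"{r.chrom}:{r.pos}: {len(r.sample_calls)} calls for "
                f"{len(sample_names)} samples"
            )
        info_parts = []
        for key in _INFO_FLOAT_KEYS:
            if key in r.info:
                val = r.info[key]
                info_parts.append(f"{key}={int(val)}" if key == "DP"
                                  else f"{key}={val:.4g}")
        info_str = ";".join(info_parts) or "."
        fields = [
            r.chrom, str(r.pos), r.id, r.ref, ",".join(r.alts),
            "." if r.qual is None else f"{r.qual:.4g}", "PASS", info_str, "GT:DP",
        ]
        for call, dp in zip(r.sample_calls, r.sample_depths):
            gt = "./." if call is None else f"{call[0]}/{call[1]}"
            fields.append(f"{gt}:{'.' if dp is None else dp}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# genotype CSV/TSV dialect
# ---------------------------------------------------------------------------

_ID_POS_RE = re.compile(r"^(?P<chrom>.+?)[_:](?P<pos>\d+)$")


def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".markers.tsv")


def write_marker_table(markers: Sequence[MarkerMeta], path: str | Path) -> None:
    pd.DataFrame(
        {"id": [m.id for m in markers], "chrom": [m.chrom for m in markers],
         "pos": [m.pos for m in markers], "ref": [m.ref for m in markers],
         "alt": [m.alt for m in markers]}
    ).to_csv(path, sep="\t", index=False)


def read_marker_table(path: str | Path) -> list[MarkerMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [MarkerMeta(str(r.id), str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
            for r in df.itertuples()]


def write_genotype_table(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write calls as CSV/TSV plus a ``<path>.markers.tsv`` metadata sidecar."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    matrix.call_frame().to_csv(path, sep=sep)
    write_marker_table(matrix.markers, _sidecar_path(path))


def _infer_marker(marker_id: str, column: pd.Series, index: int) -> MarkerMeta:
    observed = sorted({b for c in column.dropna()
                       for b in str(c).strip().upper()
                       if b in set("ACGT")})
    if len(observed) > 2:
        raise ValidationError(f"marker {marker_id}: >2 alleles observed: {observed}")
    if len(observed) == 0:
        observed = ["A", "C"]  # all-missing column: allele identity unknowable
    if len(observed) == 1:
        observed.append(next(b for b in BASES if b != observed[0]))
    m = _ID_POS_RE.match(marker_id)
    chrom = m.group("chrom") if m else "0"
    pos = int(m.group("pos")) if m else index + 1
    return MarkerMeta(marker_id, chrom, pos, observed[0], observed[1])


def read_genotype_table(
    path: str | Path, markers: Sequence[MarkerMeta] | None = None
) -> GenotypeMatrix:
    """Read the genotype CSV/TSV dialect.

    Marker metadata comes from (in order of precedence) the ``markers``
    argument, a ``<path>.markers.tsv`` sidecar, or inference from the observed
    alleles (ref = alphabetically first) with chrom/pos parsed from IDs of the
    form ``chrom_pos``.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if markers is None and _sidecar_path(path).exists():
        markers = read_marker_table(_sidecar_path(path))
    if markers is not None:
        by_id = {m.id: m for m in markers}
        missing_meta = [c for c in df.columns if c not in by_id]
        if missing_meta:
            raise ValidationError(f"no metadata for marker(s) {missing_meta}")
        metas = [by_id[c] for c in df.columns]
    else:
        metas = [_infer_marker(c, df[c], j) for j, c in enumerate(df.columns)]

    dosage = np.full(df.shape, MISSING, dtype=np.int8)
    errors: list[str] = []
    for j, meta in enumerate(metas):
        for i, raw in enumerate(df.iloc[:, j]):
            cell = "" if (raw is None or (isinstance(raw, float) and np.isnan(raw))) else str(raw)
            try:
                dosage[i, j] = meta.dosage_of(cell)
            except ValidationError as exc:
                errors.append(f"row {df.index[i]!r} × column {meta.id!r}: {exc}")
    if errors:
        raise ValidationError("invalid calls:\n  " + "\n  ".join(errors))
    return GenotypeMatrix([str(s) for s in df.index], metas, dosage)


def export_structure_format(matrix: GenotypeMatrix) -> str:
    """Render a matrix as STRUCTURE input: two rows per sample, -9 = missing.

    Alleles are recoded A=1, C=2, G=3, T=4; within a heterozygote the lower
    code is written on the first of the sample's two rows.
    """
    lines = [" ".join(m.id for m in matrix.markers)]
    for i, sample in enumerate(matrix.samples):
        rows: list[list[str]] = [[sample], [sample]]
        for j, m in enumerate(matrix.markers):
            d = int(matrix.dosage[i, j])
            if d == MISSING:
                a1 = a2 = STRUCTURE_MISSING
            else:
                bases = sorted(m.call_string(d))
                a1, a2 = STRUCTURE_CODES[bases[0]], STRUCTURE_CODES[bases[1]]
            rows[0].append(str(a1))
            rows[1].append(str(a2))
        lines.append(" ".join(rows[0]))
        lines.append(" ".join(rows[1]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_NEWICK_UNSAFE = re.compile(r"[\s(),:;\[\]']")


def _newick_label(name: str) -> str:
    if _NEWICK_UNSAFE.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _fmt_length(x: float | None) -> str:
    if x is None:
        return ""
    return f":{float(x):.6g}"


def write_newick(tree) -> str:
    """Serialize a tree (scikit-bio ``TreeNode``) to Newick.

    Branch lengths are rendered with 6 significant digits; labels containing
    Newick metacharacters are single-quoted. Every leaf must be named.
    """

    def render(node) -> str:
        if node.is_tip():
            if not node.name:
                raise ValidationError("unlabeled leaf in tree")
            return _newick_label(node.name) + _fmt_length(node.length)
        inner = ",".join(render(c) for c in node.children)
        label = _newick_label(node.name) if node.name else ""
        return f"({inner}){label}{_fmt_length(node.length)}"

    return render(tree) + ";"


def read_newick(text: str):
    """Parse Newick into a scikit-bio ``TreeNode`` (round-trip counterpart)."""
    from skbio import TreeNode

    return TreeNode.read(_io.StringIO(text))
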