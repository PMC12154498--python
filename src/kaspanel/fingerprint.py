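"""Fingerprint barcodes: genotype-call strings per sample over a marker panel.

A fingerprint is the ordered string of two-letter genotype symbols
("AA", "AG", ..., "NN" for no-call) over a fixed marker order — by
(chrom, pos) so codes are comparable across runs.  Heterozygote symbols are
alphabetized, making the encoding injective on genotype vectors.  The
fingerprint matrix plot follows the conventional orientation (one row per
marker, one column per sample) with homozygote classes colored
AA=yellow, CC=green, GG=blue, TT=purple, heterozygotes gray, no-call white.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, MISSING_CALL

SEPARATOR = "-"

#: Figure-style color classes; total and mutually exclusive over genotypes
COLOR_MAP = {
    "AA": "#f2c500",  # yellow
    "CC": "#2ca02c",  # green
    "GG": "#1f77b4",  # blue
    "TT": "#9467bd",  # purple
    "HET": "#999999",
    "NN": "#ffffff",
}


class FingerprintError(ValueError):
    pass


@dataclass(frozen=True)
class Fingerprint:
    sample_id: str
    marker_ids: tuple[str, ...]
    code: tuple[str, ...]   # one symbol per marker, canonicalized

    def __str__(self) -> str:
        return SEPARATOR.join(self.code)


def color_class(symbol: str) -> str:
    """Color-map class of a genotype symbol (homozygote base pair / HET / NN)."""
    if symbol == MISSING_CALL:
        return "NN"
    if symbol[0] == symbol[1]:
        return symbol
    return "HET"


def _marker_order(matrix: GenotypeMatrix) -> list[int]:
    return sorted(range(matrix.n_markers),
                  key=lambda j: (matrix.markers[j].chrom, matrix.markers[j].pos))


def encode_fingerprint(matrix: GenotypeMatrix, sample_id: str,
                       markers: Sequence[str] | None = None) -> Fingerprint:
    """Fingerprint of one sample; marker order fixed by (chrom, pos)."""
    try:
        i = matrix.samples.index(sample_id)
    except ValueError:
        raise FingerprintError(f"unknown sample {sample_id!r}") from None
    if markers is not None:
        by_id = {m.id: j for j, m in enumerate(matrix.markers)}
        unknown = [m for m in markers if m not in by_id]
        if unknown:
            raise FingerprintError(f"marker(s) absent from matrix: {unknown}")
        idx = sorted((by_id[m] for m in markers),
                     key=lambda j: (matrix.markers[j].chrom, matrix.markers[j].pos))
    else:
        idx = _marker_order(matrix)
    code = tuple(matrix.call(i, j) for j in idx)
    return Fingerprint(sample_id, tuple(matrix.markers[j].id for j in idx), code)


def encode_all(matrix: GenotypeMatrix,
               markers: Sequence[str] | None = None) -> list[Fingerprint]:
    return [encode_fingerprint(matrix, s, markers) for s in matrix.samples]


def compare_fingerprints(a: Fingerprint, b: Fingerprint
                         ) -> tuple[int, int, int]:
    """(matches, mismatches, incomparable) symbol counts; requires same markers.

    A position is *incomparable* when either symbol is a no-call; the three
    counts partition the code length.
    """
    if a.marker_ids != b.marker_ids:
        raise FingerprintError("fingerprints have differing marker order")
    matches = mismatches = incomparable = 0
    for x, y in zip(a.code, b.code):
        if x == MISSING_CALL or y == MISSING_CALL:
            incomparable += 1
        elif x == y:
            matches += 1
        else:
            mismatches += 1
    return matches, mismatches, incomparable


def fingerprint_table(matrix: GenotypeMatrix,
                      markers: Sequence[str] | None = None) -> pd.DataFrame:
    """Marker × sample table of genotype symbols (the plot's underlying data)."""
    fps = encode_all(matrix, markers)
    df = pd.DataFrame({fp.sample_id: list(fp.code) for fp in fps},
                      index=pd.Index(fps[0].marker_ids, name="marker"))
    return df


def fingerprint_matrix(matrix: GenotypeMatrix,
                       markers: Sequence[str] | None = None,
                       out_png: str | Path | None = None,
                       out_tsv: str | Path | None = None):
    """Render the fingerprint grid (markers × samples) and its sidecar TSV.

    Returns (matplotlib Figure, DataFrame of symbols).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    df = fingerprint_table(matrix, markers)
    classes = ["AA", "CC", "GG", "TT", "HET", "NN"]
    class_idx = {c: k for k, c in enumerate(classes)}
    grid = np.array([[class_idx[color_class(sym)] for sym in row]
                     for row in df.itertuples(index=False)])
    cmap = ListedColormap([COLOR_MAP[c] for c in classes])

    fig, ax = plt.subplots(
        figsize=(max(4, 0.12 * df.shape[1] + 1), max(3, 0.25 * df.shape[0] + 1)))
    ax.imshow(grid, cmap=cmap, vmin=0, vmax=len(classes) - 1,
              aspect="auto", interpolation="nearest")
    ax.set_yticks(range(df.shape[0]), df.index, fontsize=6)
    ax.set_xlabel("sample")
    ax.set_ylabel("marker")
    if df.shape[1] <= 40:
        ax.set_xticks(range(df.shape[1]), df.columns, rotation=90, fontsize=6)
    else:
        ax.set_xticks([])
    handles = [plt.Rectangle((0, 0), 1, 1, facecolor=COLOR_MAP[c],
                             edgecolor="#444444") for c in classes]
    ax.legend(handles, ["AA", "CC", "GG", "TT", "heterozygous", "no call"],
              loc="upper left", bbox_to_anchor=(1.01, 1), fontsize=7)
    fig.tight_layout()
    if out_png is not None:
        fig.savefig(out_png, dpi=150)
    if out_tsv is not None:
        df.to_csv(out_tsv, sep="\t")
    return fig, df


def read_fingerprint_table(path: str | Path) -> list[Fingerprint]:
    """Load the sidecar TSV back into Fingerprint objects."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    marker_ids = tuple(df.index)
    return [Fingerprint(str(col), marker_ids, tuple(df[col])) for col in df.columns]
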