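"""Strand-aware sequence context around A-to-I sites and the position-wise
nucleotide frequency matrix (the ADAR signature: G enriched at +1, depleted
at -1)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import revcomp

_BASES = ("A", "C", "G", "T")


def extract_context(
    chrom: str,
    pos: int,
    strand: str,
    genome: Mapping[str, str],
    k: int = 5,
) -> str | None:
    """(2k+1)-mer centred on the site, read on the editing strand.

    Minus-strand sites are reverse-complemented so the edited base reads as A
    at the centre. Sites closer than ``k`` to a chromosome end return None
    (dropped; padding would distort the frequency columns).
    """
    seq = genome[chrom]
    lo, hi = pos - 1 - k, pos + k
    if lo < 0 or hi > len(seq):
        return None
    window = seq[lo:hi]
    return revcomp(window) if strand == "-" else window


def extract_contexts(
    sites: Iterable[tuple[str, int, str]],
    genome: Mapping[str, str],
    k: int = 5,
) -> tuple[list[str], int]:
    """Contexts for (chrom, pos, strand) triples; returns (contexts, n_dropped)."""
    contexts = []
    dropped = 0
    for chrom, pos, strand in sites:
        ctx = extract_context(chrom, pos, strand, genome, k)
        if ctx is None:
            dropped += 1
        else:
            contexts.append(ctx)
    return contexts, dropped


@dataclass
class ContextMatrix:
    """4 x (2k+1) column-normalised base frequencies around the edited base."""

    freq: pd.DataFrame  # index A/C/G/T, columns -k..k
    enrichment: pd.DataFrame  # log2(freq / 0.25); -inf where freq == 0
    n_sites: int

    def frequency(self, base: str, offset: int) -> float:
        return float(self.freq.loc[base, offset])


def frequency_matrix(contexts: Sequence[str]) -> ContextMatrix:
    """Column-normalised counts over aligned contexts (order-invariant)."""
    if not contexts:
        raise ValueError("at least one context is required")
    width = len(contexts[0])
    if any(len(c) != width for c in contexts):
        raise ValueError("contexts must all have the same length")
    k = width // 2
    counts = np.zeros((4, width), dtype=float)
    code = {b: i for i, b in enumerate(_BASES)}
    for ctx in contexts:
        for j, base in enumerate(ctx.upper()):
            if base in code:
                counts[code[base], j] += 1
    col_tot = counts.sum(axis=0)
    col_tot[col_tot == 0] = 1.0
    freq = counts / col_tot
    offsets = list(range(-k, k + 1))
    freq_df = pd.DataFrame(freq, index=list(_BASES), columns=offsets)
    with np.errstate(divide="ignore"):
        enr = pd.DataFrame(np.log2(freq / 0.25), index=list(_BASES), columns=offsets)
    return ContextMatrix(freq_df, enr, len(contexts))


def plot_logo(matrix: ContextMatrix, path) -> None:
    """Stacked-bar rendering of the per-position base frequencies."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    offsets = list(matrix.freq.columns)
    bottom = np.zeros(len(offsets))
    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(offsets), 3))
    for base in _BASES:
        vals = matrix.freq.loc[base].to_numpy()
        ax.bar(offsets, vals, bottom=bottom, label=base, color=colors[base])
        bottom += vals
    ax.set_xlabel("position relative to edited A")
    ax.set_ylabel("frequency")
    ax.legend(ncol=4, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
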