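"""Tissue-specific editing sites (SES) by ROKU-style Shannon entropy.

A site's per-tissue editing-level vector x is centred by a one-step Tukey
biweight location estimate, the absolute residuals x' are normalised into a
probability vector p, and H = -sum p_i log2 p_i is computed. Sites with
H < 0.5 bits are tissue-specific; the assigned tissue is the argmax of x'.
A perfectly flat vector carries no specificity signal and is assigned the
maximal entropy log2(n) by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

BIWEIGHT_C = 5.0
BIWEIGHT_EPS = 1e-4


def tukey_biweight(x: Sequence[float], c: float = BIWEIGHT_C, eps: float = BIWEIGHT_EPS) -> float:
    """One-step Tukey biweight location estimate.

    m = median(x); s = MAD(x); u_i = (x_i - m) / (c*s + eps);
    w_i = (1 - u_i^2)^2 for |u_i| < 1 else 0; returns sum(w x)/sum(w)
    (the median when every weight vanishes).
    """
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ValueError("tukey_biweight requires a vector of length >= 2")
    m = float(np.median(arr))
    s = float(median_abs_deviation(arr, scale=1.0))
    u = (arr - m) / (c * s + eps)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    wsum = w.sum()
    if wsum == 0.0:
        return m
    return float((w * arr).sum() / wsum)


def roku_entropy(x: Sequence[float]) -> tuple[float, np.ndarray]:
    """Shannon entropy (bits) of the biweight-centred absolute residuals.

    Returns ``(H, x')``. A flat vector (all residuals zero) is maximally
    nonspecific: H = log2(len(x)) by convention.
    """
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ValueError("roku_entropy requires a vector of length >= 2")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("editing levels must lie in [0, 1]")
    xprime = np.abs(arr - tukey_biweight(arr))
    total = xprime.sum()
    if total == 0.0:
        return float(np.log2(arr.size)), xprime
    p = xprime / total
    nz = p[p > 0]
    h = float(-(nz * np.log2(nz)).sum())
    return h, xprime


@dataclass
class SESRecord:
    chrom: str
    pos: int
    entropy: float
    tissues: tuple[str, ...]  # argmax of x'; several when tied
    tie: bool
    xprime: np.ndarray


def build_matrix(
    atlas: pd.DataFrame, tissues: Sequence[str]
) -> tuple[pd.DataFrame, int]:
    """Sites x tissues editing-level matrix from the atlas.

    Rows are restricted to sites covered in every requested tissue (values
    are the coverage-aware per-tissue means); returns the matrix and the
    number of dropped (incomplete) rows.
    """
    for t in tissues:
        if f"level_{t}" not in atlas.columns:
            raise ValueError(f"unknown tissue {t!r}: no level_{t} column in atlas")
    level_cols = [f"level_{t}" for t in tissues]
    complete = atlas[level_cols].notna().all(axis=1)
    if all(f"n_covered_{t}" in atlas.columns for t in tissues):
        cov_cols = [f"n_covered_{t}" for t in tissues]
        complete &= (atlas[cov_cols] >= 1).all(axis=1)
    sub = atlas.loc[complete, ["chrom", "pos"] + level_cols].copy()
    sub.columns = ["chrom", "pos"] + list(tissues)
    matrix = sub.set_index(["chrom", "pos"])
    return matrix, int((~complete).sum())


def detect_ses(
    matrix: pd.DataFrame, threshold: float = 0.5
) -> list[SESRecord]:
    """Rows with H < threshold, with the specific tissue(s) assigned by
    argmax of the processed vector (ties flagged and all listed)."""
    tissues = list(matrix.columns)
    out: list[SESRecord] = []
    for (chrom, pos), row in matrix.iterrows():
        h, xprime = roku_entropy(row.to_numpy())
        if h >= threshold:
            continue
        best = xprime.max()
        winners = tuple(t for t, v in zip(tissues, xprime) if v == best)
        out.append(
            SESRecord(
                chrom=chrom,
                pos=int(pos),
                entropy=h,
                tissues=winners,
                tie=len(winners) > 1,
                xprime=xprime,
            )
        )
    return out


def ses_table(records: Sequence[SESRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "entropy": r.entropy,
                "tissue": ",".join(r.tissues),
                "tie": r.tie,
            }
            for r in records
        ],
        columns=["chrom", "pos", "entropy", "tissue", "tie"],
    )


def ses_counts(records: Sequence[SESRecord]) -> dict[str, int]:
    """Per-tissue SES counts (tied sites count once per listed tissue)."""
    counts: dict[str, int] = {}
    for r in records:
        for t in r.tissues:
            counts[t] = counts.get(t, 0) + 1
    return counts
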