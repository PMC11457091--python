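"""Editing-aware miRNA target rescan on 3'UTR windows.

For an edited 3'UTR position, two +/-150 bp windows are built that differ only
at the edited base (A = unedited, G = edited). Each window is scanned with a
fully specified miRanda-style local duplex aligner: the miRNA is threaded
3'->5' along the window 5'->3' under complementarity scoring (Watson-Crick
+5, G:U wobble +2, mismatch -4, affine gaps -9/-4), with all contributions
from miRNA seed positions 2-8 doubled; hits are non-overlapping local maxima
with score >= 140. Binding is then classified per site x miRNA as lost,
gained, retained or absent upon editing, driven only by hits whose footprint
covers the edited position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

_WC = {"A": "T", "C": "G", "G": "C", "T": "A"}
_NEG = -1e9  # sentinel for masked / invalid window positions


class SequenceError(ValueError):
    """A sequence contains symbols outside A/C/G/U/T."""


@dataclass(frozen=True)
class ScanParams:
    match: float = 5.0
    wobble: float = 2.0
    mismatch: float = -4.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_start: int = 2  # miRNA positions (1-based from the 5' end)
    seed_end: int = 8
    seed_factor: float = 2.0
    threshold: float = 140.0
    max_hits: int = 8


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    start: int  # window footprint, 0-based half-open
    end: int
    score: float
    pairs: tuple[tuple[int, int], ...]  # (window index, miRNA position 1-based)

    def covers(self, window_pos: int) -> bool:
        return self.start <= window_pos < self.end

    def seed_window_positions(self, params: ScanParams) -> frozenset[int]:
        """Window indices paired against the miRNA seed (positions 2-8)."""
        return frozenset(
            j for j, p in self.pairs if params.seed_start <= p <= params.seed_end
        )


@dataclass(frozen=True)
class RescanResult:
    status: str  # lost_by_editing / gained_by_editing / retained / absent
    score_a: float | None
    score_g: float | None
    seed_overlap: bool  # edit inside the seed-pairing region of a driving hit
    n_hits_a: int = 0
    n_hits_g: int = 0


def _clean(seq: str, what: str) -> str:
    seq = seq.upper().replace("U", "T")
    if any(b not in "ACGTN" for b in seq):
        raise SequenceError(f"{what} contains non-nucleotide symbols: {seq!r}")
    return seq


def extract_windows(
    utr: str, edit_pos: int, flank: int = 150
) -> tuple[str, str, int]:
    """Unedited (A) and edited (G) windows around a 3'UTR position.

    ``edit_pos`` is the 0-based offset of the edited base within the
    transcript-oriented UTR, which must read A when unedited. Windows
    truncate at UTR ends (equal lengths across alleles); interior sites give
    2*flank+1 = 301 nt. Returns (window_A, window_G, edit offset in window).
    """
    utr = _clean(utr, "UTR")
    if not 0 <= edit_pos < len(utr):
        raise ValueError(f"edit position {edit_pos} outside the UTR (len {len(utr)})")
    if utr[edit_pos] != "A":
        raise ValueError(
            f"unedited base at UTR offset {edit_pos} is {utr[edit_pos]!r}, expected A"
        )
    lo = max(0, edit_pos - flank)
    hi = min(len(utr), edit_pos + flank + 1)
    window_a = utr[lo:hi]
    center = edit_pos - lo
    window_g = window_a[:center] + "G" + window_a[center + 1 :]
    return window_a, window_g, center


def _pair_score(mir_base: str, win_base: str, params: ScanParams) -> float:
    if win_base == "N" or mir_base == "N":
        return _NEG
    if _WC[mir_base] == win_base:
        return params.match
    if (mir_base == "G" and win_base == "T") or (mir_base == "T" and win_base == "G"):
        return params.wobble
    return params.mismatch


def _align(
    window: str, mirna: str, params: ScanParams, masked: np.ndarray
) -> tuple[float, list[tuple[int, int]]]:
    """Best local alignment of the reversed miRNA against the window (Gotoh).

    Seed weighting doubles substitution scores and miRNA-consuming gap
    penalties at miRNA positions 2-8. Returns (score, aligned pairs as
    (window index, miRNA position)).
    """
    m, n = len(mirna), len(window)
    rev = mirna[::-1]  # rev[i] pairs 3'->5'; miRNA position = m - i
    weight = [
        params.seed_factor if params.seed_start <= m - i <= params.seed_end else 1.0
        for i in range(m)
    ]
    sub = np.full((m, n), _NEG)
    for i in range(m):
        w = weight[i]
        for j in range(n):
            if masked[j]:
                continue
            sub[i, j] = w * _pair_score(rev[i], window[j], params)

    M = np.full((m + 1, n + 1), _NEG)
    X = np.full((m + 1, n + 1), _NEG)  # gap consuming miRNA bases
    Y = np.full((m + 1, n + 1), _NEG)  # gap consuming window bases
    ptr_m = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 start, 1 M, 2 X, 3 Y
    ptr_x = np.zeros((m + 1, n + 1), dtype=np.int8)  # 1 from M, 2 from X
    ptr_y = np.zeros((m + 1, n + 1), dtype=np.int8)

    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        w = weight[i - 1]
        go_i, ge_i = params.gap_open * w, params.gap_extend * w
        for j in range(1, n + 1):
            # X: delete miRNA base i (no window base consumed)
            xo, xe = M[i - 1, j] + go_i, X[i - 1, j] + ge_i
            if xo >= xe:
                X[i, j], ptr_x[i, j] = xo, 1
            else:
                X[i, j], ptr_x[i, j] = xe, 2
            # Y: insert window base j (bulge on the target)
            yo = M[i, j - 1] + params.gap_open
            ye = Y[i, j - 1] + params.gap_extend
            if masked[j - 1]:
                yo = ye = _NEG
            if yo >= ye:
                Y[i, j], ptr_y[i, j] = yo, 1
            else:
                Y[i, j], ptr_y[i, j] = ye, 2
            # M: pair rev[i-1] with window[j-1]
            s = sub[i - 1, j - 1]
            prev = M[i - 1, j - 1]
            src = 1
            if X[i - 1, j - 1] > prev:
                prev, src = X[i - 1, j - 1], 2
            if Y[i - 1, j - 1] > prev:
                prev, src = Y[i - 1, j - 1], 3
            if prev < 0.0:
                prev, src = 0.0, 0
            val = prev + s
            if val < 0.0:
                val, src = _NEG, 0
            M[i, j] = val
            ptr_m[i, j] = src
            if val > best:
                best, bi, bj = val, i, j

    if best <= 0.0:
        return 0.0, []
    pairs: list[tuple[int, int]] = []
    state, i, j = 1, bi, bj
    while i > 0 and j > 0:
        if state == 1:  # M
            pairs.append((j - 1, m - (i - 1)))
            state = ptr_m[i, j]
            i, j = i - 1, j - 1
            if state == 0:
                break
        elif state == 2:  # X
            state = ptr_x[i, j]
            i -= 1
            state = 1 if state == 1 else 2
        else:  # Y
            state = ptr_y[i, j]
            j -= 1
            state = 1 if state == 1 else 3
    pairs.reverse()
    return float(best), pairs


def scan_targets(
    window: str, mirna: str, params: ScanParams | None = None, mirna_id: str = "miRNA"
) -> list[TargetHit]:
    """Non-overlapping local duplex hits with score >= threshold, greedily
    extracted best-first (found footprints are masked before rescanning)."""
    params = params or ScanParams()
    window = _clean(window, "window")
    mirna = _clean(mirna, "miRNA")
    if not window or not mirna:
        return []
    masked = np.zeros(len(window), dtype=bool)
    hits: list[TargetHit] = []
    for _ in range(params.max_hits):
        score, pairs = _align(window, mirna, params, masked)
        if score < params.threshold or not pairs:
            break
        win_positions = [j for j, _ in pairs]
        start, end = min(win_positions), max(win_positions) + 1
        hits.append(TargetHit(mirna_id, start, end, score, tuple(pairs)))
        masked[start:end] = True
    hits.sort(key=lambda h: h.start)
    return hits


def classify_rescan(
    hits_a: Sequence[TargetHit],
    hits_g: Sequence[TargetHit],
    edit_pos: int,
    params: ScanParams | None = None,
) -> RescanResult:
    """Compare the two alleles' hits at the edited position.

    Only hits whose footprint covers the edited base drive the status; other
    hits are counted but do not change the classification.
    """
    params = params or ScanParams()
    cov_a = [h for h in hits_a if h.covers(edit_pos)]
    cov_g = [h for h in hits_g if h.covers(edit_pos)]
    if cov_a and not cov_g:
        status = "lost_by_editing"
    elif cov_g and not cov_a:
        status = "gained_by_editing"
    elif cov_a and cov_g:
        status = "retained"
    else:
        status = "absent"
    best_a = max(cov_a, key=lambda h: h.score) if cov_a else None
    best_g = max(cov_g, key=lambda h: h.score) if cov_g else None
    seed = any(
        edit_pos in h.seed_window_positions(params)
        for h in (best_a, best_g)
        if h is not None
    )
    return RescanResult(
        status=status,
        score_a=best_a.score if best_a else None,
        score_g=best_g.score if best_g else None,
        seed_overlap=seed,
        n_hits_a=len(hits_a),
        n_hits_g=len(hits_g),
    )


def rescan_site(
    utr: str,
    edit_pos: int,
    mirna: str,
    mirna_id: str = "miRNA",
    flank: int = 150,
    params: ScanParams | None = None,
) -> RescanResult:
    """Windows + scan + classification for one (site, miRNA) pair."""
    params = params or ScanParams()
    window_a, window_g, center = extract_windows(utr, edit_pos, flank)
    hits_a = scan_targets(window_a, mirna, params, mirna_id)
    hits_g = scan_targets(window_g, mirna, params, mirna_id)
    return classify_rescan(hits_a, hits_g, center, params)


def rescan_table(
    utrs: Mapping[str, str],
    site_offsets: Mapping[str, Sequence[tuple[str, int, str, str]]] | None = None,
    pairs: Sequence[tuple[str, int, str, str]] | None = None,
    flank: int = 150,
    params: ScanParams | None = None,
) -> pd.DataFrame:
    """Rescan many (transcript, UTR offset, miRNA id, miRNA seq) pairs.

    ``pairs`` rows are (transcript_id, utr_offset, mirna_id, mirna_seq).
    """
    params = params or ScanParams()
    rows = []
    for tx_id, offset, mid, mseq in pairs or []:
        res = rescan_site(utrs[tx_id], offset, mseq, mid, flank, params)
        rows.append(
            {
                "transcript_id": tx_id,
                "utr_offset": offset,
                "mirna_id": mid,
                "status": res.status,
                "score_A": res.score_a,
                "score_G": res.score_g,
                "seed_overlap": res.seed_overlap,
                "n_hits_A": res.n_hits_a,
                "n_hits_G": res.n_hits_g,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "utr_offset",
            "mirna_id",
            "status",
            "score_A",
            "score_G",
            "seed_overlap",
            "n_hits_A",
            "n_hits_G",
        ],
    )
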