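"""Independent reference implementations used only to check the package.

These deliberately avoid the library's scanning and resampling code paths:
site matching is re-derived here from the seed definition with Biopython's
reverse complement, windows are enumerated exhaustively, and the null is
re-simulated step by step with find_sites on extracted substrings.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq


def oracle_patterns(mirna_sequence: str) -> tuple[str, str, str]:
    """(pat8, pat7m8, pat7a1) derived independently via Bio.Seq."""
    rna = mirna_sequence.upper().replace("T", "U")
    seed28 = rna[1:8]  # miRNA positions 2-8
    match78 = str(Seq(seed28.replace("U", "T")).reverse_complement())  # 7 nt
    pat7m8 = match78
    pat7a1 = match78[1:] + "A"  # positions 2-7 complement + target A
    pat8 = match78 + "A"
    return pat8, pat7m8, pat7a1


def oracle_scan(utr_seq: str, mirna_sequence: str) -> list[tuple[int, int, str]]:
    """Exhaustive all-window scan + greedy left-to-right non-overlap filter.

    Every window of length 8 and 7 is tested; each start keeps its highest-
    priority match (8mer > 7mer-m8 > 7mer-A1); greedy selection then walks
    candidates by start coordinate, skipping any that overlap the last
    accepted site. Returns (start, end, site_type) triples.
    """
    seq = utr_seq.upper().replace("U", "T")
    pat8, pat7m8, pat7a1 = oracle_patterns(mirna_sequence)
    candidates: list[tuple[int, int, str]] = []
    for start in range(len(seq)):
        w8 = seq[start:start + 8]
        w7 = seq[start:start + 7]
        if len(w8) == 8 and w8 == pat8:
            candidates.append((start, start + 8, "8mer"))
        elif len(w7) == 7 and w7 == pat7m8:
            candidates.append((start, start + 7, "7mer-m8"))
        elif len(w7) == 7 and w7 == pat7a1:
            candidates.append((start, start + 7, "7mer-A1"))
    accepted: list[tuple[int, int, str]] = []
    last_end = -1
    for start, end, site_type in candidates:  # already sorted by start
        if start >= last_end:
            accepted.append((start, end, site_type))
            last_end = end
    return accepted


def pooled_t_p(a, b) -> float:
    """Textbook pooled-variance two-sample t-test, two-sided p-value."""
    from scipy.stats import t as t_dist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t_stat = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    return float(2.0 * t_dist.sf(abs(t_stat), df))


def bh_step_up(p_values) -> np.ndarray:
    """Benjamini-Hochberg by the step-up recurrence, written longhand."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        value = p[order[rank - 1]] * m / rank
        running = min(running, value)
        adj_sorted[rank - 1] = running
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def resimulate_null(
    lengths, background, seed: int, B: int, count_sites
) -> np.ndarray:
    """Re-run the documented null RNG protocol with an independent counter.

    ``background`` is a list of (gene_id, sequence) pairs; eligibility,
    ordering and the draw sequence mirror the published protocol (background
    sorted by (length, id); per gene: B UTR draws then B start draws), while
    site counting in each extracted substring is delegated to
    ``count_sites(subsequence)`` supplied by the caller.
    """
    bg = sorted(background, key=lambda kv: (len(kv[1]), kv[0]))
    bg_lens = np.array([len(s) for _, s in bg])
    rng = np.random.default_rng(seed)
    densities = np.empty((len(lengths), B))
    for i, L in enumerate(lengths):
        lo = int(np.searchsorted(bg_lens, L, side="left"))
        assert lo < len(bg), "oracle does not model the length fallback"
        picks = lo + rng.integers(0, len(bg) - lo, size=B)
        starts = rng.integers(0, bg_lens[picks] - L + 1)
        for b in range(B):
            sub = bg[picks[b]][1][int(starts[b]):int(starts[b]) + L]
            densities[i, b] = 1000.0 * count_sites(sub) / L
    return np.median(densities, axis=0)
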