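"""Independent oracles used by the test suite and the acceptance script.

These are deliberately naive, written against the definitions rather
than against the implementations they check.
"""

from __future__ import annotations

import itertools
import re


def brute_force_local_score(a: str, b: str, substitution, gap_open: int,
                            gap_extend: int) -> int:
    """Exhaustive optimal local alignment score.

    Enumerates every local alignment as a choice of aligned-column index
    subsets (i_1 < ... < i_k) of ``a`` and (j_1 < ... < j_k) of ``b``:
    columns score via the substitution function, and the unaligned
    stretch between consecutive columns costs one affine gap run per
    sequence (gap of length g costs gap_open + gap_extend * g).
    Interleaving insertion/deletion runs between two columns can only
    add gap opens, so this enumeration covers every optimal alignment.
    The empty alignment scores 0.
    """
    best = 0
    m, n = len(a), len(b)
    for k in range(1, min(m, n) + 1):
        for ii in itertools.combinations(range(m), k):
            # best pairing of these a-columns over all b-column choices
            for jj in itertools.combinations(range(n), k):
                score = 0
                for t in range(k):
                    score += substitution(a[ii[t]], b[jj[t]])
                    if t > 0:
                        ga = ii[t] - ii[t - 1] - 1
                        gb = jj[t] - jj[t - 1] - 1
                        if ga:
                            score -= gap_open + gap_extend * ga
                        if gb:
                            score -= gap_open + gap_extend * gb
                if score > best:
                    best = score
    return best


def regex_cleavage_sites(protein: str, search_from: int,
                         multibasic: bool = True,
                         monobasic: bool = False) -> list[tuple[int, int, int]]:
    """Regex enumeration of basic-run processing sites.

    Returns (run_start, run_end, tier) 1-based tuples for the region
    after ``search_from`` (a 1-based last-signal-residue position).
    """
    out = []
    for m in re.finditer(r"[KR]+", protein):
        start, end = m.start() + 1, m.end()
        if start <= search_from:
            continue
        following = protein[end] if end < len(protein) else None
        if following == "P":
            continue
        run_len = end - start + 1
        if run_len >= 2 and multibasic:
            out.append((start, end, 1))
        elif run_len == 1 and monobasic and following is not None:
            out.append((start, end, 2))
    return out


def split_orf_segments(protein_frame: str, min_len: int) -> list[str]:
    """Regex split-on-stop oracle for ORF extraction."""
    return [s for s in re.split(r"\*", protein_frame) if len(s) >= min_len]


def pooled_t_statistic(xs: list[float], ys: list[float]) -> tuple[float, float]:
    """Textbook pooled-variance two-sample t-test (two-sided p)."""
    import math

    from scipy.stats import t as tdist

    nx, ny = len(xs), len(ys)
    mx = sum(xs) / nx
    my = sum(ys) / ny
    ssx = sum((x - mx) ** 2 for x in xs)
    ssy = sum((y - my) ** 2 for y in ys)
    df = nx + ny - 2
    sp2 = (ssx + ssy) / df
    t = (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * tdist.sf(abs(t), df)
    return t, p
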