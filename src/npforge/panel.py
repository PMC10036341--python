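"""Expression-panel analysis: RPM, two-group comparison, Z-scores.

Normalizes a gene x sample count matrix to RPM (reads per million mapped
reads), compares expression between two sample groups per gene with a
two-sided Student's t-test (pooled variance; Welch optional), computes
fold changes and significance tiers, standardizes genes across samples
for heatmap display, and intersects regulated gene sets across two
independent comparisons (e.g. the female and male panels).

No multiple-testing correction is applied by default: the panel is a
small curated gene list scored at raw p < alpha, with Benjamini-Hochberg
available by flag.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a counts TSV: first column gene_id, header = sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_design_tsv(path) -> pd.DataFrame:
    """Read a design TSV with columns sample_id, group, sex."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index("sample_id", drop=False)


def validate_design(design: pd.DataFrame, samples) -> None:
    missing = set(samples) - set(design.index)
    if missing:
        raise ValueError(f"samples without a design entry: {sorted(missing)}")


def compute_rpm(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Reads-per-million normalization with a pseudocount.

    The pseudocount is added to every cell *before* scaling so that fold
    changes stay defined for genes with zero counts; each output column
    then sums to exactly 1e6.
    """
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    raw_sums = counts.sum(axis=0)
    zero = raw_sums[raw_sums <= 0]
    if len(zero):
        raise ValueError(f"zero-count sample columns: {list(zero.index)}")
    shifted = counts.astype(float) + pseudocount
    return shifted * 1e6 / shifted.sum(axis=0)


def compare_groups(rpm: pd.DataFrame, design: pd.DataFrame,
                   group_a: str, group_b: str, alpha: float = 0.05,
                   welch: bool = False, sex: str | None = None,
                   bh_correct: bool = False) -> pd.DataFrame:
    """Per-gene two-group comparison on RPM values.

    Returns a DataFrame indexed by gene with mean/SE per group, the
    t statistic, (two-sided) p-value, fold change B/A, a direction call
    (``up``/``down``/``ns`` at ``alpha``), and a significance label
    ("*" for p < 0.05, "**" for p < 0.01). Genes with zero variance in
    both groups and equal means get t = 0, p = 1.
    """
    sub = design
    if sex is not None:
        sub = sub[sub["sex"] == sex]
    samples_a = sub.index[sub["group"] == group_a]
    samples_b = sub.index[sub["group"] == group_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each compared group needs >= 2 samples")
    if set(samples_a) & set(samples_b):
        raise ValueError("groups must be disjoint")
    a = rpm[samples_a].values
    b = rpm[samples_b].values
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    # degenerate rows: no variance anywhere and identical means -> no evidence
    degenerate = np.isnan(t) & np.isclose(mean_a, mean_b)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    se_a = a.std(axis=1, ddof=1) / np.sqrt(a.shape[1])
    se_b = b.std(axis=1, ddof=1) / np.sqrt(b.shape[1])
    fold = mean_b / mean_a
    if bh_correct:
        p = _benjamini_hochberg(p)
    direction = np.where(p >= alpha, "ns", np.where(fold < 1.0, "down", "up"))
    stars = np.where(p < 0.01, "**", np.where(p < 0.05, "*", ""))
    out = pd.DataFrame({
        "mean_a": mean_a, "mean_b": mean_b, "se_a": se_a, "se_b": se_b,
        "t_stat": t, "p_value": p, "fold_change": fold,
        "direction": direction, "significance": stars,
    }, index=rpm.index)
    out.attrs["group_a"] = group_a
    out.attrs["group_b"] = group_b
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    n = len(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


def zscore_matrix(rpm: pd.DataFrame, gene_subset=None) -> pd.DataFrame:
    """Standardize each gene across samples: (x - mean) / sd.

    Genes with zero variance across samples are dropped with a log line.
    """
    sub = rpm if gene_subset is None else rpm.loc[list(gene_subset)]
    if sub.empty:
        raise ValueError("gene subset is empty")
    sd = sub.std(axis=1, ddof=1)
    constant = sd[sd == 0].index
    for gene in constant:
        logger.info("dropping constant gene %s from Z-score matrix", gene)
    sub = sub.drop(index=constant)
    sd = sd.drop(index=constant)
    return sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)


def intersect_regulated(cmp_a: pd.DataFrame, cmp_b: pd.DataFrame,
                        direction: str = "down", alpha: float = 0.05) -> list[str]:
    """Genes regulated in the stated direction at p < alpha in both panels.

    The two comparisons must cover the same gene universe. Used to find
    e.g. the precursors down-regulated in both female and male panels.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if set(cmp_a.index) != set(cmp_b.index):
        raise ValueError("comparisons cover different gene universes")
    cmp_b = cmp_b.loc[cmp_a.index]

    def hits(cmp: pd.DataFrame) -> pd.Series:
        sig = cmp["p_value"] < alpha
        if direction == "down":
            return sig & (cmp["fold_change"] < 1.0)
        return sig & (cmp["fold_change"] > 1.0)

    both = hits(cmp_a) & hits(cmp_b)
    return list(cmp_a.index[both])
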