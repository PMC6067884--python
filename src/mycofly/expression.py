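"""Expression-matrix analysis: TPM, filtering, clustering, ANOVA, enrichment.

Works on a transcripts x samples matrix of TPM values with per-sample
metadata (treatment: control / exposed / cadaver; timepoint in hours;
tissue; optional fungal-titer fraction).  The analysis path mirrors a
standard infection time-course workflow:

1.  TPM from raw counts and transcript lengths;
2.  expression filtering (at least ``min_tpm`` in at least
    ``min_samples`` samples, boundaries inclusive);
3.  log2(TPM + pseudocount) transform and per-transcript mean centering;
4.  complete-linkage hierarchical clustering by gene, with heatmap
    columns ordered by fungal titer;
5.  per-transcript one-way ANOVA between two pooled sample groups
    (typically 24-96 hr controls vs 24-96 hr exposed; cadavers are
    excluded because post-mortem RNA degradation confounds expression);
6.  Fisher-exact term enrichment with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_P_THRESHOLD = 1e-3


def tpm_from_counts(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from a count matrix and transcript lengths.

    Per sample: rate_t = count_t / length_t, TPM_t = 1e6 * rate_t / sum(rate).
    Columns with no counts stay all-zero; every other column sums to 1e6.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every transcript needs a positive length")
    rate = counts.div(lengths, axis=0)
    colsum = rate.sum(axis=0)
    return 1e6 * rate.div(colsum.where(colsum > 0, 1.0), axis=1)


def filter_min_expression(matrix: pd.DataFrame, min_tpm: float, min_samples: int) -> pd.DataFrame:
    """Keep transcripts with TPM >= min_tpm in >= min_samples samples (inclusive)."""
    if min_samples > matrix.shape[1]:
        raise ValueError("min_samples exceeds the number of samples")
    keep = (matrix >= min_tpm).sum(axis=1) >= min_samples
    return matrix.loc[keep]


def log_center(matrix: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """log2(TPM + pseudocount), centered on each transcript's mean.

    A positive pseudocount is required whenever the matrix contains
    zeros.  Every output row has mean zero.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (matrix.to_numpy() <= 0).any():
        raise ValueError("zeros present: a positive pseudocount is required")
    logged = np.log2(matrix + pseudocount)
    return logged.sub(logged.mean(axis=1), axis=0)


# ---------------------------------------------------------------------------
# complete-linkage hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Agglomerative merge tree over matrix rows.

    ``merges`` lists (node_a, node_b, height) in merge order; leaves are
    numbered 0..n-1 by input row order and the cluster formed by merge
    step s gets id n+s (the scipy linkage convention).  Complete linkage
    is monotone, so heights never decrease along the merge sequence.
    """

    merges: list[tuple[int, int, float]]
    n_leaves: int
    row_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a tree over n leaves has exactly n-1 merges")

    def _members(self) -> dict[int, list[int]]:
        members = {i: [i] for i in range(self.n_leaves)}
        for step, (a, b, _h) in enumerate(self.merges):
            members[self.n_leaves + step] = members[a] + members[b]
        return members

    @property
    def leaf_order(self) -> list[int]:
        """Left-to-right leaf ordering of the final dendrogram."""
        if self.n_leaves == 1:
            return [0]
        return self._members()[self.n_leaves + len(self.merges) - 1]

    def cut(self, n_clusters: int) -> pd.Series:
        """Flat cluster labels (0-based, by first appearance) at a k-cluster cut."""
        if not 1 <= n_clusters <= self.n_leaves:
            raise ValueError("n_clusters out of range")
        members = self._members()
        parent = list(range(self.n_leaves))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b, _h in self.merges[: self.n_leaves - n_clusters]:
            ra = find(members[a][0])
            rb = find(members[b][0])
            parent[rb] = ra
        labels: dict[int, int] = {}
        out = np.empty(self.n_leaves, dtype=int)
        for i in range(self.n_leaves):
            root = find(i)
            out[i] = labels.setdefault(root, len(labels))
        return pd.Series(out, index=self.row_ids, name="cluster")


def _pearson_centered_distance(values: np.ndarray) -> np.ndarray:
    corr = np.corrcoef(values)
    return squareform(1.0 - corr, checks=False)


def hcluster_complete(matrix: pd.DataFrame, distance: str = "euclidean") -> ClusterResult:
    """Complete-linkage agglomerative clustering of matrix rows.

    The inter-cluster distance is the maximum pairwise member distance.
    ``distance`` is ``euclidean`` or ``pearson_centered`` (1 - Pearson
    correlation of the rows).  Deterministic: among pairs at the minimal
    distance, the pair with the lexicographically smallest (node id,
    node id) merges first.
    """
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least 2 rows")
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("missing values are not allowed")
    if distance == "euclidean":
        from scipy.spatial.distance import pdist

        condensed = pdist(values)
    elif distance == "pearson_centered":
        condensed = _pearson_centered_distance(values)
    else:
        raise ValueError(f"unknown distance {distance!r}")

    dist = squareform(condensed)
    # active cluster id -> index row in `dist`; new clusters reuse slot of
    # the first merged member
    active: dict[int, int] = {i: i for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        best: tuple[float, int, int] | None = None
        ids = sorted(active)
        for ai, a in enumerate(ids):
            for b in ids[ai + 1:]:
                d = dist[active[a], active[b]]
                if best is None or (d, a, b) < best:
                    best = (d, a, b)
        d, a, b = best  # type: ignore[misc]
        ra, rb = active[a], active[b]
        # complete linkage: distance to the union is the max of the parts
        dist[ra, :] = np.maximum(dist[ra, :], dist[rb, :])
        dist[:, ra] = dist[ra, :]
        del active[a], active[b]
        active[n + step] = ra
        merges.append((a, b, float(d)))
    return ClusterResult(merges=merges, n_leaves=n, row_ids=list(matrix.index))


def order_samples_by_titer(meta: pd.DataFrame) -> list[int]:
    """Column permutation sorting samples by ascending titer fraction.

    Ties are broken by sample id, keeping the ordering fully
    deterministic.  Raises if any titer is missing.
    """
    if meta["titer_fraction"].isna().any():
        raise ValueError("titer_fraction missing for some samples")
    keyed = sorted(
        range(len(meta)),
        key=lambda i: (meta["titer_fraction"].iat[i], meta["sample_id"].iat[i]),
    )
    return keyed


# ---------------------------------------------------------------------------
# differential expression and enrichment
# ---------------------------------------------------------------------------

def select_samples(
    meta: pd.DataFrame,
    treatment: str | None = None,
    timepoints: Sequence[int] | None = None,
    tissue: str | None = None,
) -> list[str]:
    """Sample ids matching the given metadata filters."""
    mask = pd.Series(True, index=meta.index)
    if treatment is not None:
        mask &= meta["treatment"] == treatment
    if timepoints is not None:
        mask &= meta["timepoint_hr"].isin(list(timepoints))
    if tissue is not None:
        mask &= meta["tissue"] == tissue
    return meta.loc[mask, "sample_id"].tolist()


def anova_pooled(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-transcript one-way fixed-effects ANOVA between two pooled groups.

    With two groups this is the classical F test (equivalent to the
    squared two-sample equal-variance t statistic).  Returns a frame with
    F, p, the mean log2 ratio of group_a over group_b (with pseudocount),
    and a significance flag at ``p_threshold``.  Both groups need at
    least two samples, otherwise the within-group variance is undefined.
    """
    a = list(group_a)
    b = list(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples for ANOVA")
    if set(a) & set(b):
        raise ValueError("sample groups overlap")
    xa = matrix[a].to_numpy(dtype=float)
    xb = matrix[b].to_numpy(dtype=float)
    na, nb = xa.shape[1], xb.shape[1]
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    grand = (xa.sum(axis=1) + xb.sum(axis=1)) / (na + nb)
    ss_between = na * (mean_a - grand) ** 2 + nb * (mean_b - grand) ** 2
    ss_within = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    df_between, df_within = 1, na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_between) / (ss_within / df_within)
    f = np.where(ss_between == 0, 0.0, f)  # identical group means, incl. constant data
    p = stats.f.sf(f, df_between, df_within)
    with np.errstate(divide="ignore", invalid="ignore"):
        # TPM means are non-negative; arbitrary (e.g. centered) inputs may
        # produce undefined ratios, reported as NaN
        log_ratio = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    return pd.DataFrame(
        {
            "F": f,
            "p": p,
            "mean_log_ratio": log_ratio,
            "significant": p < p_threshold,
        },
        index=matrix.index,
    )


def fisher_enrichment(
    study: set[str],
    background: set[str],
    annotation: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Two-sided Fisher-exact term enrichment with BH FDR correction.

    For each term, the 2x2 table crosses study/background-only membership
    with in-term/out-of-term.  The two-sided p sums hypergeometric tables
    whose point probability does not exceed the observed table's.
    Adjustment is Benjamini-Hochberg over exactly the tested terms.
    """
    if not study:
        raise ValueError("study set is empty")
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    rest = background - study
    rows = []
    for term in sorted(annotation):
        genes = annotation[term] & background
        a = len(study & genes)
        b = len(study) - a
        c = len(rest & genes)
        d = len(rest) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({
            "term": term, "study_count": a, "background_count": a + c,
            "odds_ratio": odds, "p": p,
        })
    result = pd.DataFrame(rows)
    if len(result):
        result["p_adjusted"] = multipletests(result["p"], method="fdr_bh")[1]
    return result


def annotation_percentage(n_annotated: int, n_total: int, decimals: int = 1) -> float:
    """Percentage of transcripts with homology support, e.g. for a summary table.

    Rounded to the stated number of decimals, matching how such rates are
    reported (42.0 means 42.0%).
    """
    if not 0 <= n_annotated <= n_total:
        raise ValueError("need 0 <= n_annotated <= n_total")
    return round(100.0 * n_annotated / n_total, decimals)
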