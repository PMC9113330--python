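"""Held-out evaluation of a stability table.

Two complementary checks on an independent dataset:

* **rank-group comparison** — stable sites should show the smallest maximum
  absolute log2 fold-changes compared with size-matched mid-ranked and
  bottom-ranked sites and with all non-stable sites (one-sided Wilcoxon
  rank-sum tests).
* **clustering concordance** — samples clustered on the stable-site subset
  should *fail* to recover the known condition/time-point structure that
  clustering on all sites recovers, quantified by five partition-agreement
  metrics (ARI, FMI, NMI, purity, Jaccard).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .io import DatasetTable, SiteId
from .stability import StabilityResult


@dataclass(frozen=True)
class Partition:
    """An assignment of every sample to exactly one cluster."""

    labels: Mapping[str, object]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("partition must label at least one sample")

    @property
    def samples(self) -> frozenset[str]:
        return frozenset(self.labels)

    def to_array(self, order: Sequence[str]) -> np.ndarray:
        return np.asarray([self.labels[s] for s in order], dtype=object)


@dataclass(frozen=True)
class ConcordanceReport:
    """Agreement between a clustering and reference labels, five ways."""

    ari: float
    fmi: float
    nmi: float
    purity: float
    jaccard: float

    def as_dict(self) -> dict[str, float]:
        return {
            "ari": self.ari,
            "fmi": self.fmi,
            "nmi": self.nmi,
            "purity": self.purity,
            "jaccard": self.jaccard,
        }


def contingency_matrix(truth: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Contingency table of two label vectors: rows = truth classes,
    columns = predicted clusters."""
    _, t_inv = np.unique(truth, return_inverse=True)
    _, p_inv = np.unique(pred, return_inverse=True)
    cont = np.zeros((t_inv.max() + 1, p_inv.max() + 1), dtype=np.int64)
    np.add.at(cont, (t_inv, p_inv), 1)
    return cont


def concordance(clustering: Partition, truth: Partition) -> ConcordanceReport:
    """Score a clustering against reference labels with ARI, FMI, NMI
    (arithmetic-mean normalization), purity and pair-counting Jaccard.

    All five metrics are computed from the partition contingency table and
    are invariant to cluster relabeling. Over sample pairs: TP = pairs
    co-clustered in both partitions, FP = co-clustered only in the clustering,
    FN = co-clustered only in the truth; FMI = TP/sqrt((TP+FP)(TP+FN)),
    Jaccard = TP/(TP+FP+FN), and ARI is the chance-adjusted Rand index
    (RI - E[RI]) / (max RI - E[RI]).

    Degenerate conventions: when a normalizer vanishes the two partitions are
    necessarily identical (e.g. both all-singletons, both one cluster) and the
    metric is 1. Purity is 1 for the all-singleton clustering by construction
    (a documented caveat — purity is monotone under refinement).
    """
    if clustering.samples != truth.samples:
        missing = truth.samples ^ clustering.samples
        raise ValueError(f"sample mismatch between partitions: {sorted(missing)[:5]}")
    order = sorted(truth.samples)
    t = truth.to_array(order)
    c = clustering.to_array(order)
    n = t.size
    cont = contingency_matrix(t, c)
    a = cont.sum(axis=1)  # truth class sizes
    b = cont.sum(axis=0)  # cluster sizes

    tp = float((cont * (cont - 1) // 2).sum())
    pairs_truth = float((a * (a - 1) // 2).sum())  # TP + FN
    pairs_pred = float((b * (b - 1) // 2).sum())  # TP + FP
    total_pairs = n * (n - 1) / 2.0

    # adjusted Rand index
    expected = pairs_truth * pairs_pred / total_pairs if total_pairs > 0 else 0.0
    max_index = 0.5 * (pairs_truth + pairs_pred)
    ari = 1.0 if max_index == expected else (tp - expected) / (max_index - expected)

    # Fowlkes-Mallows
    if pairs_pred == 0 and pairs_truth == 0:
        fmi = 1.0  # both all-singletons, hence identical
    elif pairs_pred == 0 or pairs_truth == 0:
        fmi = 0.0
    else:
        fmi = tp / math.sqrt(pairs_pred * pairs_truth)

    fp = pairs_pred - tp
    fn = pairs_truth - tp
    jaccard = 1.0 if (tp + fp + fn) == 0 else tp / (tp + fp + fn)

    # NMI with arithmetic-mean normalization
    nz = cont > 0
    pij = cont[nz] / n
    outer = (a[:, None] * b[None, :])[nz] / (n * n)
    mi = float(np.sum(pij * np.log(pij / outer)))
    h_t = float(-np.sum((a[a > 0] / n) * np.log(a[a > 0] / n)))
    h_c = float(-np.sum((b[b > 0] / n) * np.log(b[b > 0] / n)))
    mean_h = 0.5 * (h_t + h_c)
    nmi = 1.0 if mean_h == 0 else mi / mean_h  # both single-cluster => identical

    purity = float(cont.max(axis=0).sum() / n)

    return ConcordanceReport(
        ari=float(np.clip(ari, -1.0, 1.0)),
        fmi=float(np.clip(fmi, 0.0, 1.0)),
        nmi=float(np.clip(nmi, 0.0, 1.0)),
        purity=purity,
        jaccard=float(np.clip(jaccard, 0.0, 1.0)),
    )


def rank_groups(
    results: Sequence[StabilityResult], n: int
) -> tuple[set[SiteId], set[SiteId], set[SiteId], set[SiteId]]:
    """Split sites into (SPS, mid-ranked, bottom-ranked, non-SPS) groups.

    Sites are ranked by combined p ascending (ties broken by site id for
    determinism). The mid group is the n-site window centered on the median
    rank: ranks floor((M - n)/2) + 1 .. + n; the bottom group is the last n
    ranks. SPS and non-SPS partition the whole table.
    """
    M = len(results)
    if n < 1:
        raise ValueError("n must be >= 1")
    if 3 * n > M:
        raise ValueError(f"n={n} too large for {M} ranked sites (need n <= M/3)")
    ranked = sorted(results, key=lambda r: (r.p_combined, str(r.site)))
    sps = {r.site for r in ranked if r.is_sps}
    non_sps = {r.site for r in ranked if not r.is_sps}
    start = (M - n) // 2
    mid = {r.site for r in ranked[start : start + n]}
    bottom = {r.site for r in ranked[M - n :]}
    return sps, mid, bottom, non_sps


@dataclass
class GroupComparison:
    """Per-group max-|log2FC| distributions and one-sided rank-sum p-values
    for the hypothesis that the SPS group shifts lower than each other group."""

    values: dict[str, np.ndarray]
    p_less: dict[str, float]

    @property
    def medians(self) -> dict[str, float]:
        return {g: float(np.median(v)) for g, v in self.values.items()}


def group_change_comparison(
    groups: tuple[set[SiteId], set[SiteId], set[SiteId], set[SiteId]],
    eval_dataset: DatasetTable,
    min_sites: int = 5,
) -> GroupComparison:
    """Compare per-group maximum absolute log2 fold-changes in a held-out
    dataset; Wilcoxon rank-sum (Mann-Whitney U), one-sided SPS < other."""
    names = ("sps", "mid", "bottom", "non_sps")
    maxabs = eval_dataset.data.abs().max(axis=1, skipna=True)
    present = set(eval_dataset.data.index)
    values: dict[str, np.ndarray] = {}
    for name, sites in zip(names, groups):
        overlap = sorted(sites & present, key=str)
        if len(overlap) < min_sites:
            raise ValueError(
                f"group {name!r} has only {len(overlap)} site(s) in the "
                f"evaluation dataset (need >= {min_sites})"
            )
        values[name] = maxabs.loc[overlap].to_numpy(dtype=float)
    p_less = {
        g: float(stats.mannwhitneyu(values["sps"], values[g], alternative="less").pvalue)
        for g in names[1:]
    }
    return GroupComparison(values=values, p_less=p_less)


def _masked_euclidean_condensed(X: np.ndarray) -> np.ndarray:
    """Condensed pairwise-complete Euclidean distances between the columns of
    X (sites x samples), each scaled by sqrt(total/observed dimensions)."""
    n_sites, n_samples = X.shape
    obs = ~np.isnan(X)
    out = []
    for i in range(n_samples):
        for j in range(i + 1, n_samples):
            mask = obs[:, i] & obs[:, j]
            m = int(mask.sum())
            if m == 0:
                raise ValueError(
                    f"samples {i} and {j} share no observed sites in the subset"
                )
            diff = X[mask, i] - X[mask, j]
            out.append(math.sqrt(float(diff @ diff) * (n_sites / m)))
    return np.asarray(out)


def subset_and_cluster(
    eval_dataset: DatasetTable,
    site_set: Iterable[SiteId],
    k: int,
    seed: int = 0,
    method: str = "average",
) -> Partition:
    """Subset the dataset's rows to ``site_set`` and cluster its samples.

    Average-linkage hierarchical clustering on pairwise-complete Euclidean
    distance (scaled by sqrt(total/observed) to keep distances comparable
    under missingness), cut into k clusters. Deterministic: the seed exists
    only for interface symmetry with stochastic steps.
    """
    sites = sorted(set(site_set) & set(eval_dataset.data.index), key=str)
    if len(sites) < 2:
        raise ValueError(
            f"only {len(sites)} site(s) of the subset present in the dataset (need >= 2)"
        )
    samples = eval_dataset.conditions
    if not (1 <= k <= len(samples)):
        raise ValueError(f"k={k} must be in [1, {len(samples)}]")
    X = eval_dataset.data.loc[sites].to_numpy(dtype=float)
    dist = _masked_euclidean_condensed(X)
    Z = linkage(dist, method=method)
    assignment = fcluster(Z, t=k, criterion="maxclust")
    return Partition(labels={s: int(a) for s, a in zip(samples, assignment)})


def principal_components(
    eval_dataset: DatasetTable, site_set: Iterable[SiteId] | None = None, n_components: int = 2
) -> np.ndarray:
    """Sample-space PCA scores for visualization (missing values mean-imputed
    per site; not part of any statistical result)."""
    df = eval_dataset.data
    if site_set is not None:
        sites = sorted(set(site_set) & set(df.index), key=str)
        df = df.loc[sites]
    X = df.to_numpy(dtype=float)
    row_means = np.nanmean(X, axis=1, keepdims=True)
    X = np.where(np.isnan(X), row_means, X)
    Xs = (X - X.mean(axis=1, keepdims=True)).T  # samples x sites
    U, S, Vt = np.linalg.svd(Xs - Xs.mean(axis=0), full_matrices=False)
    return U[:, :n_components] * S[:n_components]
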