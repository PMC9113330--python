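"""Per-site stability features computed across a dataset collection.

Two features summarize how stably a phosphosite is phosphorylated:

* **recurrence** (X1) — the number of datasets in which the site was
  identified at all; stably phosphorylated sites are expected to be seen
  nearly everywhere.
* **phosphorylation change** (X2) — within each dataset the maximum absolute
  log2 fold-change over all conditions, quantile-normalized across datasets
  to remove per-study scale differences, then averaged over the datasets in
  which the site was observed; stable sites barely move, so X2 is small.

Only sites identified in more than a configurable fraction (default 20%) of
datasets enter the X2 computation — rarely-seen sites carry too little
fold-change evidence to normalize meaningfully.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import Collection, DatasetTable, SiteId

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StabilityFeatures:
    """The (recurrence, phosphorylation change) feature pair for one site."""

    site: SiteId
    recurrence: int
    phospho_change: float
    n_contributing: int

    def __post_init__(self) -> None:
        if self.recurrence < 1:
            raise ValueError("recurrence must be >= 1")
        if self.n_contributing > self.recurrence:
            raise ValueError("n_contributing cannot exceed recurrence")
        if not (self.phospho_change >= 0):
            raise ValueError("phospho_change must be non-negative")


def compute_recurrence(collection: Collection) -> dict[SiteId, int]:
    """Count, for every site in the collection universe, the number of
    datasets in which it was identified."""
    if collection.n_datasets == 0:
        raise ValueError("collection is empty")
    counts: dict[SiteId, int] = {}
    for ds in collection.datasets:
        for site in ds.data.index:
            counts[site] = counts.get(site, 0) + 1
    return counts


def filter_by_recurrence(
    recurrence: Mapping[SiteId, int], n_datasets: int, fraction: float = 0.20
) -> set[SiteId]:
    """Sites identified in strictly more than ``fraction`` of the datasets.

    With 53 datasets and the default 20% this keeps recurrence >= 11
    (threshold 10.6, strict inequality).
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    threshold = fraction * n_datasets
    return {s for s, r in recurrence.items() if r > threshold}


def max_abs_log2fc(dataset: DatasetTable) -> dict[SiteId, float]:
    """Per site, the maximum absolute log2 fold-change over the non-missing
    conditions of one dataset."""
    series = dataset.data.abs().max(axis=1, skipna=True)
    return {site: float(v) for site, v in series.items()}


def _empirical_quantiles(sorted_values: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Evaluate the empirical quantile function of ``sorted_values`` (length n,
    defined at probability points (i - 0.5)/n) at ``probs`` by linear
    interpolation, clamped at the extremes."""
    n = sorted_values.size
    pts = (np.arange(1, n + 1) - 0.5) / n
    return np.interp(probs, pts, sorted_values)


def quantile_normalize(
    vectors: Sequence[Mapping[SiteId, float]],
    filtered_sites: set[SiteId] | frozenset[SiteId] | None = None,
) -> list[dict[SiteId, float]]:
    """Quantile-normalize per-dataset value maps to a common reference.

    The reference distribution is the pointwise mean of all datasets'
    empirical quantile functions evaluated on a grid of G probability points
    ((i - 0.5)/G for i = 1..G), where G is the largest dataset size. Each
    dataset's rank r of n is then mapped to the reference evaluated at
    (r - 0.5)/n by linear interpolation, which reduces to classical quantile
    normalization when all datasets have equal size. Tied values receive the
    mean of the reference values their rank range spans, so equal inputs stay
    equal.

    Datasets with fewer than 2 observed sites are dropped (with a warning)
    and contribute neither to the reference nor to the output.
    """
    restricted: list[tuple[int, list[SiteId], np.ndarray]] = []
    for idx, vec in enumerate(vectors):
        if filtered_sites is not None:
            items = [(s, v) for s, v in vec.items() if s in filtered_sites]
        else:
            items = list(vec.items())
        if len(items) < 2:
            logger.warning(
                "quantile_normalize: dropping dataset %d with %d observed filtered site(s)",
                idx,
                len(items),
            )
            continue
        sites = [s for s, _ in items]
        vals = np.asarray([v for _, v in items], dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite values in dataset {idx}")
        restricted.append((idx, sites, vals))

    if not restricted:
        return []

    grid_size = max(vals.size for _, _, vals in restricted)
    grid = (np.arange(1, grid_size + 1) - 0.5) / grid_size
    reference = np.mean(
        [_empirical_quantiles(np.sort(vals), grid) for _, _, vals in restricted], axis=0
    )

    out: list[dict[SiteId, float]] = []
    for _, sites, vals in restricted:
        n = vals.size
        # mapped value for each sorted rank 1..n
        rank_probs = (np.arange(1, n + 1) - 0.5) / n
        mapped_by_rank = np.interp(rank_probs, grid, reference)
        order = np.argsort(vals, kind="stable")
        sorted_vals = vals[order]
        mapped_sorted = np.empty(n)
        # average mapped values over ties so equal inputs map to equal outputs
        i = 0
        while i < n:
            j = i
            while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
                j += 1
            mapped_sorted[i : j + 1] = mapped_by_rank[i : j + 1].mean()
            i = j + 1
        mapped = np.empty(n)
        mapped[order] = mapped_sorted
        out.append({s: float(v) for s, v in zip(sites, mapped)})
    return out


def average_phospho_change(
    normalized: Sequence[Mapping[SiteId, float]],
    filtered_sites: set[SiteId] | frozenset[SiteId] | None = None,
) -> tuple[dict[SiteId, float], dict[SiteId, int]]:
    """Average normalized max-|log2FC| per site over the datasets in which the
    site was observed. Returns (mean per site, contributing-dataset count)."""
    sums: dict[SiteId, float] = {}
    counts: dict[SiteId, int] = {}
    for vec in normalized:
        for site, v in vec.items():
            if filtered_sites is not None and site not in filtered_sites:
                continue
            sums[site] = sums.get(site, 0.0) + v
            counts[site] = counts.get(site, 0) + 1
    means = {s: sums[s] / counts[s] for s in sums}
    return means, counts


def compute_features(
    collection: Collection, fraction: float = 0.20
) -> list[StabilityFeatures]:
    """Compute the (recurrence, phosphorylation change) feature pair for every
    site passing the recurrence filter.

    Pipeline order: recurrence → filter → per-dataset max |log2FC| →
    quantile normalization → average over observed datasets.
    """
    recurrence = compute_recurrence(collection)
    filtered = filter_by_recurrence(recurrence, collection.n_datasets, fraction)
    if not filtered:
        raise ValueError(
            f"no site passes the {fraction:.0%} recurrence filter over "
            f"{collection.n_datasets} datasets; use a smaller fraction"
        )
    per_dataset = [max_abs_log2fc(ds) for ds in collection.datasets]
    normalized = quantile_normalize(per_dataset, filtered)
    means, counts = average_phospho_change(normalized, filtered)
    dropped = filtered - set(means)
    if dropped:
        logger.warning(
            "%d filtered site(s) observed in no normalized dataset were excluded",
            len(dropped),
        )
    out = [
        StabilityFeatures(
            site=s,
            recurrence=recurrence[s],
            phospho_change=means[s],
            n_contributing=counts[s],
        )
        for s in sorted(means, key=str)
    ]
    return out
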