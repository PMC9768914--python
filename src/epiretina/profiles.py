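"""Peak-centered density profiles and shape-based k-means clustering.

Each peak contributes one row: extended-read counts in 100 bp bins across a
10 kb window centered on the peak midpoint, linearly scaled per row to a
maximum of 1 so clustering groups profile *shapes* (narrow spike vs broad
plateau) independent of peak height.  Cluster labels are renumbered so
breadth (number of mean-profile bins >= 0.25 of the profile max) increases
with the label: "cluster k" is always the broadest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .genome import ReadLibrary
from .peaks import PeakSet


@dataclass
class ProfileMatrix:
    peak_ids: list[str]
    values: np.ndarray  # rows scaled to max 1 (all-zero rows stay zero)
    bin_size: int
    half_window: int

    def __post_init__(self):
        if self.values.ndim != 2 or len(self.peak_ids) != self.values.shape[0]:
            raise ValueError("matrix shape does not match peak ids")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def linear_row_scale(raw: np.ndarray) -> np.ndarray:
    """Scale each row to max 1; all-zero rows are left zero. Idempotent."""
    raw = np.asarray(raw, dtype=float)
    row_max = raw.max(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(row_max > 0, raw / row_max, 0.0)
    return out


def build_profile_matrix(
    peaks: PeakSet,
    reads: ReadLibrary,
    chrom_sizes: Mapping[str, int],
    half_window: int = 5000,
    bin_size: int = 100,
    extend_to: int = 200,
) -> ProfileMatrix:
    """One row per peak: midpoint-binned extended-read counts over peak
    center +/- half_window, zero-filled past chromosome ends."""
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    ext = reads.extended(chrom_sizes, extend_to)
    chroms = ext.chrom.astype(str)
    mids_by_chrom = {
        c: np.sort((ext.start[chroms == c] + ext.end[chroms == c]) // 2)
        for c in np.unique(chroms)
    }
    n_bins = (2 * half_window) // bin_size
    rows = np.zeros((len(peaks), n_bins))
    ids = []
    for i, p in enumerate(peaks):
        ids.append(f"peak_{i + 1}")
        center = p.interval.midpoint
        w_start = center - half_window
        mids = mids_by_chrom.get(p.interval.chrom)
        if mids is None:
            continue
        edges = w_start + bin_size * np.arange(n_bins + 1)
        size = chrom_sizes.get(p.interval.chrom, edges[-1])
        lo = np.searchsorted(mids, np.maximum(edges[:-1], 0), side="left")
        hi = np.searchsorted(mids, np.minimum(edges[1:], size), side="left")
        counts = np.maximum(hi - lo, 0)
        valid = (edges[:-1] >= 0) & (edges[1:] <= size)
        rows[i] = np.where(valid, counts, 0)
    return ProfileMatrix(ids, linear_row_scale(rows), bin_size, half_window)


def profile_breadth(mean_profile: np.ndarray, rel_threshold: float = 0.25) -> int:
    """Number of bins at or above ``rel_threshold`` of the profile max."""
    m = mean_profile.max()
    if m <= 0:
        return 0
    return int(np.sum(mean_profile >= rel_threshold * m))


@dataclass
class ClusterAssignment:
    peak_ids: list[str]
    labels: np.ndarray  # 1..k, k = broadest mean profile
    mean_profiles: np.ndarray  # (k, n_bins), row i-1 = cluster i
    inertia: float

    @property
    def k(self) -> int:
        return self.mean_profiles.shape[0]

    def cluster_sizes(self) -> dict[int, int]:
        return {c: int(np.sum(self.labels == c)) for c in range(1, self.k + 1)}

    def members(self, cluster: int) -> list[str]:
        return [pid for pid, l in zip(self.peak_ids, self.labels) if l == cluster]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"peak_id": self.peak_ids, "cluster": self.labels})


def kmeans_profiles(
    matrix: ProfileMatrix, k: int = 10, seed: int = 0, n_init: int = 20
) -> ClusterAssignment:
    """Euclidean k-means (k-means++ init, ``n_init`` restarts, best inertia
    kept), deterministic for a fixed seed, labels renumbered by breadth."""
    n = matrix.values.shape[0]
    if n < k:
        raise ValueError(f"{n} profiles but k={k}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(matrix.values)
    means = np.vstack(
        [matrix.values[raw_labels == c].mean(axis=0) for c in range(k)]
    )
    order = sorted(
        range(k),
        key=lambda c: (profile_breadth(means[c]), int(np.sum(raw_labels == c)), c),
    )
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([relabel[c] for c in raw_labels])
    return ClusterAssignment(
        matrix.peak_ids, labels, means[order], float(km.inertia_)
    )


def cluster_summaries(
    assignment: ClusterAssignment,
    peak_genes: Mapping[str, str | None],
    expression_rpk: Mapping[str, float] | pd.Series | None = None,
    pi: Mapping[str, float] | pd.Series | None = None,
    broadness: Mapping[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Per-cluster medians of expression, pausing and broadness.

    ``peak_genes`` maps peak_id -> annotated gene (None allowed);
    ``broadness`` maps genotype -> per-gene broadness Series; the summary
    then reports the mutant/WT broadness change per cluster.
    """
    rows = []
    for c in range(1, assignment.k + 1):
        genes = sorted(
            {g for pid in assignment.members(c) if (g := peak_genes.get(pid))}
        )
        row: dict = {"cluster": c, "n_peaks": assignment.cluster_sizes()[c],
                     "n_genes": len(genes)}
        if expression_rpk is not None:
            vals = [expression_rpk[g] for g in genes if g in expression_rpk]
            row["median_rpk"] = float(np.median(vals)) if vals else float("nan")
        if pi is not None:
            vals = [pi[g] for g in genes if g in pi and np.isfinite(pi[g])]
            row["median_pi"] = float(np.median(vals)) if vals else float("nan")
        if broadness is not None:
            meds = {}
            for genotype, series in broadness.items():
                vals = [series[g] for g in genes if g in series.index]
                meds[genotype] = float(np.median(vals)) if vals else float("nan")
                row[f"median_broadness_{genotype}"] = meds[genotype]
            if {"WT"} < set(meds) and meds.get("WT", 0) > 0:
                other = next(g for g in meds if g != "WT")
                row["broadness_change"] = meds[other] / meds["WT"] - 1.0
        rows.append(row)
    return pd.DataFrame(rows)
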