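"""Per-cluster enrichment, superenhancer calling and intersection rules.

Gene-category enrichment per cluster is the classical urn model: observed =
|category ∩ cluster|, expected = |category ∩ universe| x |cluster| /
|universe|, with a hypergeometric upper tail for enrichment (ratio >= 1)
and lower tail for depletion.  Interval features (binding sites, motif
hits) use the same observed/expected ratio against the cluster-window
share, with a binomial tail since several features may fall in one window.

Superenhancers follow the ROSE recipe: TSS-proximal peaks removed, peaks
within the stitch distance merged, stitched regions ranked by
background-subtracted signal, and the hockey-stick cutoff placed where the
slope of the scaled rank/signal curve reaches 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    GenomeAnnotation,
    Interval,
    ReadIndex,
    annotate_to_nearest_tss,
    merge_interval_tuples,
    union_length_within,
)
from .peaks import Peak, PeakSet


@dataclass(frozen=True)
class EnrichmentResult:
    cluster: int | str
    n_observed: int
    n_expected: float
    ratio: float
    p: float
    direction: str  # "enrichment" (upper tail) or "depletion" (lower tail)


def hypergeometric_enrichment(
    category: Iterable[str],
    cluster_genes: Iterable[str],
    universe: Iterable[str],
    cluster: int | str = 0,
) -> EnrichmentResult:
    """Observed/expected ratio and hypergeometric tail p for one cluster.

    The category is intersected with the universe first; cluster genes must
    be a subset of the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    cluster_set = set(cluster_genes)
    if not cluster_set:
        raise ValueError("empty cluster")
    if not cluster_set <= universe:
        raise ValueError("cluster genes must be a subset of the universe")
    cat = set(category) & universe
    observed = len(cat & cluster_set)
    expected = len(cat) * len(cluster_set) / len(universe)
    ratio = observed / expected if expected > 0 else 0.0
    hg = stats.hypergeom(len(universe), len(cat), len(cluster_set))
    if ratio >= 1.0:
        p, direction = float(hg.sf(observed - 1)), "enrichment"
    else:
        p, direction = float(hg.cdf(observed)), "depletion"
    return EnrichmentResult(cluster, observed, expected, ratio, p, direction)


def category_enrichment_by_cluster(
    category: Iterable[str],
    cluster_map: Mapping[int, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    rows = [
        hypergeometric_enrichment(category, genes, universe, cluster=c).__dict__
        for c, genes in sorted(cluster_map.items())
    ]
    return pd.DataFrame(rows)


def assign_features_to_windows(
    features: Sequence[Interval],
    windows_by_cluster: Mapping[int, Sequence[Interval]],
) -> list[int | None]:
    """Cluster label per feature by midpoint membership in any cluster
    window; overlaps resolve to the nearest window center (tie: lower
    cluster label); None when no window contains the midpoint."""
    flat = [
        (w, c)
        for c in sorted(windows_by_cluster)
        for w in windows_by_cluster[c]
    ]
    out: list[int | None] = []
    for f in features:
        mid = f.midpoint
        best: tuple[int, int] | None = None
        for w, c in flat:
            if w.chrom == f.chrom and w.start <= mid < w.end:
                key = (abs(mid - w.midpoint), c)
                if best is None or key < best:
                    best = key
        out.append(best[1] if best else None)
    return out


def interval_feature_enrichment(
    features: Sequence[Interval],
    windows_by_cluster: Mapping[int, Sequence[Interval]],
) -> pd.DataFrame:
    """Observed/expected feature counts per cluster (expected proportional
    to cluster window counts) with a binomial tail p under the uniform
    null.  Features falling in no window are dropped from the universe."""
    assigned = assign_features_to_windows(features, windows_by_cluster)
    labels = [a for a in assigned if a is not None]
    n_total = len(labels)
    n_windows = {c: len(ws) for c, ws in windows_by_cluster.items()}
    total_windows = sum(n_windows.values())
    rows = []
    for c in sorted(windows_by_cluster):
        obs = sum(1 for a in labels if a == c)
        share = n_windows[c] / total_windows if total_windows else 0.0
        expected = n_total * share
        ratio = obs / expected if expected > 0 else 0.0
        if n_total == 0:
            p, direction = 1.0, "enrichment"
        elif ratio >= 1.0:
            p, direction = float(stats.binom.sf(obs - 1, n_total, share)), "enrichment"
        else:
            p, direction = float(stats.binom.cdf(obs, n_total, share)), "depletion"
        rows.append(EnrichmentResult(c, obs, expected, ratio, p, direction).__dict__)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Superenhancers


@dataclass
class SuperEnhancer:
    interval: Interval
    stitched_peak_ids: list[int]
    signal: float
    rank: int = 0
    is_super: bool = False


def rose_cutoff_index(signals_ascending: np.ndarray) -> int:
    """Hockey-stick cutoff on the ascending rank/signal curve.

    Both axes are scaled to [0, 1]; the cutoff is the tangency point where
    the (convex) curve's slope reaches 1, located as argmin(y - x).
    Regions with signal strictly above the cutoff signal are
    superenhancers; for a flat curve the argmin lands on the last point and
    nothing is super.
    """
    y = np.asarray(signals_ascending, dtype=float)
    n = len(y)
    if n < 2 or y.max() <= 0:
        return n - 1 if n else 0
    ys = y / y.max()
    xs = np.arange(n) / (n - 1)
    return int(np.argmin(ys - xs))


def call_superenhancers(
    peaks: PeakSet,
    chip: ReadIndex,
    control: ReadIndex | None,
    annotation: GenomeAnnotation,
    stitch: int = 12500,
    tss_exclusion: int = 2000,
) -> list[SuperEnhancer]:
    """ROSE-style superenhancer calling from (H3K27ac) peaks.

    Peaks fully inside TSS +/- ``tss_exclusion`` of any gene are removed;
    survivors within ``stitch`` bp are merged; each stitched region is
    scored by ChIP reads minus depth-scaled control reads (floored at 0);
    the hockey-stick cutoff flags the superenhancers.
    """
    tss_windows: dict[str, list[tuple[int, int]]] = {}
    for g in annotation:
        tss_windows.setdefault(g.chrom, []).append(
            (max(0, g.tss - tss_exclusion), g.tss + tss_exclusion)
        )
    kept: list[tuple[int, Peak]] = []
    for i, p in enumerate(peaks):
        iv = p.interval
        inside = any(
            s <= iv.start and iv.end <= e
            for s, e in tss_windows.get(iv.chrom, [])
        )
        if not inside:
            kept.append((i, p))
    kept.sort(key=lambda t: (t[1].interval.chrom, t[1].interval.start))

    stitched: list[SuperEnhancer] = []
    current: list[tuple[int, Peak]] = []

    def _flush():
        if not current:
            return
        chrom = current[0][1].interval.chrom
        s = min(p.interval.start for _, p in current)
        e = max(p.interval.end for _, p in current)
        region = Interval(chrom, s, e)
        n_chip = chip.count(region)
        bg = 0.0
        if control is not None and control.total > 0:
            bg = control.count(region) * (chip.total / control.total)
        stitched.append(
            SuperEnhancer(region, [i for i, _ in current], max(0.0, n_chip - bg))
        )

    for i, p in kept:
        if (
            current
            and p.interval.chrom == current[-1][1].interval.chrom
            and p.interval.start - current[-1][1].interval.end <= stitch
        ):
            current.append((i, p))
        else:
            _flush()
            current = [(i, p)]
    _flush()

    if len(stitched) < 3:
        if stitched:
            warnings.warn("fewer than 3 stitched regions; cutoff undefined, none super")
        for r, se in enumerate(sorted(stitched, key=lambda s: -s.signal)):
            se.rank = r + 1
        return stitched

    order = np.argsort([se.signal for se in stitched], kind="stable")
    signals_sorted = np.array([stitched[i].signal for i in order])
    cut = rose_cutoff_index(signals_sorted)
    cutoff_signal = signals_sorted[cut]
    for pos, i in enumerate(order):
        stitched[i].rank = len(stitched) - pos
        stitched[i].is_super = stitched[i].signal > cutoff_signal
    return stitched


def coverage_overlap_fraction(a: Interval, b_set: Iterable[Interval]) -> float:
    """Fraction of a's length covered by the union of b_set; the covered
    predicate of the intersection rule is fraction >= 0.5 (bedtools -f 0.5
    semantics)."""
    return union_length_within(a, list(b_set)) / a.length


def covered_at_least_half(a: Interval, b_set: Iterable[Interval]) -> bool:
    return coverage_overlap_fraction(a, b_set) >= 0.5


# ---------------------------------------------------------------------------
# Motif occurrences and direct targets


def motif_occurrence_summary(
    regions_by_cluster: Mapping[int | str, Sequence[Interval]],
    motif_hits: Mapping[str, Sequence[Interval]],
) -> pd.DataFrame:
    """Per cluster: fraction of regions with >= 1 hit of any motif, and the
    mean total hit count among hit-positive regions.  Hits are counted by
    >= 1 bp overlap."""
    rows = []
    for cluster, regions in sorted(regions_by_cluster.items(), key=lambda kv: str(kv[0])):
        if not regions:
            raise ValueError(f"cluster {cluster} has no regions")
        totals = []
        for r in regions:
            n = sum(
                1
                for hits in motif_hits.values()
                for h in hits
                if h.chrom == r.chrom and h.start < r.end and h.end > r.start
            )
            totals.append(n)
        totals = np.array(totals)
        with_hit = totals > 0
        frac = float(with_hit.mean())
        mean_cooc = float(totals[with_hit].mean()) if with_hit.any() else float("nan")
        rows.append(
            {
                "cluster": cluster,
                "n_regions": len(regions),
                "n_with_hit": int(with_hit.sum()),
                "fraction_with_hit": frac,
                "percent_with_hit": round(100.0 * frac),
                "mean_cooccurrence": mean_cooc,
            }
        )
    return pd.DataFrame(rows)


def genes_with_binding_site(
    binding_sites: Sequence[Interval], annotation: GenomeAnnotation
) -> set[str]:
    """Genes to which at least one binding site annotates (nearest TSS)."""
    if not binding_sites:
        return set()
    ann = annotate_to_nearest_tss(binding_sites, annotation)
    return set(ann["gene_id"].dropna())


def define_direct_targets(
    binding_sites: Sequence[Interval],
    ko_deregulated_genes: Iterable[str],
    annotation: GenomeAnnotation,
) -> set[str]:
    """Direct targets of a TF: genes with >= 1 annotated binding site whose
    expression changes in the TF knockout."""
    return genes_with_binding_site(binding_sites, annotation) & set(
        ko_deregulated_genes
    )


def two_factor_partition(targets_a: Iterable[str], targets_b: Iterable[str]) -> dict:
    """Three-way partition of two target gene sets (A-only / B-only /
    common) and their union size."""
    a, b = set(targets_a), set(targets_b)
    return {
        "a_only": len(a - b),
        "b_only": len(b - a),
        "common": len(a & b),
        "union": len(a | b),
    }
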