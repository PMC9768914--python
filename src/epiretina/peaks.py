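"""Enriched-region ("island") detection and peak statistics.

The detector is a deliberately simple window/gap island caller in the SICER
parameter family: the genome is tiled into fixed windows (default 200 bp),
each extended read is assigned to the window holding its midpoint, a window
is *eligible* when its count k satisfies P[Poisson(lambda) >= k] < p, and
eligible windows separated by at most the gap (default 600 bp) are merged
into one island spanning first to last eligible window.  lambda is the
uniform genome-wide expectation estimated from the control library scaled
to the ChIP library size (or from the ChIP library itself when no control
is given).  Externally called peak BEDs can be substituted anywhere a
PeakSet is consumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    GenomeAnnotation,
    Interval,
    ReadLibrary,
    annotate_to_nearest_tss,
)


@dataclass(frozen=True)
class Peak:
    interval: Interval
    score: float  # total reads in the island span
    mark: str = ""
    source: str = "island_caller"

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class PeakSet:
    peaks: list[Peak] = field(default_factory=list)
    mark: str = ""

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def intervals(self) -> list[Interval]:
        return [p.interval for p in self.peaks]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.interval.chrom for p in self.peaks],
                "start": [p.interval.start for p in self.peaks],
                "end": [p.interval.end for p in self.peaks],
                "name": [self.mark or p.mark or "peak" for p in self.peaks],
                "score": [p.score for p in self.peaks],
                "strand": [p.interval.strand for p in self.peaks],
            }
        )

    def write_bed(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path, mark: str = "", source: str = "external_bed") -> "PeakSet":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str},
        )
        peaks = [
            Peak(
                Interval(
                    r.chrom, int(r.start), int(r.end),
                    r.strand if r.strand in ("+", "-") else ".",
                ),
                float(r.score) if pd.notna(r.score) else 0.0,
                mark,
                source,
            )
            for r in df.itertuples()
        ]
        return cls(peaks, mark)


def poisson_eligibility_threshold(lam: float, p_threshold: float) -> int:
    """Smallest k with P[Poisson(lam) >= k] < p_threshold (k >= 1)."""
    k = max(1, int(stats.poisson.ppf(1.0 - p_threshold, lam)))
    while stats.poisson.sf(k - 1, lam) >= p_threshold:
        k += 1
    while k > 1 and stats.poisson.sf(k - 2, lam) < p_threshold:
        k -= 1
    return k


def _window_counts(
    library: ReadLibrary, chrom: str, n_bins: int, window: int
) -> np.ndarray:
    """Midpoint-assignment counts of (already extended) reads per window."""
    m = library.chrom.astype(str) == chrom
    mid = (library.start[m] + library.end[m]) // 2
    bins = np.clip(mid // window, 0, n_bins - 1)
    return np.bincount(bins, minlength=n_bins)


def call_islands(
    chip_reads: ReadLibrary,
    control_reads: ReadLibrary | None,
    chrom_sizes: Mapping[str, int],
    window: int = 200,
    gap: int = 600,
    p_threshold: float = 1e-2,
    mark: str = "",
    extend_to: int = 200,
    dedupe: bool = True,
) -> PeakSet:
    """Window/gap island calling against a uniform Poisson background.

    ``dedupe`` collapses identical read intervals first (redundancy
    threshold 1); pass False for keep-dup=all behaviour.
    """
    if len(chip_reads) == 0:
        raise ValueError("chip library is empty")
    if dedupe:
        chip_reads = chip_reads.deduplicated()
        if control_reads is not None and len(control_reads):
            control_reads = control_reads.deduplicated()
    chip = chip_reads.extended(chrom_sizes, extend_to)
    n_bins_total = sum(-(-size // window) for size in chrom_sizes.values())
    if control_reads is None or len(control_reads) == 0:
        if control_reads is not None:
            warnings.warn("control library empty; using ChIP-wide background")
        lam = len(chip) / n_bins_total
    else:
        # control-scaled expected count per window at ChIP depth
        lam = (len(control_reads) / n_bins_total) * (len(chip) / len(control_reads))
    kstar = poisson_eligibility_threshold(lam, p_threshold)
    gap_bins = gap // window

    peaks: list[Peak] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        n_bins = -(-size // window)
        counts = _window_counts(chip, chrom, n_bins, window)
        eligible = np.flatnonzero(counts >= kstar)
        if len(eligible) == 0:
            continue
        # merge runs of eligible windows separated by <= gap_bins windows
        breaks = np.flatnonzero(np.diff(eligible) - 1 > gap_bins)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(eligible) - 1]])
        for i0, i1 in zip(starts, ends):
            b0, b1 = int(eligible[i0]), int(eligible[i1])
            s = b0 * window
            e = min((b1 + 1) * window, size)
            score = float(counts[b0 : b1 + 1].sum())
            peaks.append(Peak(Interval(chrom, s, e), score, mark))
    return PeakSet(peaks, mark)


def broadness_by_gene(
    peaks: PeakSet,
    annotation: GenomeAnnotation,
    gene_set: Sequence[str] | None = None,
    per_peak: bool = False,
) -> pd.DataFrame:
    """Per-gene broadness: sum of lengths of peaks annotated (nearest TSS)
    to the gene.  ``per_peak=True`` returns the per-peak table instead."""
    if len(peaks) == 0:
        ann = pd.DataFrame(columns=["gene_id", "length"])
    else:
        ann = annotate_to_nearest_tss(peaks.intervals(), annotation)
        ann["length"] = ann["end"] - ann["start"]
    if per_peak:
        return ann
    sums = ann.groupby("gene_id")["length"].sum()
    ids = list(gene_set) if gene_set is not None else sorted(sums.index)
    rows = [
        {
            "gene_id": gid,
            "broadness": int(sums.get(gid, 0)),
            "has_peak": gid in sums.index,
        }
        for gid in ids
    ]
    return pd.DataFrame(rows, columns=["gene_id", "broadness", "has_peak"])


_FEATURE_ORDER = [
    "promoter_tss", "tts", "distal_promoter", "utr5", "utr3",
    "exon", "intron", "intergenic",
]


def _signed_offset(pos: int, anchor: int, strand: str) -> int:
    return pos - anchor if strand == "+" else anchor - pos


def classify_peak_position(mid: int, chrom: str, annotation: GenomeAnnotation) -> str:
    """Feature class of a peak midpoint with the declared precedence:
    promoter-TSS (-1 kb..+100) > TTS (-100..+1 kb) > distal promoter
    (-20 kb..-1 kb) > 5'UTR > 3'UTR > exon > intron > intergenic."""
    genes = [g for g in annotation.genes_on(chrom)]
    hits = {k: False for k in _FEATURE_ORDER}
    for g in genes:
        d_tss = _signed_offset(mid, g.tss, g.strand)
        d_tts = _signed_offset(mid, g.tts, g.strand)
        if -1000 <= d_tss <= 100:
            hits["promoter_tss"] = True
        if -100 <= d_tts <= 1000:
            hits["tts"] = True
        if -20000 <= d_tss < -1000:
            hits["distal_promoter"] = True
        if g.start <= mid < g.end:
            if any(s <= mid < e for s, e in g.utr5):
                hits["utr5"] = True
            elif any(s <= mid < e for s, e in g.utr3):
                hits["utr3"] = True
            elif any(s <= mid < e for s, e in g.exons):
                hits["exon"] = True
            else:
                hits["intron"] = True
    for k in _FEATURE_ORDER[:-1]:
        if hits[k]:
            return k
    return "intergenic"


def genomic_peak_distribution(
    peaks: PeakSet, annotation: GenomeAnnotation
) -> pd.DataFrame:
    """Percentage of peaks (by midpoint) per genomic feature class."""
    counts = {k: 0 for k in _FEATURE_ORDER}
    for p in peaks:
        counts[classify_peak_position(p.interval.midpoint, p.interval.chrom, annotation)] += 1
    n = max(1, len(peaks))
    return pd.DataFrame(
        {
            "feature": list(counts),
            "n_peaks": list(counts.values()),
            "percent": [100.0 * c / n for c in counts.values()],
        }
    )
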