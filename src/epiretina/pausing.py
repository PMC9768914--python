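"""RNAPII pausing index.

PI = 5' read density / gene-body density, with the 5' window spanning
TSS-30..TSS+300 (330 bp) and the body TSS+301..TTS-300, both strand-aware.
Densities enter as reads-per-Mb of the same library, so library size and
any normalization constant cancel: PI is a within-gene shape statistic.

Genes too short for a body window are skipped; genes with promoter signal
but zero body signal are reported as "fully paused" rather than given an
infinite index, and excluded from medians.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .density import mann_whitney_p, raw_density
from .genome import GeneModel, GenomeAnnotation, Interval, ReadIndex


@dataclass(frozen=True)
class PausingRecord:
    gene_id: str
    five_prime_density: float
    body_density: float
    pi: float  # nan when undefined
    defined: bool
    fully_paused: bool


def _pausing_windows(gene: GeneModel) -> tuple[Interval, Interval] | None:
    """(5' window, body window) for one gene, or None if the gene is too
    short (body requires TSS+301 < TTS-300 in transcription direction)."""
    if gene.strand == "+":
        f_s, f_e = gene.tss - 30, gene.tss + 300
        b_s, b_e = gene.tss + 301, gene.tts - 300
    else:
        f_s, f_e = gene.tss - 300, gene.tss + 30
        b_s, b_e = gene.tts + 300, gene.tss - 301
    if b_e - b_s < 1:
        return None
    return (
        Interval(gene.chrom, max(0, f_s), f_e),
        Interval(gene.chrom, b_s, b_e),
    )


def pausing_index(
    rnapii: ReadIndex, gene: GeneModel, total_reads: int | None = None
) -> PausingRecord | None:
    """PI for one gene from an indexed (extended) RNAPII library.

    Returns None when the gene is too short for the body window.
    """
    windows = _pausing_windows(gene)
    if windows is None:
        return None
    five, body = windows
    total = total_reads or rnapii.total
    d5 = raw_density(rnapii.count(five), five, total)
    db = raw_density(rnapii.count(body), body, total)
    if db > 0:
        return PausingRecord(gene.gene_id, d5, db, d5 / db, True, False)
    return PausingRecord(gene.gene_id, d5, db, float("nan"), False, d5 > 0)


def pausing_table(
    rnapii: ReadIndex,
    annotation: GenomeAnnotation,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """PI records for a gene set (default: all genes long enough)."""
    ids = gene_ids if gene_ids is not None else list(annotation.genes)
    rows = []
    for gid in ids:
        rec = pausing_index(rnapii, annotation[gid])
        if rec is not None:
            rows.append(rec.__dict__)
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "five_prime_density", "body_density", "pi",
            "defined", "fully_paused",
        ],
    )


def ratio_of_medians(
    group_a: Sequence[float], group_b: Sequence[float], decimals: int = 1
) -> dict:
    """median(a)/median(b), rounded, with a two-sided Mann-Whitney p."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_b == 0:
        raise ValueError("median of group_b is zero; ratio undefined")
    return {
        "median_a": med_a,
        "median_b": med_b,
        "ratio": round(med_a / med_b, decimals),
        "mannwhitney_p": mann_whitney_p(a, b),
    }


def pausing_by_deregulation_class(
    pi_table: pd.DataFrame,
    classes: Mapping[str, str],
    baseline: str = "non_deregulated",
    decimals: int = 1,
) -> pd.DataFrame:
    """WT-basal PI medians per deregulation stratum and ratios vs baseline.

    ``classes`` maps gene_id -> stratum label (e.g. non_deregulated,
    down_fc_lt_0.5, down_fc_lt_0.3).  The ratio reported is
    baseline-median / stratum-median (how much lower the stratum pauses).
    """
    t = pi_table[pi_table["defined"]].copy()
    t["stratum"] = t["gene_id"].map(classes)
    t = t.dropna(subset=["stratum"])
    base = t.loc[t["stratum"] == baseline, "pi"].to_numpy()
    rows = []
    for stratum, sub in t.groupby("stratum"):
        pis = sub["pi"].to_numpy()
        row = {
            "stratum": stratum,
            "n": len(pis),
            "median_pi": float(np.median(pis)) if len(pis) else float("nan"),
        }
        if stratum == baseline or len(base) == 0 or len(pis) == 0:
            row["ratio_vs_baseline"] = float("nan")
            row["mannwhitney_p"] = float("nan")
        else:
            stats = ratio_of_medians(base, pis, decimals)
            row["ratio_vs_baseline"] = stats["ratio"]
            row["mannwhitney_p"] = stats["mannwhitney_p"]
        rows.append(row)
    return pd.DataFrame(rows).sort_values("stratum").reset_index(drop=True)
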