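"""Normalized ChIP occupancy densities and genotype comparisons.

The density of a library over a region is

    density = (n / L_Mb) / (N x 1e-8)

with ``n`` the number of 200-bp-extended reads overlapping the region by at
least 1 bp, ``L_Mb`` the region length in megabases and ``N`` the library
size — i.e. reads per Mb scaled to a 10^8-read library.  The unit constant
cancels in every fold change and pausing index.

Wild-type densities are multiplied by the intergenic normalization factor
(the median mutant/WT density ratio over intergenic regions) so that the
genomic background matches between genotypes before promoters are compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    GenomeAnnotation,
    Interval,
    ReadIndex,
    ReadLibrary,
)

DENSITY_SCALE = 1e-8  # "per 10^8 library reads"


@dataclass(frozen=True)
class NormalizationFactor:
    """Median intergenic mutant/WT density ratio, applied to WT densities."""

    value: float
    n_intergenic_regions: int
    mark: str = ""

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("normalization factor must be positive")


def raw_density(n_reads: int, region: Interval, total_reads: int) -> float:
    """Density from a precomputed overlap count (see module docstring)."""
    if region.length <= 0:
        raise ValueError("zero-length region")
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    length_mb = region.length / 1e6
    return (n_reads / length_mb) / (total_reads * DENSITY_SCALE)


def library_density(
    index: ReadIndex, region: Interval, total_reads: int | None = None
) -> float:
    """Density of an indexed (already extended) library over a region."""
    n = index.count(region)
    return raw_density(n, region, total_reads or index.total)


def prepare_library(
    library: ReadLibrary,
    chrom_sizes: Mapping[str, int],
    extend_to: int = 200,
) -> ReadIndex:
    """Extend reads to 200 bp and index them; ``index.total`` is the library
    size used as N."""
    return ReadIndex(library.extended(chrom_sizes, extend_to))


def intergenic_normalization_factor(
    wt: ReadIndex,
    mut: ReadIndex,
    intergenic: Sequence[Interval],
    mark: str = "",
    min_regions: int = 20,
) -> NormalizationFactor:
    """Median over intergenic regions of mutant/WT density.

    Regions with zero WT reads are excluded (undefined ratio).  Requires at
    least ``min_regions`` usable regions.
    """
    fcs = []
    for region in intergenic:
        n_wt = wt.count(region)
        if n_wt == 0:
            continue
        n_mut = mut.count(region)
        d_wt = raw_density(n_wt, region, wt.total)
        d_mut = raw_density(n_mut, region, mut.total)
        fcs.append(d_mut / d_wt)
    if len(fcs) < min_regions:
        raise ValueError(
            f"only {len(fcs)} intergenic regions with nonzero WT density "
            f"(need >= {min_regions}); simulate a larger genome or relax the "
            "intergenic minimum length"
        )
    return NormalizationFactor(float(np.median(fcs)), len(fcs), mark)


def _gene_region(gene, mode: str, half_window: int) -> Interval | None:
    """Strand-aware analysis window for one gene; None if degenerate."""
    tss, tts = gene.tss, gene.tts
    if mode == "promoter_window":
        return Interval(gene.chrom, max(0, tss - half_window), tss + half_window)
    if mode == "tss_to_tts":
        return gene.span
    if mode == "tss301_to_tts":
        if gene.strand == "+":
            s, e = tss + 301, tts
        else:
            s, e = tts, tss - 301
        if e - s < 1:
            return None
        return Interval(gene.chrom, s, e)
    raise ValueError(f"unknown region mode {mode!r}")


def _density_table(
    libraries: Mapping[str, ReadIndex],
    annotation: GenomeAnnotation,
    mark: str,
    gene_ids: Sequence[str],
    mode: str,
    region_role: str,
    half_window: int,
    norm_factor: NormalizationFactor | None,
    wt_genotype: str,
) -> pd.DataFrame:
    rows = []
    for gid in gene_ids:
        gene = annotation[gid]
        region = _gene_region(gene, mode, half_window)
        if region is None:
            import warnings

            warnings.warn(f"gene {gid} too short for mode {mode}; skipped")
            continue
        for genotype, index in libraries.items():
            n = index.count(region)
            dens = raw_density(n, region, index.total)
            applied = 1.0
            if norm_factor is not None and genotype == wt_genotype:
                applied = norm_factor.value
                dens *= applied
            rows.append(
                {
                    "gene_id": gid,
                    "mark": mark,
                    "genotype": genotype,
                    "region_role": region_role,
                    "chrom": region.chrom,
                    "start": region.start,
                    "end": region.end,
                    "n_reads": n,
                    "length_mb": region.length / 1e6,
                    "total_reads": index.total,
                    "norm_factor_applied": applied,
                    "density": dens,
                }
            )
    return pd.DataFrame(rows)


def promoter_density_table(
    libraries: Mapping[str, ReadIndex],
    annotation: GenomeAnnotation,
    mark: str,
    gene_filter: Sequence[str],
    half_window: int = 300,
    norm_factor: NormalizationFactor | None = None,
    wt_genotype: str = "WT",
) -> pd.DataFrame:
    """Densities on the TSS window (TSS +/- ``half_window``) for the
    expressed-and-RNAPII-peaked gene set."""
    gene_ids = [g for g in gene_filter if g in annotation.genes]
    if not gene_ids:
        raise ValueError("gene_filter selected no genes")
    return _density_table(
        libraries, annotation, mark, gene_ids, "promoter_window",
        "promoter_window", half_window, norm_factor, wt_genotype,
    )


def genebody_density_table(
    libraries: Mapping[str, ReadIndex],
    annotation: GenomeAnnotation,
    mark: str,
    gene_filter: Sequence[str],
    mode: str = "tss_to_tts",
    norm_factor: NormalizationFactor | None = None,
    wt_genotype: str = "WT",
) -> pd.DataFrame:
    """Densities over the gene body, either TSS..TTS (H3K4me1) or
    TSS+301..TTS (RNAPII body)."""
    if mode not in ("tss_to_tts", "tss301_to_tts"):
        raise ValueError(f"unknown mode {mode!r}")
    gene_ids = [g for g in gene_filter if g in annotation.genes]
    if not gene_ids:
        raise ValueError("gene_filter selected no genes")
    return _density_table(
        libraries, annotation, mark, gene_ids, mode, "gene_body",
        0, norm_factor, wt_genotype,
    )


def mann_whitney_p(a: np.ndarray, b: np.ndarray, exact_max_n: int = 50) -> float:
    """Two-sided Mann-Whitney U p: exact enumeration for small tie-free
    samples, normal approximation with tie correction otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = len(np.unique(pooled)) == len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= exact_max_n and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def compare_conditions(
    table: pd.DataFrame, wt_genotype: str = "WT", mut_genotype: str | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-gene mutant/WT density fold change plus group summary.

    WT densities are expected to be already normalized in ``table``.  Genes
    with zero WT density have undefined FC: they are flagged and excluded
    from the median.  The summary carries the median FC and a two-sided
    Mann-Whitney p between the genotype density vectors.
    """
    genotypes = sorted(table["genotype"].unique())
    if wt_genotype not in genotypes or len(genotypes) < 2:
        raise ValueError("both genotypes must be present")
    if mut_genotype is None:
        mut_genotype = next(g for g in genotypes if g != wt_genotype)
    wide = table.pivot_table(
        index="gene_id", columns="genotype", values="density", aggfunc="first"
    )
    wt = wide[wt_genotype]
    mut = wide[mut_genotype]
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mut / wt
    per_gene = pd.DataFrame(
        {
            "gene_id": wide.index,
            "density_wt": wt.to_numpy(),
            "density_mut": mut.to_numpy(),
            "fc": np.where(wt.to_numpy() > 0, fc.to_numpy(), np.nan),
            "fc_defined": wt.to_numpy() > 0,
        }
    ).reset_index(drop=True)
    defined = per_gene.loc[per_gene["fc_defined"], "fc"]
    summary = {
        "median_fc": float(defined.median()) if len(defined) else float("nan"),
        "n_genes": int(len(per_gene)),
        "n_fc_defined": int(per_gene["fc_defined"].sum()),
        "mannwhitney_p": mann_whitney_p(mut.to_numpy(), wt.to_numpy()),
    }
    return per_gene, summary


def write_density_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
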