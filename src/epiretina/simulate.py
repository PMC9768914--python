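"""Synthetic two-genotype retina dataset with planted effect sizes.

The generator emulates the study design the pipeline targets: a wild-type
(WT) and a mutant genotype, four gene classes, and mark-specific ChIP
libraries plus stranded total RNA-seq.

Gene classes
    broad_identity      highly expressed identity genes carrying a broad
                        acetylation domain (gene body + 2 kb upstream),
                        low RNAPII pausing, an antisense eRNA, and
                        downregulation in the mutant.
    narrow_housekeeping expressed genes with a narrow TSS +/- 300 bp
                        acetylation peak and high pausing.
    other_expressed     like housekeeping but lower expression.
    silent              no expression, no acetylation domain.

Planted mutant/WT effect sizes (defaults): promoter density factors 0.26
(H3K9ac), 0.60 (H3K27ac), 0.61 (RNAPII) at downregulated promoters;
H3K4me1 1.09 on all expressed gene bodies; broad-domain shrinkage to 0.38
of the WT length keeping the TSS-proximal edge; pausing-index increase
1.3x; eRNA log2 fold change -1.2; mRNA mean factor 0.4 for the
downregulated class.  All randomness flows from ``SimConfig.seed``;
outputs are bit-identical for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .expression import write_count_table
from .genome import (
    GeneModel,
    GenomeAnnotation,
    Interval,
    ReadLibrary,
    write_bed_reads,
    write_gene_annotation,
)

MARKS = ("H3K9ac", "H3K27ac", "H3K4me1", "RNAPII", "input")
GENOTYPES = ("WT", "SCA7")
GENE_CLASSES = ("broad_identity", "narrow_housekeeping", "other_expressed", "silent")
EXPRESSED_CLASSES = ("broad_identity", "narrow_housekeeping", "other_expressed")


def _default_n_genes() -> dict:
    return {
        "broad_identity": 25,
        "narrow_housekeeping": 40,
        "other_expressed": 60,
        "silent": 40,
    }


def _default_density_factors() -> dict:
    return {"H3K9ac": 0.26, "H3K27ac": 0.60, "RNAPII": 0.61, "H3K4me1": 1.09}


def _default_factor_classes() -> dict:
    return {
        "H3K9ac": ("broad_identity",),
        "H3K27ac": ("broad_identity",),
        "RNAPII": ("broad_identity",),
        "H3K4me1": EXPRESSED_CLASSES,
    }


def _default_expression_means() -> dict:
    # mean RPK per class; broad/housekeeping = 8 (median comparison of
    # identity vs housekeeping genes), broad/other = 20
    return {
        "broad_identity": 100.0,
        "narrow_housekeeping": 12.5,
        "other_expressed": 5.0,
        "silent": 0.02,
    }


def _default_mutant_expression() -> dict:
    return {"broad_identity": 0.4}


def _default_pausing_levels() -> dict:
    return {"broad_identity": 5.0, "narrow_housekeeping": 11.5, "other_expressed": 11.5}


@dataclass
class SimConfig:
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: dict = field(default_factory=_default_n_genes)
    chip_reads_per_library: int = 150_000
    chip_enrichment_fold: float = 25.0
    promoter_density_factor: dict = field(default_factory=_default_density_factors)
    density_factor_classes: dict = field(default_factory=_default_factor_classes)
    broadness_factor: float = 0.38
    pausing_factor: float = 1.3
    erna_log2fc: float = -1.2
    erna_mean_reads: float = 200.0
    expression_mean_rpk: dict = field(default_factory=_default_expression_means)
    mutant_expression_factor: dict = field(default_factory=_default_mutant_expression)
    pausing_level: dict = field(default_factory=_default_pausing_levels)
    dispersion: float = 0.05
    chip_intensity_sigma: float = 0.4  # log2-normal spread of acetylation strength
    n_wt: int = 4
    n_mut: int = 3
    rna_background_fraction: float = 0.02
    min_gene_spacing: int = 20_000
    read_length: int = 50
    seed: int = 0

    def __post_init__(self):
        if any(n <= 0 for n in self.n_genes.values()):
            raise ValueError("gene counts must be positive")
        if self.chip_reads_per_library <= 0 or self.n_wt <= 0 or self.n_mut <= 0:
            raise ValueError("counts must be positive")
        for d in (self.promoter_density_factor,):
            if any(v <= 0 for v in d.values()):
                raise ValueError("density factors must be positive")
        if self.broadness_factor <= 0 or self.pausing_factor <= 0:
            raise ValueError("factors must be positive")
        if not 0 <= self.rna_background_fraction <= 1:
            raise ValueError("background fraction must be in [0, 1]")


@dataclass
class GeneTruth:
    gene_id: str
    gene_class: str
    chrom: str
    strand: str
    start: int
    end: int
    acet_domain: tuple | None  # WT H3K9ac/H3K27ac domain (start, end)
    erna: tuple | None  # (start, end, strand)
    mean_rpk_wt: float
    mean_rpk_mut: float
    pausing_wt: float
    length_kb: float = 0.0  # median transcript length in kb (RPK length)
    chip_intensity: float = 1.0  # per-locus acetylation strength (both genotypes)


@dataclass
class SimTruth:
    """Ground truth for recovery tests."""

    genes: dict[str, GeneTruth]
    config: SimConfig

    def gene_ids(self, gene_class: str | None = None) -> list[str]:
        return [
            g.gene_id
            for g in self.genes.values()
            if gene_class is None or g.gene_class == gene_class
        ]

    def mutant_acet_domain(self, gene_id: str) -> tuple | None:
        """Mutant acetylation domain: broad domains shrink to
        broadness_factor of their WT length keeping the TSS-proximal edge;
        narrow domains are unchanged."""
        g = self.genes[gene_id]
        if g.acet_domain is None:
            return None
        s, e = g.acet_domain
        if g.gene_class != "broad_identity":
            return (s, e)
        new_len = max(1, int(round(self.config.broadness_factor * (e - s))))
        if g.strand == "+":
            return (s, s + new_len)
        return (e - new_len, e)

    def to_json(self, path) -> None:
        payload = {
            "config": {
                k: (v if not isinstance(v, tuple) else list(v))
                for k, v in asdict(self.config).items()
            },
            "genes": {gid: asdict(g) for gid, g in self.genes.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _gene_length(rng: np.random.Generator, gene_class: str) -> int:
    if gene_class == "broad_identity":
        return int(rng.integers(12_000, 18_001))
    return int(rng.integers(4_000, 6_001))


def simulate_genome(config: SimConfig) -> tuple[GenomeAnnotation, SimTruth]:
    """Place non-overlapping genes with >= ``min_gene_spacing`` bp spacing
    and build the ground truth (domains, eRNAs, expression means)."""
    rng = np.random.default_rng([config.seed, 0])
    chrom_sizes = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)
    }
    specs = [
        (cls, i)
        for cls in GENE_CLASSES
        for i in range(config.n_genes.get(cls, 0))
    ]
    rng.shuffle(specs)

    genes: list[GeneModel] = []
    truths: dict[str, GeneTruth] = {}
    chrom_names = sorted(chrom_sizes)
    chrom_idx, cursor = 0, 5_000
    spacing = config.min_gene_spacing
    for cls, i in specs:
        length = _gene_length(rng, cls)
        jitter = int(rng.integers(0, 5_001))
        placed = False
        while chrom_idx < len(chrom_names):
            start = cursor + spacing + jitter
            end = start + length
            if end + spacing <= chrom_sizes[chrom_names[chrom_idx]]:
                placed = True
                break
            chrom_idx += 1
            cursor = 5_000
        if not placed:
            total_needed = sum(
                _gene_length_hint(c) + spacing for c, _ in specs
            )
            raise ValueError(
                f"genes do not fit: need roughly {total_needed} bp of genome"
            )
        chrom = chrom_names[chrom_idx]
        cursor = end
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"{cls}_{i + 1:03d}"
        tx_frac = rng.uniform(0.6, 0.9, size=2)
        tx_lengths = sorted(int(length * f) for f in tx_frac)
        genes.append(
            GeneModel(gid, chrom, strand, start, end, tx_lengths, "protein_coding")
        )

        if cls == "broad_identity":
            domain = (start - 2_000, end) if strand == "+" else (start, end + 2_000)
        elif cls == "silent":
            domain = None
        else:
            tss = start if strand == "+" else end
            domain = (tss - 300, tss + 300)

        erna = None
        if cls == "broad_identity":
            erna_len = int(rng.integers(6_000, 10_001))
            if strand == "+":
                erna = (start - 2_000, start - 2_000 + erna_len, "+")
            else:
                erna = (end + 2_000 - erna_len, end + 2_000, "-")

        mean_wt = config.expression_mean_rpk[cls] * float(
            2.0 ** rng.normal(0.0, 0.25)
        )
        mean_mut = mean_wt * config.mutant_expression_factor.get(cls, 1.0)
        truths[gid] = GeneTruth(
            gid, cls, chrom, strand, start, end, domain, erna,
            mean_wt, mean_mut, config.pausing_level.get(cls, 10.0),
            float(np.median(tx_lengths)) / 1000.0,
            float(2.0 ** rng.normal(0.0, config.chip_intensity_sigma)),
        )

    annotation = GenomeAnnotation(genes, chrom_sizes)
    return annotation, SimTruth(truths, config)


def _gene_length_hint(gene_class: str) -> int:
    return 15_000 if gene_class == "broad_identity" else 5_000


# ---------------------------------------------------------------------------
# ChIP read simulation


def _fragment_reads(
    rng: np.random.Generator,
    chrom: str,
    centers: np.ndarray,
    chrom_length: int,
    read_length: int,
    half_fragment: int = 100,
) -> tuple[np.ndarray, ...]:
    """Reads are the 5' ``read_length`` bp of 200 bp fragments centered at
    ``centers`` on a random strand; 200 bp extension reconstructs the
    fragment."""
    centers = np.clip(centers, half_fragment, chrom_length - half_fragment)
    strands = np.where(rng.random(len(centers)) < 0.5, "+", "-")
    start = np.where(
        strands == "+", centers - half_fragment, centers + half_fragment - read_length
    )
    end = start + read_length
    chroms = np.full(len(centers), chrom, dtype=object)
    return chroms, start.astype(np.int64), end.astype(np.int64), strands


def _effective_domain_factor(target: float, fold: float) -> float:
    """Domain-intensity factor that makes the MEASURED density ratio equal
    ``target``.

    The density readout reports enrichment plus uniform background; scaling
    the domain alone would recover (target*fold+1)/(fold+1) instead of
    target, so the planted factor is defined on the measured quantity and
    the intensity factor derived from it.
    """
    return max((target * (fold + 1.0) - 1.0) / fold, 0.01)


def _chip_components(
    truth: SimTruth, mark: str, genotype: str
) -> list[tuple[str, int, int, float]]:
    """(chrom, start, end, weight) enrichment components for one library."""
    config = truth.config
    fold = config.chip_enrichment_fold
    mutant = genotype != "WT"
    affected = set(config.density_factor_classes.get(mark, ()))
    comps: list[tuple[str, int, int, float]] = []
    for g in truth.genes.values():
        if mutant and g.gene_class in affected:
            factor = _effective_domain_factor(
                config.promoter_density_factor.get(mark, 1.0),
                fold * (g.chip_intensity if mark in ("H3K9ac", "H3K27ac") else 1.0),
            )
        else:
            factor = 1.0
        if mark in ("H3K9ac", "H3K27ac"):
            dom = (
                truth.mutant_acet_domain(g.gene_id)
                if mutant
                else truth.genes[g.gene_id].acet_domain
            )
            if dom is not None:
                s, e = dom
                comps.append(
                    (g.chrom, s, e, fold * factor * g.chip_intensity * (e - s))
                )
        elif mark == "H3K4me1":
            if g.gene_class in EXPRESSED_CLASSES:
                comps.append(
                    (g.chrom, g.start, g.end, fold * factor * (g.end - g.start))
                )
        elif mark == "RNAPII":
            if g.gene_class in EXPRESSED_CLASSES:
                comps.append(
                    (g.chrom, g.start, g.end, fold * factor * (g.end - g.start))
                )
                pi = g.pausing_wt * (config.pausing_factor if mutant else 1.0)
                tss = g.start if g.strand == "+" else g.end
                if g.strand == "+":
                    ps, pe = tss - 30, tss + 300
                else:
                    ps, pe = tss - 300, tss + 30
                comps.append((g.chrom, ps, pe, fold * factor * pi * (pe - ps)))
        elif mark == "input":
            pass
        else:
            raise ValueError(f"unknown mark {mark!r}")
    return comps


def simulate_chip_reads(
    truth: SimTruth, mark: str, genotype: str, config: SimConfig | None = None
) -> ReadLibrary:
    """One ChIP library: a uniform-background/enriched-domain mixture with
    exactly ``chip_reads_per_library`` reads."""
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}; expected one of {MARKS}")
    config = config or truth.config
    rng = np.random.default_rng(
        [config.seed, 1, MARKS.index(mark), GENOTYPES.index(genotype)]
    )
    chrom_sizes = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)
    }
    comps = [
        (chrom, 0, size, float(size)) for chrom, size in sorted(chrom_sizes.items())
    ]
    comps += _chip_components(truth, mark, genotype)
    weights = np.array([c[3] for c in comps])
    counts = rng.multinomial(config.chip_reads_per_library, weights / weights.sum())
    parts = []
    for (chrom, s, e, _), n in zip(comps, counts):
        if n == 0:
            continue
        centers = rng.integers(s, e, size=n)
        parts.append(
            ReadLibrary(
                *_fragment_reads(
                    rng, chrom, centers, chrom_sizes[chrom], config.read_length
                )
            )
        )
    library = ReadLibrary.concat(parts)
    assert len(library) == config.chip_reads_per_library
    return library


# ---------------------------------------------------------------------------
# RNA read simulation


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_rna_reads(
    truth: SimTruth, genotype: str, config: SimConfig | None = None
) -> tuple[list[ReadLibrary], pd.DataFrame]:
    """Stranded RNA reads per replicate plus the gene-level count table.

    Genic reads are placed within the gene span ANTISENSE to the gene (dUTP
    first-strand convention); eRNA reads go on the truth eRNA strand within
    the truth interval; a small uniform background is added.  Counts are
    negative binomial around the class means scaled by gene length.
    """
    config = config or truth.config
    n_reps = config.n_wt if genotype == "WT" else config.n_mut
    chrom_sizes = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)
    }
    gene_order = sorted(truth.genes)
    lengths_kb = {gid: truth.genes[gid].length_kb for gid in gene_order}
    counts = np.zeros((len(gene_order), n_reps), dtype=np.int64)
    libs: list[ReadLibrary] = []
    erna_factor = 2.0 ** config.erna_log2fc if genotype != "WT" else 1.0

    for rep in range(n_reps):
        rng = np.random.default_rng(
            [config.seed, 2, GENOTYPES.index(genotype), rep]
        )
        parts = []
        total_genic = 0
        for i, gid in enumerate(gene_order):
            g = truth.genes[gid]
            mean_rpk = g.mean_rpk_wt if genotype == "WT" else g.mean_rpk_mut
            mu = mean_rpk * lengths_kb[gid]
            k = int(_nb_draw(rng, np.array([mu]), config.dispersion)[0])
            counts[i, rep] = k
            total_genic += k
            if k > 0:
                starts = rng.integers(g.start, max(g.start + 1, g.end - config.read_length), size=k)
                strand = "-" if g.strand == "+" else "+"  # antisense
                parts.append(
                    ReadLibrary(
                        np.full(k, g.chrom, dtype=object),
                        starts.astype(np.int64),
                        (starts + config.read_length).astype(np.int64),
                        np.full(k, strand, dtype="U1"),
                    )
                )
            if g.erna is not None:
                ke = int(
                    _nb_draw(
                        rng,
                        np.array([config.erna_mean_reads * erna_factor]),
                        config.dispersion,
                    )[0]
                )
                if ke > 0:
                    es, ee, estrand = g.erna
                    estarts = rng.integers(
                        max(0, es), max(es + 1, ee - config.read_length), size=ke
                    )
                    parts.append(
                        ReadLibrary(
                            np.full(ke, g.chrom, dtype=object),
                            estarts.astype(np.int64),
                            (estarts + config.read_length).astype(np.int64),
                            np.full(ke, estrand, dtype="U1"),
                        )
                    )
        n_bg = int(rng.poisson(config.rna_background_fraction * max(1, total_genic)))
        if n_bg > 0:
            chrom_names = sorted(chrom_sizes)
            which = rng.integers(0, len(chrom_names), size=n_bg)
            for ci, chrom in enumerate(chrom_names):
                m = which == ci
                nb = int(m.sum())
                if nb == 0:
                    continue
                starts = rng.integers(
                    0, chrom_sizes[chrom] - config.read_length, size=nb
                )
                strands = np.where(rng.random(nb) < 0.5, "+", "-")
                parts.append(
                    ReadLibrary(
                        np.full(nb, chrom, dtype=object),
                        starts.astype(np.int64),
                        (starts + config.read_length).astype(np.int64),
                        strands.astype("U1"),
                    )
                )
        libs.append(ReadLibrary.concat(parts))

    cols = [f"{genotype}_{r + 1}" for r in range(n_reps)]
    table = pd.DataFrame(counts, index=gene_order, columns=cols)
    table.index.name = "gene_id"
    return libs, table


# ---------------------------------------------------------------------------
# Dataset bundle


@dataclass
class SimulatedDataset:
    config: SimConfig
    annotation: GenomeAnnotation
    truth: SimTruth
    chip: dict  # (mark, genotype) -> ReadLibrary
    rna: dict  # genotype -> list[ReadLibrary] per replicate
    counts: pd.DataFrame
    sample_genotypes: dict

    @property
    def wt_samples(self) -> list[str]:
        return [s for s, g in self.sample_genotypes.items() if g == "WT"]

    @property
    def mut_samples(self) -> list[str]:
        return [s for s, g in self.sample_genotypes.items() if g != "WT"]


def simulate_dataset(
    config: SimConfig,
    outdir: str | Path | None = None,
    marks: tuple = MARKS,
) -> SimulatedDataset:
    """Simulate the full dataset (and optionally write it as plain-text
    files: GTF, chrom sizes, BED reads per library, counts TSV, truth
    JSON)."""
    annotation, truth = simulate_genome(config)
    chip = {
        (mark, genotype): simulate_chip_reads(truth, mark, genotype, config)
        for mark in marks
        for genotype in GENOTYPES
    }
    rna = {}
    tables = []
    sample_genotypes = {}
    for genotype in GENOTYPES:
        libs, table = simulate_rna_reads(truth, genotype, config)
        rna[genotype] = libs
        tables.append(table)
        for col in table.columns:
            sample_genotypes[col] = genotype
    counts = pd.concat(tables, axis=1)

    ds = SimulatedDataset(
        config, annotation, truth, chip, rna, counts, sample_genotypes
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_annotation(annotation, outdir / "genome.gtf")
        with open(outdir / "chrom.sizes", "w") as fh:
            for chrom, size in sorted(annotation.chrom_sizes.items()):
                fh.write(f"{chrom}\t{size}\n")
        for (mark, genotype), lib in chip.items():
            write_bed_reads(lib, outdir / f"chip_{mark}_{genotype}.bed")
        for genotype, libs in rna.items():
            for i, lib in enumerate(libs):
                write_bed_reads(lib, outdir / f"rna_{genotype}_rep{i + 1}.bed")
        write_count_table(counts, sample_genotypes, outdir / "counts.tsv")
        truth.to_json(outdir / "truth.json")
    return ds
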