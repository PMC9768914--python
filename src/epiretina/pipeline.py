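"""End-to-end orchestration: simulate (or load) a dataset, run every stage,
write TSV outputs, a manifest and a plain-text report."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import density as density_mod
from . import erna as erna_mod
from . import expression as expr_mod
from . import pausing as pausing_mod
from .enrichment import (
    call_superenhancers,
    category_enrichment_by_cluster,
    covered_at_least_half,
)
from .genome import Interval, ReadLibrary, derive_intergenic_regions
from .peaks import PeakSet, broadness_by_gene, call_islands
from .profiles import build_profile_matrix, cluster_summaries, kmeans_profiles
from .simulate import GENOTYPES, SimConfig, SimulatedDataset, simulate_dataset


@dataclass
class RunConfig:
    """Pipeline parameters; defaults reproduce the simulated analysis."""

    seed: int = 0
    outdir: str = "epiretina_run"
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # overrides for SimConfig
    promoter_half_window: int = 300
    island_window: int = 200
    island_gap: int = 600
    island_p: float = 1e-2
    erna_p: float = 1e-4
    kmeans_k: int = 10
    stitch: int = 12_500
    tss_exclusion: int = 2_000
    intergenic_min_length: int = 1_000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)


STAGES = (
    "simulate", "expression", "peaks", "density", "pausing",
    "clusters", "enrichment", "erna", "report",
)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, dataset: SimulatedDataset | None = None) -> dict:
    """Execute every stage on a simulated dataset and return the manifest.

    Each stage's tables land under ``config.outdir``; any stage error
    aborts with the stage name in the exception.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": asdict(config), "stages": {}}
    stage = "simulate"
    try:
        if dataset is None:
            dataset = simulate_dataset(config.sim_config(), out / "simulated")
        ann = dataset.annotation
        chrom_sizes = ann.chrom_sizes
        manifest["stages"]["simulate"] = {
            "n_genes": len(ann),
            "n_chip_libraries": len(dataset.chip),
        }

        # ------------------------------------------------ expression
        stage = "expression"
        counts = dataset.counts
        factors = expr_mod.size_factors(counts)
        lengths = ann.gene_lengths_kb()
        rpk = expr_mod.rpk_table(counts, factors, lengths)
        expressed = expr_mod.expressed_genes(rpk, dataset.wt_samples)
        de = expr_mod.differential_expression(
            counts, dataset.wt_samples, dataset.mut_samples, factors
        )
        de.to_csv(out / "expression_de.tsv", sep="\t")
        rpk.to_csv(out / "expression_rpk.tsv", sep="\t")
        class_counts = de["class"].value_counts().to_dict()
        manifest["stages"]["expression"] = {
            "n_expressed": len(expressed),
            "n_down": int(class_counts.get("down", 0)),
            "n_up": int(class_counts.get("up", 0)),
            "p_value_mode": de.attrs["p_value_mode"],
        }

        # ------------------------------------------------ peaks
        stage = "peaks"
        peak_sets: dict[tuple[str, str], PeakSet] = {}
        for mark in ("H3K9ac", "H3K27ac", "RNAPII"):
            for genotype in GENOTYPES:
                ps = call_islands(
                    dataset.chip[(mark, genotype)],
                    dataset.chip[("input", genotype)],
                    chrom_sizes,
                    window=config.island_window,
                    gap=config.island_gap,
                    p_threshold=config.island_p,
                    mark=mark,
                )
                peak_sets[(mark, genotype)] = ps
                ps.write_bed(out / f"peaks_{mark}_{genotype}.bed")
        manifest["stages"]["peaks"] = {
            f"{m}_{g}": len(ps) for (m, g), ps in peak_sets.items()
        }

        # expressed genes with >= 1 annotated RNAPII peak
        rnapii_genes = set(
            broadness_by_gene(peak_sets[("RNAPII", "WT")], ann, per_peak=True)[
                "gene_id"
            ].dropna()
        )
        gene_filter = sorted(expressed & rnapii_genes)

        # ------------------------------------------------ densities
        stage = "density"
        intergenic = derive_intergenic_regions(ann, config.intergenic_min_length)
        indexes = {
            key: density_mod.prepare_library(lib, chrom_sizes)
            for key, lib in dataset.chip.items()
        }
        density_summaries = {}
        for mark, mode in (
            ("H3K9ac", "promoter"), ("H3K27ac", "promoter"),
            ("RNAPII", "promoter"), ("H3K4me1", "body"),
        ):
            nf = density_mod.intergenic_normalization_factor(
                indexes[(mark, "WT")], indexes[(mark, "SCA7")], intergenic, mark
            )
            libs = {g: indexes[(mark, g)] for g in GENOTYPES}
            if mode == "promoter":
                table = density_mod.promoter_density_table(
                    libs, ann, mark, gene_filter,
                    half_window=config.promoter_half_window, norm_factor=nf,
                )
            else:
                table = density_mod.genebody_density_table(
                    libs, ann, mark, gene_filter, mode="tss_to_tts", norm_factor=nf,
                )
            per_gene, summary = density_mod.compare_conditions(table)
            table.to_csv(out / f"density_{mark}.tsv", sep="\t", index=False)
            per_gene.to_csv(out / f"density_fc_{mark}.tsv", sep="\t", index=False)
            summary["norm_factor"] = nf.value
            density_summaries[mark] = summary
        (out / "normalization_factors.json").write_text(
            json.dumps(
                {m: s["norm_factor"] for m, s in density_summaries.items()}, indent=1
            )
        )
        manifest["stages"]["density"] = {
            m: {"median_fc": s["median_fc"], "norm_factor": s["norm_factor"]}
            for m, s in density_summaries.items()
        }

        # ------------------------------------------------ pausing
        stage = "pausing"
        pi_tables = {
            g: pausing_mod.pausing_table(indexes[("RNAPII", g)], ann, gene_filter)
            for g in GENOTYPES
        }
        for g, t in pi_tables.items():
            t.to_csv(out / f"pausing_{g}.tsv", sep="\t", index=False)
        wt_def = pi_tables["WT"][pi_tables["WT"]["defined"]]
        mut_def = pi_tables["SCA7"][pi_tables["SCA7"]["defined"]]
        pi_ratio = pausing_mod.ratio_of_medians(
            mut_def["pi"], wt_def["pi"], decimals=2
        )
        strata = {
            gid: ("down" if de.loc[gid, "class"] == "down" else "non_deregulated")
            for gid in wt_def["gene_id"]
            if gid in de.index
        }
        by_class = pausing_mod.pausing_by_deregulation_class(
            pi_tables["WT"], strata, baseline="non_deregulated"
        )
        by_class.to_csv(out / "pausing_by_class.tsv", sep="\t", index=False)
        manifest["stages"]["pausing"] = {
            "median_pi_wt": pi_ratio["median_b"],
            "median_pi_mut": pi_ratio["median_a"],
            "mut_over_wt": pi_ratio["ratio"],
        }

        # ------------------------------------------------ clusters
        stage = "clusters"
        wt_k9 = peak_sets[("H3K9ac", "WT")]
        k = min(config.kmeans_k, max(2, len(wt_k9)))
        matrix = build_profile_matrix(wt_k9, dataset.chip[("H3K9ac", "WT")], chrom_sizes)
        assignment = kmeans_profiles(matrix, k=k, seed=config.seed)
        assignment.to_dataframe().to_csv(out / "clusters.tsv", sep="\t", index=False)
        peak_ann = broadness_by_gene(wt_k9, ann, per_peak=True)
        peak_genes = {
            f"peak_{i + 1}": g
            for i, g in enumerate(peak_ann["gene_id"])
        }
        broadness = {
            g: broadness_by_gene(peak_sets[("H3K9ac", g)], ann)
            .set_index("gene_id")["broadness"]
            for g in GENOTYPES
        }
        mean_rpk = rpk[dataset.wt_samples].mean(axis=1)
        wt_pi = pi_tables["WT"].set_index("gene_id")["pi"]
        summaries = cluster_summaries(
            assignment, peak_genes, mean_rpk, wt_pi, broadness
        )
        summaries.to_csv(out / "cluster_summaries.tsv", sep="\t", index=False)
        manifest["stages"]["clusters"] = {
            "k": k, "sizes": assignment.cluster_sizes()
        }

        # ------------------------------------------------ enrichment + SE
        stage = "enrichment"
        truth = dataset.truth
        categories = {
            "photoreceptor_like": set(truth.gene_ids("broad_identity")),
            "housekeeping_like": set(truth.gene_ids("narrow_housekeeping")),
        }
        universe = {g for g in peak_genes.values() if g} & set(de.index)
        cluster_map = {
            c: {g for pid in assignment.members(c) if (g := peak_genes.get(pid))}
            & universe
            for c in range(1, assignment.k + 1)
        }
        cluster_map = {c: g for c, g in cluster_map.items() if g}
        enr_tables = []
        for name, cat in categories.items():
            t = category_enrichment_by_cluster(cat, cluster_map, universe)
            t.insert(0, "category", name)
            enr_tables.append(t)
        enr = pd.concat(enr_tables, ignore_index=True)
        enr.to_csv(out / "cluster_enrichment.tsv", sep="\t", index=False)

        ses = call_superenhancers(
            peak_sets[("H3K27ac", "WT")],
            indexes[("H3K27ac", "WT")],
            indexes[("input", "WT")],
            ann,
            stitch=config.stitch,
            tss_exclusion=config.tss_exclusion,
        )
        se_intervals = [s.interval for s in ses if s.is_super]
        with open(out / "superenhancers.bed", "w") as fh:
            for s in sorted(ses, key=lambda s: s.rank):
                fh.write(
                    f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}\t"
                    f"SE_rank{s.rank}|{'super' if s.is_super else 'typical'}\t"
                    f"{s.signal:.1f}\t.\n"
                )
        se_cover = {
            c: sum(
                covered_at_least_half(p, se_intervals)
                for pid in assignment.members(c)
                for p in [wt_k9.peaks[int(pid.split('_')[1]) - 1].interval]
            )
            for c in range(1, assignment.k + 1)
        }
        manifest["stages"]["enrichment"] = {
            "n_superenhancers": int(sum(s.is_super for s in ses)),
            "n_stitched": len(ses),
            "peaks_covered_by_se": se_cover,
        }

        # ------------------------------------------------ eRNA
        stage = "erna"
        filtered = {
            g: [
                erna_mod.filter_reads_for_erna(lib, ann)
                for lib in dataset.rna[g]
            ]
            for g in GENOTYPES
        }
        pooled_wt = ReadLibrary.concat(filtered["WT"])
        regions = erna_mod.detect_transcribed_regions(
            pooled_wt, chrom_sizes, p_threshold=config.erna_p
        )
        candidates = erna_mod.designate_ernas(
            regions, wt_k9, peak_sets[("H3K27ac", "WT")], ann,
            photoreceptor_genes=categories["photoreceptor_like"],
        )
        erna_mod.write_candidates_bed(candidates, out / "erna_candidates.bed")
        reads_by_sample = {}
        for g in GENOTYPES:
            for i, lib in enumerate(filtered[g]):
                reads_by_sample[f"{g}_{i + 1}"] = lib
        region_counts = erna_mod.count_reads_in_regions(candidates, reads_by_sample)
        report = erna_mod.erna_deregulation_report(
            candidates, region_counts,
            dataset.wt_samples, dataset.mut_samples,
            mrna_table=de, size_factors=factors,
        )
        report.to_csv(out / "erna_report.tsv", sep="\t", index=False)
        manifest["stages"]["erna"] = {
            "n_regions": len(regions),
            "n_erna": int(sum(c.is_erna for c in candidates)),
            "n_concordantly_down": int(report["concordantly_down"].sum()),
        }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc

    manifest["checksums"] = {
        p.name: _sha256(p)
        for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.bed"))
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def make_report(workspace: str | Path) -> str:
    """Assemble the plain-text headline report from a completed run."""
    out = Path(workspace)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        missing = [s for s in STAGES if not (out / "manifest.json").exists()]
        raise FileNotFoundError(
            f"incomplete workspace {out}: missing stages {missing}"
        )
    m = json.loads(manifest_path.read_text())
    s = m["stages"]
    lines = ["# epiretina run report", ""]
    lines += [
        "## Deregulation classes",
        f"expressed: {s['expression']['n_expressed']}  "
        f"down: {s['expression']['n_down']}  up: {s['expression']['n_up']}",
        "",
        "## Density median fold changes (mutant/WT)",
    ]
    for mark, d in s["density"].items():
        lines.append(
            f"{mark}: median FC {d['median_fc']:.3f} (norm factor {d['norm_factor']:.3f})"
        )
    lines += [
        "",
        "## RNAPII pausing",
        f"median PI WT {s['pausing']['median_pi_wt']:.2f}, "
        f"mutant {s['pausing']['median_pi_mut']:.2f}, "
        f"ratio {s['pausing']['mut_over_wt']:.2f}",
        "",
        "## Profile clusters",
        f"k = {s['clusters']['k']}, sizes {s['clusters']['sizes']}",
        "",
        "## Superenhancers",
        f"{s['enrichment']['n_superenhancers']} super / "
        f"{s['enrichment']['n_stitched']} stitched regions",
        "",
        "## Cluster enrichment",
        f"peaks >=50% covered by SEs per cluster: "
        f"{s['enrichment']['peaks_covered_by_se']}",
        "",
        "## eRNAs",
        f"transcribed regions: {s['erna']['n_regions']}, "
        f"designated eRNAs: {s['erna']['n_erna']}, "
        f"concordantly down: {s['erna']['n_concordantly_down']}",
        "",
    ]
    text = "\n".join(lines)
    (out / "report.txt").write_text(text)
    return text
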