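"""End-to-end orchestration: simulate -> filter -> scan -> annotate ->
report, with a reproducibility manifest (seed, parameter hash, per-file
checksums)."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .afmap import CandidateRegion, ScanParams, detect_candidate_regions, plot_af_tracks, region_snp_report, smooth_track, build_af_tracks
from .annotation import annotate_variants, annotations_to_table, nonsynonymous_summary
from .config import SimConfig
from .cross import make_pools, simulate_cross
from .filtering import FilterParams, FilterResult, apply_filters, mask_repeats, observations_to_variants
from .genes import make_gene_models
from .genome import make_genome
from .mutagenesis import mutagenize
from .sequencing import sample_pooled_reads
from .studyio import read_pool_vcf, read_wt_sites, write_study

log = logging.getLogger("bsamap")

ALL_STAGES = ("simulate", "filter", "scan", "annotate")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    outdir: str = "bsamap_run"
    stages: tuple[str, ...] = ALL_STAGES
    filter_params: FilterParams = field(default_factory=FilterParams)
    scan_params: ScanParams = field(default_factory=ScanParams)
    promoter_bp: int = 1_000
    write_plots: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")


@dataclass
class RunResult:
    manifest: dict
    paths: dict[str, str]
    regions: list[CandidateRegion]
    region_summary: dict | None
    effect_summary: dict | None
    filter_result: FilterResult | None

    @property
    def top_region(self) -> CandidateRegion | None:
        return self.regions[0] if self.regions else None


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(rc: RunConfig) -> RunResult:
    """Execute the enabled stages in order on one simulated study.

    The default full run writes the study files, filters the pooled VCF,
    scans for candidate regions, annotates the top region's SNPs and reports
    the genes with nonsynonymous changes — ending at a candidate list that
    names the planted causal gene. When the filter stage is disabled the scan
    consumes raw variants and the manifest flags the nonstandard path.
    """
    outdir = Path(rc.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "bsamap",
        "version": __version__,
        "seed": rc.sim.seed,
        "stages": list(rc.stages),
        "params_hash": hashlib.sha256(
            json.dumps(
                {
                    "sim": rc.sim.to_dict(),
                    "filter": vars(rc.filter_params) | {"mutant_pools": list(rc.filter_params.mutant_pools)},
                    "scan": vars(rc.scan_params) | {"mutant_pools": list(rc.scan_params.mutant_pools)},
                    "promoter_bp": rc.promoter_bp,
                },
                sort_keys=True, default=str,
            ).encode()
        ).hexdigest(),
        "stage_outputs": {},
        "counts": {},
    }
    paths: dict[str, str] = {}
    chrom_lengths = dict(zip(rc.sim.chrom_names, rc.sim.resolved_chrom_lengths()))

    genome = genes = truth = None
    variants = None
    filter_result = None
    regions: list[CandidateRegion] = []
    region_summary = effect_summary = None

    def record(stage, files):
        manifest["stage_outputs"][stage] = {
            str(p): _sha256(p) for p in files if Path(p).exists()
        }

    if "simulate" in rc.stages:
        try:
            log.info("simulate: seed=%s genome=%s chromosomes", rc.sim.seed, rc.sim.n_chromosomes)
            genome = make_genome(rc.sim)
            genes = make_gene_models(genome, rc.sim)
            truth = mutagenize(genome, rc.sim, genes)
            individuals = simulate_cross(truth, rc.sim)
            pools = make_pools(individuals, rc.sim)
            obs = sample_pooled_reads(truth, pools, rc.sim)
            paths.update(
                write_study(genome, genes, truth, obs, outdir, rc.sim, individuals, pools)
            )
            manifest["counts"]["simulated_variants"] = len(truth.variants)
            manifest["counts"]["population_size"] = len(individuals)
            record("simulate", paths.values())
        except Exception as e:  # noqa: BLE001
            raise StageError("simulate", e) from e

    if "filter" in rc.stages or "scan" in rc.stages:
        if "pool_vcf" not in paths:
            raise StageError("filter", FileNotFoundError("no pooled VCF available"))
        wt_sites = read_wt_sites(paths["wt_vcf"])
        variants = read_pool_vcf(paths["pool_vcf"], wt_sites)

    if "filter" in rc.stages:
        try:
            filter_result = apply_filters(variants, set(), rc.filter_params)
            audit = filter_result.audit_table()
            paths["filter_audit"] = str(outdir / "filter_audit.tsv")
            audit.to_csv(paths["filter_audit"], sep="\t", index=False)
            manifest["counts"]["variants_in"] = len(variants)
            manifest["counts"]["variants_kept"] = len(filter_result.kept)
            reasons = pd.Series([v.reason for v in filter_result.removed]).value_counts()
            manifest["counts"]["removed_by_reason"] = reasons.to_dict()
            log.info(
                "filter: %d in, %d kept, removed %s",
                len(variants), len(filter_result.kept),
                manifest["counts"]["removed_by_reason"],
            )
            variants = filter_result.kept
            record("filter", [paths["filter_audit"]])
        except Exception as e:  # noqa: BLE001
            raise StageError("filter", e) from e
    else:
        manifest["nonstandard_path"] = "scan consumed unfiltered variants"

    if "scan" in rc.stages:
        try:
            regions = detect_candidate_regions(variants, rc.scan_params, chrom_lengths)
            manifest["counts"]["candidate_regions"] = len(regions)
            # windows table for the mutant pools, all chromosomes
            win_rows = []
            for pool in rc.scan_params.mutant_pools + (rc.scan_params.nonmutant_pool,):
                for chrom, track in sorted(build_af_tracks(variants, pool).items()):
                    w = smooth_track(
                        track, rc.scan_params.window_bp, rc.scan_params.step_bp,
                        rc.scan_params.min_snps, chrom_lengths.get(chrom),
                    )
                    w.insert(0, "chrom", chrom)
                    w.insert(0, "pool", pool)
                    win_rows.append(w)
            paths["windows"] = str(outdir / "af_windows.tsv")
            pd.concat(win_rows, ignore_index=True).to_csv(paths["windows"], sep="\t", index=False)
            paths["regions_bed"] = str(outdir / "candidate_regions.bed")
            with open(paths["regions_bed"], "w") as fh:
                for i, r in enumerate(regions):
                    fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tregion{i + 1}\t{r.peak_af:.4f}\n")
            if rc.write_plots:
                for pool in rc.scan_params.mutant_pools:
                    plot_af_tracks(variants, pool, outdir / "plots", rc.scan_params, chrom_lengths)
            record("scan", [paths["windows"], paths["regions_bed"]])
            if regions:
                log.info("scan: top region %s:%d-%d (%d SNPs)",
                         regions[0].chrom, regions[0].start, regions[0].end, regions[0].n_snps)
        except Exception as e:  # noqa: BLE001
            raise StageError("scan", e) from e

    if "annotate" in rc.stages and regions:
        try:
            if genome is None or genes is None:
                raise RuntimeError("annotation needs the simulated genome in memory")
            top = regions[0]
            # repeat masking is applied only inside the candidate region
            masked = mask_repeats(
                top.snps, genome.repeats, (top.chrom, top.start - 1, top.end)
            )
            anns = annotate_variants(masked.kept, genes, genome, rc.promoter_bp)
            table = annotations_to_table(anns)
            paths["annotations"] = str(outdir / "region_annotations.tsv")
            table.to_csv(paths["annotations"], sep="\t", index=False)
            effect_summary = nonsynonymous_summary(anns)
            report_df, region_summary = region_snp_report(top, anns)
            region_summary["n_repeat_masked"] = len(masked.removed)
            paths["region_report"] = str(outdir / "region_report.tsv")
            report_df.to_csv(paths["region_report"], sep="\t", index=False)
            paths["effect_summary"] = str(outdir / "effect_summary.json")
            Path(paths["effect_summary"]).write_text(json.dumps(effect_summary, indent=1))
            manifest["counts"]["region_snps"] = region_summary["n_snps"]
            manifest["counts"]["nonsynonymous_genes"] = effect_summary["n_nonsynonymous_genes"]
            record("annotate", [paths["annotations"], paths["region_report"], paths["effect_summary"]])
        except Exception as e:  # noqa: BLE001
            raise StageError("annotate", e) from e

    paths["manifest"] = str(outdir / "manifest.json")
    Path(paths["manifest"]).write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return RunResult(
        manifest=manifest, paths=paths, regions=regions,
        region_summary=region_summary, effect_summary=effect_summary,
        filter_result=filter_result,
    )
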