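"""File I/O for a simulated (or real) study: reference FASTA, gene-model
GFF3, repeat BED, pooled multi-sample VCF, WT-parent VCF, phenotype TSV and
ground-truth JSON. Coordinates are 0-based half-open in memory and 1-based in
VCF/GFF3/BED output as those formats require (BED stays 0-based)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .config import POOL_NAMES, SimConfig
from .cross import Individual, Pool
from .filtering import PoolObservation, Variant
from .genes import GeneModel, write_gff3
from .genome import GenomeRef
from .mutagenesis import SimVariant, TruthSet

_WRAP = 60


def write_fasta(genome: GenomeRef, path) -> None:
    path = str(path)
    with open(path, "w") as fh:
        for chrom in genome.names:
            fh.write(f">{chrom}\n")
            seq = genome.sequence(chrom)
            for i in range(0, len(seq), _WRAP):
                fh.write(seq[i : i + _WRAP] + "\n")
    pysam.faidx(path)


def read_fasta(path, repeats_bed=None) -> GenomeRef:
    with pysam.FastaFile(str(path)) as fa:
        names = list(fa.references)
        seqs = {
            c: np.frombuffer(fa.fetch(c).upper().encode("ascii"), dtype=np.uint8).copy()
            for c in names
        }
    repeats = read_repeats_bed(repeats_bed) if repeats_bed else {}
    return GenomeRef(names=names, seqs=seqs, repeats=repeats)


def write_repeats_bed(genome: GenomeRef, path) -> None:
    with open(path, "w") as fh:
        for chrom in genome.names:
            for s, e in genome.repeats.get(chrom, []):
                fh.write(f"{chrom}\t{s}\t{e}\trepeat\n")


def read_repeats_bed(path) -> dict[str, list[tuple[int, int]]]:
    repeats: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e = line.split("\t")[:3]
            repeats.setdefault(chrom, []).append((int(s), int(e)))
    for v in repeats.values():
        v.sort()
    return repeats


def _vcf_header(chrom_lengths: dict[str, int], samples) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, L in chrom_lengths.items():
        header.contigs.add(chrom, length=int(L))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths for ref and alt")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    for s in samples:
        header.add_sample(s)
    return header


def _gt_from_af(depth: int, alt: int):
    if depth == 0:
        return (None, None)
    af = alt / depth
    if af >= 0.9:
        return (1, 1)
    if af > 0.1:
        return (0, 1)
    return (0, 0)


def write_pool_vcf(
    observations: pd.DataFrame, chrom_lengths: dict[str, int], path,
    pool_names=POOL_NAMES,
) -> None:
    """Multi-sample VCF from the tidy observation table (one sample per
    pool; per-sample DP, AD, GQ)."""
    header = _vcf_header(chrom_lengths, pool_names)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for (chrom, pos0), grp in observations.groupby(["chrom", "pos0"], sort=True):
            first = grp.iloc[0]
            rec = vf.new_record(
                contig=chrom, start=int(pos0), stop=int(pos0) + 1,
                alleles=(first.ref, first.alt_allele),
            )
            by_pool = {r.pool: r for r in grp.itertuples()}
            for pool in pool_names:
                r = by_pool.get(pool)
                sample = rec.samples[pool]
                if r is None or r.depth == 0:
                    sample["GT"] = (None, None)
                    sample["DP"] = 0 if r is not None else None
                    continue
                sample["GT"] = _gt_from_af(int(r.depth), int(r.alt_count))
                sample["DP"] = int(r.depth)
                sample["AD"] = (int(r.depth) - int(r.alt_count), int(r.alt_count))
                sample["GQ"] = int(r.gq)
            vf.write(rec)


def read_pool_vcf(path, wt_sites: set | None = None) -> list[Variant]:
    """Parse a multi-sample pooled VCF into Variant records (SNPs only;
    multi-allelic records are split into biallelic ones)."""
    wt_sites = wt_sites or set()
    variants = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or alt == "*":
                    continue
                pools = {}
                for s in samples:
                    sd = rec.samples[s]
                    dp = sd.get("DP") or 0
                    ad = sd.get("AD")
                    alt_n = int(ad[1]) if ad and ad[1] is not None else 0
                    gq = sd.get("GQ")
                    pools[s] = PoolObservation(
                        depth=int(dp), alt=min(alt_n, int(dp)), gq=int(gq or 0)
                    )
                variants.append(
                    Variant(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                        pools=pools,
                        in_wt=(rec.chrom, rec.pos, rec.ref, alt) in wt_sites
                        or (rec.chrom, rec.pos) in wt_sites,
                    )
                )
    return variants


def write_wt_vcf(truth: TruthSet, chrom_lengths: dict[str, int], path) -> None:
    """Sites-only VCF of the variants the WT parent shares against the
    reference."""
    header = _vcf_header(chrom_lengths, samples=())
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in truth.wt_variants:
            rec = vf.new_record(
                contig=v.chrom, start=v.pos0, stop=v.pos0 + 1, alleles=(v.ref, v.alt)
            )
            vf.write(rec)


def read_wt_sites(path) -> set[tuple]:
    sites = set()
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                sites.add((rec.chrom, rec.pos, rec.ref, alt))
    return sites


def write_phenotypes(individuals: list[Individual], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": i.id,
                "phenotype_class": i.phenotype_class,
                "delta13C": round(i.delta13c, 4),
            }
            for i in individuals
        ]
    ).to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_json(
    truth: TruthSet, config: SimConfig, path,
    pools: dict[str, Pool] | None = None,
) -> None:
    cv = truth.causal_variant
    payload = {
        "config": config.to_dict(),
        "causal_gene_id": truth.causal_gene_id,
        "causal_variant": {
            "chrom": cv.chrom, "pos": cv.pos, "ref": cv.ref, "alt": cv.alt,
        },
        "n_variants": len(truth.variants),
        "n_ems_variants": len(truth.ems_variants),
        "n_wt_variants": len(truth.wt_variants),
        "variants": [
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "ems_canonical": v.ems_canonical, "in_wt": v.in_wt, "causal": v.causal,
            }
            for v in truth.variants
        ],
    }
    if pools is not None:
        payload["pools"] = {
            name: {
                "members": [m.id for m in pool.members],
                "true_causal_af": pool.true_allele_fraction(cv.chrom, cv.pos0),
            }
            for name, pool in pools.items()
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path) -> TruthSet:
    payload = json.loads(Path(path).read_text())
    variants = [
        SimVariant(
            chrom=v["chrom"], pos0=v["pos"] - 1, ref=v["ref"], alt=v["alt"],
            ems_canonical=v["ems_canonical"], in_wt=v["in_wt"], causal=v["causal"],
        )
        for v in payload["variants"]
    ]
    return TruthSet(variants=variants, causal_gene_id=payload["causal_gene_id"])


STUDY_FILES = {
    "fasta": "reference.fasta",
    "gff3": "genes.gff3",
    "repeats": "repeats.bed",
    "pool_vcf": "pools.vcf",
    "wt_vcf": "wt.vcf",
    "phenotypes": "phenotypes.tsv",
    "truth": "truth.json",
}


def write_study(
    genome: GenomeRef,
    genes: list[GeneModel],
    truth: TruthSet,
    observations: pd.DataFrame,
    outdir,
    config: SimConfig,
    individuals: list[Individual] | None = None,
    pools: dict[str, Pool] | None = None,
) -> dict[str, str]:
    """Write the complete study to ``outdir``; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: str(outdir / v) for k, v in STUDY_FILES.items()}
    lengths = {c: genome.length(c) for c in genome.names}
    write_fasta(genome, paths["fasta"])
    write_gff3(genes, paths["gff3"])
    write_repeats_bed(genome, paths["repeats"])
    write_pool_vcf(observations, lengths, paths["pool_vcf"])
    write_wt_vcf(truth, lengths, paths["wt_vcf"])
    if individuals is not None:
        write_phenotypes(individuals, paths["phenotypes"])
    else:
        del paths["phenotypes"]
    write_truth_json(truth, config, paths["truth"], pools=pools)
    return paths
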