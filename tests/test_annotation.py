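from dataclasses import dataclass

import numpy as np
import pytest

from bsamap import GeneModel, annotate_variants, classify_context, codon_change
from bsamap.annotation import (
    CONTEXT_CDS, CONTEXT_INTERGENIC, CONTEXT_INTRON, CONTEXT_PROMOTER, CONTEXT_UTR,
    EFFECT_NONSYNONYMOUS, EFFECT_STOP_GAIN, EFFECT_SYNONYMOUS, AnnotationError,
    gene_boundary_overlap_count, nonsynonymous_summary,
)
from bsamap.genes import translate
from bsamap.genome import GenomeRef, revcomp


@dataclass
class Var:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str


def genome_from(seq: str, chrom="c"):
    return GenomeRef(
        names=[chrom],
        seqs={chrom: np.frombuffer(seq.encode(), dtype=np.uint8).copy()},
        repeats={},
    )


def plus_gene(coding: str, pad=2000, utr=100, chrom="c", gene_id="g1"):
    """A one-exon plus-strand gene embedded in random-free padding."""
    seq = "A" * pad + "T" * utr + coding + "T" * utr + "A" * pad
    genome = genome_from(seq, chrom)
    s = pad + utr
    gene = GeneModel(
        gene_id, chrom, "+", pad, pad + 2 * utr + len(coding),
        cds=[(s, s + len(coding))],
        utr5=[(pad, s)], utr3=[(s + len(coding), s + len(coding) + utr)],
    )
    return genome, gene


class TestClassifyContext:
    def setup_method(self):
        self.genome, self.gene = plus_gene("ATG" + "GCA" * 20 + "TAA")
        self.cds0 = self.gene.cds[0][0]

    def test_cds_with_owning_gene(self):
        ctx, gid = classify_context("c", self.cds0 + 5, [self.gene])
        assert (ctx, gid) == (CONTEXT_CDS, "g1")

    def test_utr_and_promoter(self):
        assert classify_context("c", 2050, [self.gene])[0] == CONTEXT_UTR
        # 500 bp upstream of the transcript start, 1 kb promoter window
        assert classify_context("c", 1500, [self.gene])[0] == CONTEXT_PROMOTER

    def test_intron_excluded_from_gene_boundary_count(self):
        g = GeneModel("gi", "c", "+", 100, 1000, cds=[(150, 300), (600, 900)])
        ctx, _ = classify_context("c", 400, [g])
        assert ctx == CONTEXT_INTRON
        anns = annotate_variants(
            [Var("c", 401, "A", "G")], [g],
            genome_from("A" * 2000),
        )
        assert gene_boundary_overlap_count(anns) == 0

    def test_intergenic_and_bounds(self):
        assert classify_context("c", 10, [self.gene])[0] == CONTEXT_INTERGENIC
        with pytest.raises(AnnotationError):
            classify_context("c", 10_000_000, [self.gene], chrom_lengths={"c": 5000})

    def test_precedence_cds_over_promoter(self):
        # a minus-strand gene downstream whose (long) promoter covers the
        # first gene's CDS: the CDS context must win
        other = GeneModel("g2", "c", "-", 100, 700, cds=[(100, 700)])
        pos = self.cds0 + 2
        promoter = other.promoter(10_000)
        assert promoter[0] <= pos < promoter[1]
        ctx, gid = classify_context("c", pos, [other, self.gene], promoter_bp=10_000)
        assert (ctx, gid) == (CONTEXT_CDS, "g1")


class TestCodonChange:
    def test_ala_to_thr(self):
        genome, gene = plus_gene("ATG" + "GCA" + "TAA")
        pos0 = gene.cds[0][0] + 3  # the G of GCA
        ann = codon_change("c", pos0, "G", "A", gene, genome)
        assert (ann.ref_codon, ann.alt_codon) == ("GCA", "ACA")
        assert ann.aa_change == "Ala>Thr"
        assert ann.effect == EFFECT_NONSYNONYMOUS

    def test_synonymous_leu(self):
        genome, gene = plus_gene("ATG" + "CTG" + "TAA")
        pos0 = gene.cds[0][0] + 3
        ann = codon_change("c", pos0, "C", "T", gene, genome)
        assert (ann.ref_codon, ann.alt_codon) == ("CTG", "TTG")
        assert ann.effect == EFFECT_SYNONYMOUS

    def test_stop_gain(self):
        genome, gene = plus_gene("ATG" + "TGG" + "TAA")
        pos0 = gene.cds[0][0] + 5  # third base of TGG
        ann = codon_change("c", pos0, "G", "A", gene, genome)
        assert ann.alt_codon == "TGA"
        assert ann.effect == EFFECT_STOP_GAIN

    def test_minus_strand_hand_translated(self):
        """Reference C>T on a minus-strand gene is a coding-strand G>A; the
        hand-translated codon change must match."""
        coding = "ATGGCATAA"  # Met-Ala-stop on the coding (minus) strand
        pad = 50
        genomic = revcomp(coding)
        seq = "A" * pad + genomic + "A" * pad
        genome = genome_from(seq)
        gene = GeneModel("gm", "c", "-", pad, pad + 9, cds=[(pad, pad + 9)])
        assert gene.coding_sequence(genome) == coding
        # coding offset 3 = the G of GCA; genomic position holds C
        genomic_pos = pad + (9 - 1 - 3)
        assert genome.base("c", genomic_pos) == "C"
        ann = codon_change("c", genomic_pos, "C", "T", gene, genome)
        assert (ann.ref_codon, ann.alt_codon) == ("GCA", "ACA")
        assert ann.aa_change == "Ala>Thr"

    def test_frame_inconsistency_names_gene(self):
        genome, gene = plus_gene("ATG" + "GCA" + "TAA")
        with pytest.raises(AnnotationError, match="g1"):
            codon_change("c", gene.cds[0][0], "T", "A", gene, genome)  # wrong ref


class TestFullCdsTranslationOracle:
    def test_effect_matches_full_translation(self, tiny_study):
        """For CDS variants across the simulated gene set, the single-codon
        effect call agrees with translating the entire CDS before and after
        substituting the base (both strands)."""
        genome, genes = tiny_study["genome"], tiny_study["genes"]
        rng = np.random.default_rng(8)
        checked = 0
        for gene in genes[:50]:
            span = [(s, e) for s, e in gene.cds]
            positions = [int(rng.integers(s, e)) for s, e in span for _ in range(3)]
            for pos0 in positions:
                ref = genome.base(gene.chrom, pos0)
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    ann = codon_change(gene.chrom, pos0, ref, alt, gene, genome)
                    before = translate(gene.coding_sequence(genome))
                    mutated = genome.copy()
                    mutated.set_bases(gene.chrom, pos0, alt)
                    after = translate(gene.coding_sequence(mutated))
                    diff = [i for i, (a, b) in enumerate(zip(before, after)) if a != b]
                    if ann.effect == EFFECT_SYNONYMOUS:
                        assert before == after
                    elif ann.effect == EFFECT_STOP_GAIN:
                        assert after[diff[0]] == "*" and before[diff[0]] != "*"
                    else:
                        assert len(diff) == 1 and after[diff[0]] != "*"
                    if diff:
                        assert diff[0] == ann.codon_index
                    checked += 1
        assert checked > 200

    def test_strand_symmetry(self):
        """Reverse-complementing the genome and mirroring the gene yields
        identical effect calls."""
        coding = "ATG" + "GCATGGCTGCCA" * 4 + "TAA"
        genome, gene = plus_gene(coding, pad=300, utr=50)
        L = genome.length("c")
        mirrored = GenomeRef(
            names=["c"],
            seqs={"c": np.frombuffer(revcomp(genome.sequence("c")).encode(), np.uint8).copy()},
            repeats={},
        )

        def mirror_ival(iv):
            s, e = iv
            return (L - e, L - s)

        mgene = GeneModel(
            gene.gene_id, "c", "-", L - gene.tx_end, L - gene.tx_start,
            cds=sorted(mirror_ival(iv) for iv in gene.cds),
            utr5=sorted(mirror_ival(iv) for iv in gene.utr5),
            utr3=sorted(mirror_ival(iv) for iv in gene.utr3),
        )
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        s, e = gene.cds[0]
        rng = np.random.default_rng(11)
        for pos0 in rng.integers(s, e, size=40):
            pos0 = int(pos0)
            ref = genome.base("c", pos0)
            for alt in "ACGT":
                if alt == ref:
                    continue
                a = codon_change("c", pos0, ref, alt, gene, genome)
                b = codon_change("c", L - 1 - pos0, comp[ref], comp[alt], mgene, mirrored)
                assert (a.effect, a.ref_codon, a.alt_codon, a.codon_index) == (
                    b.effect, b.ref_codon, b.alt_codon, b.codon_index,
                )


class TestSummary:
    def _ann(self, gene_id, effect):
        from bsamap.annotation import EffectAnnotation

        return EffectAnnotation(
            chrom="c", pos=1, ref="G", alt="A", gene_id=gene_id,
            context=CONTEXT_CDS, effect=effect,
        )

    def test_nine_planted_nonsynonymous_genes(self):
        anns = [self._ann(f"Gene{i}", EFFECT_NONSYNONYMOUS) for i in range(9)]
        anns += [self._ann("GeneS", EFFECT_SYNONYMOUS)] * 4
        s = nonsynonymous_summary(anns)
        assert s["n_nonsynonymous_genes"] == 9
        assert s["counts"][EFFECT_NONSYNONYMOUS] == 9

    def test_all_synonymous_zero_genes(self):
        anns = [self._ann("g", EFFECT_SYNONYMOUS)] * 3
        assert nonsynonymous_summary(anns)["n_nonsynonymous_genes"] == 0

    def test_empty_input(self):
        s = nonsynonymous_summary([])
        assert s["n_nonsynonymous_genes"] == 0
        assert all(v == 0 for v in s["counts"].values())

    def test_causal_variant_annotated_nonsynonymous_end_to_end(self, desk_run):
        rc, res = desk_run
        import json
        truth = json.load(open(res.paths["truth"]))
        causal_gene = truth["causal_gene_id"]
        assert causal_gene in res.effect_summary["nonsynonymous_genes"]
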