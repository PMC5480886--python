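"""SNP effect annotation against single-transcript gene models.

Classifies each variant's positional context (CDS / UTR / core promoter /
intron / intergenic) and, for CDS variants, calls the codon change with the
standard genetic code — the step that separates candidate mutations causing
amino-acid changes or stop gains from silent ones.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from Bio.Seq import Seq

from .genes import GeneModel
from .genome import GenomeRef

CONTEXT_CDS = "CDS"
CONTEXT_UTR = "UTR"
CONTEXT_PROMOTER = "core_promoter"
CONTEXT_INTRON = "intron"
CONTEXT_INTERGENIC = "intergenic"

#: precedence when features of different genes overlap a position
_PRECEDENCE = {
    CONTEXT_CDS: 0,
    CONTEXT_UTR: 1,
    CONTEXT_PROMOTER: 2,
    CONTEXT_INTRON: 3,
    CONTEXT_INTERGENIC: 4,
}

EFFECT_SYNONYMOUS = "synonymous"
EFFECT_NONSYNONYMOUS = "nonsynonymous"
EFFECT_STOP_GAIN = "stop_gain"
EFFECT_NONCODING = "noncoding"

#: contexts counted as "overlapping gene boundaries" (introns excluded)
GENE_BOUNDARY_CONTEXTS = frozenset({CONTEXT_CDS, CONTEXT_UTR, CONTEXT_PROMOTER})

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "*",
}


@dataclass
class EffectAnnotation:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene_id: str | None
    context: str
    codon_index: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_residue: str | None = None
    alt_residue: str | None = None
    effect: str = EFFECT_NONCODING

    @property
    def aa_change(self) -> str | None:
        """Three-letter amino-acid change, e.g. ``Ala>Thr``."""
        if self.ref_residue is None:
            return None
        return f"{AA3[self.ref_residue]}>{AA3[self.alt_residue]}"


class AnnotationError(ValueError):
    pass


def classify_context(
    chrom: str,
    pos0: int,
    gene_models: list[GeneModel],
    promoter_bp: int = 1000,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[str, str | None]:
    """Positional context of a variant, with precedence
    CDS > UTR > core promoter > intron > intergenic when genes overlap.

    Returns ``(context, gene_id)``; gene_id is ``None`` for intergenic.
    """
    if pos0 < 0 or (
        chrom_lengths is not None and (chrom not in chrom_lengths or pos0 >= chrom_lengths[chrom])
    ):
        raise AnnotationError(f"position {chrom}:{pos0 + 1} beyond chromosome bounds")
    best = (CONTEXT_INTERGENIC, None)
    for g in gene_models:
        if g.chrom != chrom:
            continue
        ctx = None
        if g.contains(pos0):
            if g.in_cds(pos0):
                ctx = CONTEXT_CDS
            elif g.in_utr(pos0):
                ctx = CONTEXT_UTR
            else:
                ctx = CONTEXT_INTRON
        else:
            ps, pe = g.promoter(promoter_bp)
            if ps <= pos0 < pe:
                ctx = CONTEXT_PROMOTER
        if ctx is not None and _PRECEDENCE[ctx] < _PRECEDENCE[best[0]]:
            best = (ctx, g.gene_id)
    return best


def codon_change(
    chrom: str, pos0: int, ref: str, alt: str, gene: GeneModel, genome: GenomeRef
) -> EffectAnnotation:
    """Codon-level effect of a CDS SNP.

    The codon containing the variant is extracted in coding orientation
    (minus-strand genes are reverse-complemented), the alternate base is
    substituted, and both codons are translated with the standard code.
    """
    if genome.base(chrom, pos0) != ref:
        raise AnnotationError(
            f"{gene.gene_id}: reference base at {chrom}:{pos0 + 1} is "
            f"{genome.base(chrom, pos0)}, variant says {ref}"
        )
    coding = gene.coding_sequence(genome)
    if len(coding) % 3 != 0:
        raise AnnotationError(f"{gene.gene_id}: CDS frame inconsistency")
    off = gene.coding_offset(pos0)
    ci = off // 3
    within = off % 3
    ref_codon = coding[3 * ci : 3 * ci + 3]
    ref_base_coding = ref if gene.strand == "+" else _COMP[ref]
    alt_base_coding = alt if gene.strand == "+" else _COMP[alt]
    if ref_codon[within] != ref_base_coding:
        raise AnnotationError(f"{gene.gene_id}: CDS frame inconsistency at {chrom}:{pos0 + 1}")
    alt_codon = ref_codon[:within] + alt_base_coding + ref_codon[within + 1 :]
    ref_res = str(Seq(ref_codon).translate())
    alt_res = str(Seq(alt_codon).translate())
    if alt_res == "*" and ref_res != "*":
        effect = EFFECT_STOP_GAIN
    elif alt_res == ref_res:
        effect = EFFECT_SYNONYMOUS
    else:
        effect = EFFECT_NONSYNONYMOUS
    return EffectAnnotation(
        chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt, gene_id=gene.gene_id,
        context=CONTEXT_CDS, codon_index=ci, ref_codon=ref_codon, alt_codon=alt_codon,
        ref_residue=ref_res, alt_residue=alt_res, effect=effect,
    )


def annotate_variants(
    variants,
    gene_models: list[GeneModel],
    genome: GenomeRef,
    promoter_bp: int = 1000,
) -> list[EffectAnnotation]:
    """Annotate an iterable of objects with chrom/pos (1-based)/ref/alt."""
    by_id = {g.gene_id: g for g in gene_models}
    out = []
    for v in variants:
        pos0 = v.pos - 1
        ctx, gid = classify_context(v.chrom, pos0, gene_models, promoter_bp)
        if ctx == CONTEXT_CDS:
            out.append(codon_change(v.chrom, pos0, v.ref, v.alt, by_id[gid], genome))
        else:
            out.append(
                EffectAnnotation(
                    chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                    gene_id=gid, context=ctx, effect=EFFECT_NONCODING,
                )
            )
    return out


def nonsynonymous_summary(annotations: list[EffectAnnotation]) -> dict:
    """Counts per effect class plus the distinct genes carrying at least one
    nonsynonymous or stop-gain change."""
    counts = Counter(a.effect for a in annotations)
    genes = sorted(
        {
            a.gene_id
            for a in annotations
            if a.effect in (EFFECT_NONSYNONYMOUS, EFFECT_STOP_GAIN) and a.gene_id
        }
    )
    return {
        "counts": {
            k: counts.get(k, 0)
            for k in (EFFECT_SYNONYMOUS, EFFECT_NONSYNONYMOUS, EFFECT_STOP_GAIN, EFFECT_NONCODING)
        },
        "nonsynonymous_genes": genes,
        "n_nonsynonymous_genes": len(genes),
    }


def gene_boundary_overlap_count(annotations: list[EffectAnnotation]) -> int:
    """Number of variants overlapping gene boundaries, counting CDS, UTR and
    core promoter but excluding introns."""
    return sum(1 for a in annotations if a.context in GENE_BOUNDARY_CONTEXTS)


def annotations_to_table(annotations: list[EffectAnnotation]):
    """Annotation table with the candidate-report column set."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene_id": a.gene_id or "",
                "chrom": a.chrom,
                "position": a.pos,
                "ref": a.ref,
                "alt": a.alt,
                "context": a.context,
                "amino_acid_change": a.aa_change or "",
                "effect": a.effect,
            }
            for a in annotations
        ]
    )
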