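"""Single-transcript gene models: synthetic construction, coordinate maps
between genome and coding sequence, and GFF3 round-trip.

Gene models are deliberately simple — one transcript per gene, UTRs flanking a
multi-exon CDS, and a core promoter defined as a fixed window upstream of the
transcription start on the coding strand. That is all the effect annotation
and the gene-overlap counting need.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .config import SimConfig, STAGE_GENES, stage_rng
from .genome import GenomeRef, revcomp

STOP_CODONS = ("TAA", "TAG", "TGA")
#: the 61 sense codons
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS
)


def translate(seq: str) -> str:
    return str(Seq(seq).translate())


@dataclass
class GeneModel:
    """One gene with a single transcript.

    All intervals are 0-based half-open on the genome. ``cds`` intervals are
    sorted in genomic order; for minus-strand genes the coding order is the
    genomic reverse.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    tx_start: int
    tx_end: int
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.cds_length % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3")
        for name in ("cds", "utr5", "utr3"):
            ivals = getattr(self, name)
            if ivals != sorted(ivals):
                raise ValueError(f"{self.gene_id}: {name} intervals not sorted")
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if e1 > s2:
                    raise ValueError(f"{self.gene_id}: overlapping {name} intervals")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def promoter(self, promoter_bp: int = 1000) -> tuple[int, int]:
        """Core promoter: ``promoter_bp`` upstream of the transcript start on
        the coding strand (abutting it)."""
        if self.strand == "+":
            return (max(0, self.tx_start - promoter_bp), self.tx_start)
        return (self.tx_end, self.tx_end + promoter_bp)

    def contains(self, pos0: int) -> bool:
        return self.tx_start <= pos0 < self.tx_end

    def in_cds(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.cds)

    def in_utr(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.utr5 + self.utr3)

    def coding_offset(self, pos0: int) -> int:
        """Offset of a genomic position within the coding sequence (0-based,
        in coding orientation). Raises ``ValueError`` outside the CDS."""
        fwd = 0
        for s, e in self.cds:
            if s <= pos0 < e:
                fwd += pos0 - s
                break
            fwd += e - s
        else:
            raise ValueError(f"{self.chrom}:{pos0} not in CDS of {self.gene_id}")
        return fwd if self.strand == "+" else self.cds_length - 1 - fwd

    def coding_sequence(self, genome: GenomeRef) -> str:
        concat = "".join(genome.sequence(self.chrom, s, e) for s, e in self.cds)
        return concat if self.strand == "+" else revcomp(concat)

    def cds_phases(self) -> list[int]:
        """GFF3 phase for each ``cds`` interval (genomic order)."""
        order = self.cds if self.strand == "+" else list(reversed(self.cds))
        phases, cum = [], 0
        for s, e in order:
            phases.append((3 - cum % 3) % 3)
            cum += e - s
        return phases if self.strand == "+" else list(reversed(phases))


# ---------------------------------------------------------------------------
# synthetic construction


def _coding_seq(rng, n_codons: int, forced: dict[int, str] | None = None) -> str:
    """ATG + random sense codons + TAA; ``forced`` pins specific codon
    indices (may include 0)."""
    codons = ["ATG"] + [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons - 2)] + ["TAA"]
    for idx, codon in (forced or {}).items():
        codons[idx] = codon
    return "".join(codons)


def _layout_gene(rng, gene_id, chrom, strand, anchor, coding_seq, n_exons, utr_len=150):
    """Place a gene whose transcript starts at ``anchor`` (genomic low edge),
    splitting the CDS into ``n_exons`` exons separated by random introns.
    Returns (GeneModel, [(genomic_start, exon_seq_on_plus_strand), ...])."""
    L = len(coding_seq)
    cuts = sorted(rng.choice(np.arange(3, L - 3, 3), size=n_exons - 1, replace=False)) if n_exons > 1 else []
    bounds = [0] + [int(c) for c in cuts] + [L]
    exon_lens = [b - a for a, b in zip(bounds, bounds[1:])]
    intron_lens = [int(rng.integers(120, 301)) for _ in range(n_exons - 1)]

    genomic_plus = coding_seq if strand == "+" else revcomp(coding_seq)
    # split the genomic-orientation sequence into exon chunks (genomic order)
    glens = exon_lens if strand == "+" else list(reversed(exon_lens))
    pos = anchor + utr_len
    cds, chunks, off = [], [], 0
    for i, ln in enumerate(glens):
        cds.append((pos, pos + ln))
        chunks.append((pos, genomic_plus[off : off + ln]))
        off += ln
        pos += ln
        if i < n_exons - 1:
            pos += intron_lens[i]
    tx_start, tx_end = anchor, pos + utr_len
    low_utr = [(anchor, anchor + utr_len)]
    high_utr = [(pos, tx_end)]
    utr5, utr3 = (low_utr, high_utr) if strand == "+" else (high_utr, low_utr)
    gm = GeneModel(gene_id, chrom, strand, tx_start, tx_end, cds, utr5, utr3)
    return gm, chunks


def make_gene_models(genome: GenomeRef, config: SimConfig) -> list[GeneModel]:
    """Construct gene models and embed their coding sequences in ``genome``
    (in place).

    ``causal_window_genes`` genes are laid out inside a ``causal_window_bp``
    window centred on the causal position, mirroring the gene content of a
    mapped locus; ``n_genes_per_chromosome`` more are spread over the rest of
    each chromosome. One designated plus-strand gene overlaps the causal
    position with an Ala codon (GCA) whose first base sits exactly on it, so a
    G>A transition there is nonsynonymous (Ala>Thr).
    """
    rng = stage_rng(config, STAGE_GENES)
    causal_pos = config.resolved_causal_pos()
    causal_chrom = config.causal_chrom_name
    if genome.in_repeat(causal_chrom, causal_pos):
        raise ValueError(
            f"causal position {causal_chrom}:{causal_pos} lies in a repeat "
            "tract; the causal variant would not survive masking"
        )

    genes: list[GeneModel] = []
    counter = 0

    def _embed(gm: GeneModel, chunks) -> None:
        for start, seq in chunks:
            genome.set_bases(gm.chrom, start, seq)

    def _random_gene(chrom, lo, hi, strand=None):
        """Place a random gene entirely within [lo, hi); None if too tight."""
        nonlocal counter
        strand = strand or ("+" if rng.random() < 0.5 else "-")
        n_exons = int(rng.integers(1, 4))
        # span budget: 2 UTRs of 150 + introns of at most 300 each + CDS
        max_codons = (hi - lo - 300 - 300 * (n_exons - 1) - 1) // 3
        if max_codons < 10:
            n_exons, max_codons = 1, (hi - lo - 301) // 3
        if max_codons < 4:
            return None
        n_codons = int(rng.integers(10, min(220, max_codons) + 1)) if max_codons >= 10 else int(max_codons)
        span_bound = 300 + 3 * n_codons + 300 * (n_exons - 1)
        anchor = lo if hi - lo <= span_bound + 1 else int(rng.integers(lo, hi - span_bound))
        counter += 1
        gm, chunks = _layout_gene(
            rng, f"Gene{counter:05d}", chrom, strand, anchor, _coding_seq(rng, n_codons), n_exons
        )
        _embed(gm, chunks)
        return gm

    window = (
        max(0, causal_pos - config.causal_window_bp // 2),
        min(genome.length(causal_chrom), causal_pos + config.causal_window_bp // 2),
    )

    # the designated causal gene: plus strand, single exon, Ala codon (GCA)
    # anchored so its G is the causal base
    causal_gm = None
    if config.causal_window_genes > 0 or config.n_genes_per_chromosome > 0:
        counter += 1
        n_before = 100  # codons upstream of the causal codon
        anchor = causal_pos - 3 * n_before - 150
        if anchor < 0:
            raise ValueError("causal position too close to the chromosome start")
        coding = _coding_seq(rng, 200, forced={n_before: "GCA"})
        causal_gm, causal_chunks = _layout_gene(
            rng, f"Gene{counter:05d}", causal_chrom, "+", anchor, coding, n_exons=1
        )
        if causal_gm.tx_end > genome.length(causal_chrom):
            raise ValueError("causal gene does not fit before the chromosome end")
        _embed(causal_gm, causal_chunks)

    for ci, chrom in enumerate(genome.names):
        L = genome.length(chrom)
        is_causal_chrom = ci == config.causal_chrom
        if is_causal_chrom and config.causal_window_genes > 0:
            n = config.causal_window_genes
            slot = max(1, (window[1] - window[0]) // n)
            causal_slot = min((causal_pos - window[0]) // slot, n - 1)
            genes.append(causal_gm)
            for k in range(n):
                if k == causal_slot:
                    continue
                lo, hi = window[0] + k * slot, window[0] + (k + 1) * slot
                # clip away any overlap with the causal gene's span
                if hi > causal_gm.tx_start and lo < causal_gm.tx_end:
                    if lo < causal_gm.tx_start:
                        hi = causal_gm.tx_start
                    else:
                        lo = causal_gm.tx_end
                gm = _random_gene(chrom, lo, hi) if hi > lo else None
                if gm is not None:
                    genes.append(gm)
        elif is_causal_chrom and causal_gm is not None:
            genes.append(causal_gm)
        n_bg = config.n_genes_per_chromosome
        if n_bg <= 0:
            continue
        slot = L // n_bg
        avoid = window if (is_causal_chrom and config.causal_window_genes > 0) else (
            (causal_gm.tx_start, causal_gm.tx_end) if is_causal_chrom else None
        )
        for k in range(n_bg):
            lo, hi = k * slot, (k + 1) * slot
            if avoid is not None and not (hi <= avoid[0] or lo >= avoid[1]):
                continue  # keep the causal region to its own layout
            gm = _random_gene(chrom, lo, hi)
            if gm is not None:
                genes.append(gm)
    return genes


def causal_gene(genes: list[GeneModel], config: SimConfig) -> GeneModel:
    """The designated gene whose CDS covers the causal position."""
    pos = config.resolved_causal_pos()
    chrom = config.causal_chrom_name
    for g in genes:
        if g.chrom == chrom and g.in_cds(pos):
            return g
    raise ValueError("no gene model covers the causal position")


# ---------------------------------------------------------------------------
# GFF3 I/O


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start)):
            tid = f"{g.gene_id}.1"
            rows = [
                (g.tx_start, g.tx_end, "gene", ".", f"ID={g.gene_id}"),
                (g.tx_start, g.tx_end, "mRNA", ".", f"ID={tid};Parent={g.gene_id}"),
            ]
            for s, e in g.utr5:
                rows.append((s, e, "five_prime_UTR", ".", f"Parent={tid}"))
            for (s, e), ph in zip(g.cds, g.cds_phases()):
                rows.append((s, e, "CDS", str(ph), f"Parent={tid}"))
            for s, e in g.utr3:
                rows.append((s, e, "three_prime_UTR", ".", f"Parent={tid}"))
            for s, e, ftype, phase, attrs in rows:
                fh.write(
                    f"{g.chrom}\tbsamap\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t{phase}\t{attrs}\n"
                )


def read_gff3(path) -> list[GeneModel]:
    """Load single-transcript gene models from GFF3 (via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for gf in db.features_of_type("gene"):
        cds = sorted((f.start - 1, f.end) for f in db.children(gf, featuretype="CDS"))
        utr5 = sorted((f.start - 1, f.end) for f in db.children(gf, featuretype="five_prime_UTR"))
        utr3 = sorted((f.start - 1, f.end) for f in db.children(gf, featuretype="three_prime_UTR"))
        genes.append(
            GeneModel(gf.id, gf.seqid, gf.strand, gf.start - 1, gf.end, cds, utr5, utr3)
        )
    return sorted(genes, key=lambda g: (g.chrom, g.tx_start))
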