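"""Reference-genome container, random genome generation, repeat tracts, and
SNP application (reconstructing an individual parental genome from a variant
list)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimConfig, STAGE_GENOME, stage_rng

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass
class GenomeRef:
    """In-memory reference genome.

    Sequences are stored as uint8 ASCII arrays (mutable: the gene-model
    builder embeds coding sequence in place). Repeat intervals are 0-based
    half-open and sorted, non-overlapping per chromosome.
    """

    names: list[str]
    seqs: dict[str, np.ndarray]
    repeats: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def length(self, chrom: str) -> int:
        return int(self.seqs[chrom].size)

    def sequence(self, chrom: str, start: int = 0, end: int | None = None) -> str:
        arr = self.seqs[chrom]
        end = arr.size if end is None else end
        return arr[start:end].tobytes().decode("ascii")

    def base(self, chrom: str, pos0: int) -> str:
        return chr(self.seqs[chrom][pos0])

    def set_bases(self, chrom: str, start: int, seq: str) -> None:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        self.seqs[chrom][start : start + arr.size] = arr

    def in_repeat(self, chrom: str, pos0: int) -> bool:
        ivals = self.repeats.get(chrom, [])
        starts = [s for s, _ in ivals]
        import bisect

        i = bisect.bisect_right(starts, pos0) - 1
        return i >= 0 and ivals[i][0] <= pos0 < ivals[i][1]

    def repeat_fraction(self, chrom: str) -> float:
        covered = sum(e - s for s, e in self.repeats.get(chrom, []))
        return covered / self.length(chrom)

    def copy(self) -> "GenomeRef":
        return GenomeRef(
            names=list(self.names),
            seqs={c: s.copy() for c, s in self.seqs.items()},
            repeats={c: list(v) for c, v in self.repeats.items()},
        )


def make_genome(config: SimConfig) -> GenomeRef:
    """Generate a random multi-chromosome genome with repeat tracts.

    Repeat tracts of ``repeat_tract_bp`` are laid on a tract-sized grid until
    ``repeat_fraction`` of each chromosome is covered; the grid slot holding
    the causal position is never chosen, so the causal SNP always survives
    repeat masking. Deterministic for a fixed seed.
    """
    rng = stage_rng(config, STAGE_GENOME)
    lengths = config.resolved_chrom_lengths()
    names = list(config.chrom_names)
    seqs: dict[str, np.ndarray] = {}
    repeats: dict[str, list[tuple[int, int]]] = {}
    causal_pos = config.resolved_causal_pos()

    for ci, (name, L) in enumerate(zip(names, lengths)):
        seqs[name] = _BASES[rng.integers(0, 4, size=L)]
        tract = min(config.repeat_tract_bp, L)
        n_slots = L // tract if tract else 0
        n_pick = int(round(config.repeat_fraction * n_slots))
        ivals: list[tuple[int, int]] = []
        if n_pick and n_slots:
            slots = np.arange(n_slots)
            if ci == config.causal_chrom:
                slots = slots[slots != causal_pos // tract]
            chosen = np.sort(rng.choice(slots, size=min(n_pick, slots.size), replace=False))
            ivals = [(int(s) * tract, int(s) * tract + tract) for s in chosen]
        repeats[name] = ivals
    return GenomeRef(names=names, seqs=seqs, repeats=repeats)


def apply_variants_to_reference(genome: GenomeRef, variants) -> GenomeRef:
    """Return a copy of ``genome`` with each SNP's alternate base substituted.

    ``variants`` is an iterable of objects with ``chrom``, ``pos0``, ``ref``,
    ``alt`` attributes (or (chrom, pos0, ref, alt) tuples). Raises
    ``ValueError`` listing every position whose reference base disagrees.
    """
    out = genome.copy()
    mismatches = []
    for v in variants:
        chrom, pos0, ref, alt = (
            (v.chrom, v.pos0, v.ref, v.alt) if hasattr(v, "chrom") else v
        )
        if not 0 <= pos0 < out.length(chrom):
            raise ValueError(f"variant position {chrom}:{pos0} out of bounds")
        if out.base(chrom, pos0) != ref:
            mismatches.append((chrom, pos0, ref, out.base(chrom, pos0)))
            continue
        out.set_bases(chrom, pos0, alt)
    if mismatches:
        raise ValueError(
            "reference-base mismatch at "
            + ", ".join(f"{c}:{p} (expected {r}, found {f})" for c, p, r, f in mismatches)
        )
    return out


def call_differences(a: GenomeRef, b: GenomeRef) -> list[tuple[str, int, str, str]]:
    """All single-base differences between two equal-shape genomes, as
    (chrom, pos0, base_a, base_b). The round-trip oracle for
    :func:`apply_variants_to_reference`."""
    diffs = []
    for chrom in a.names:
        sa, sb = a.seqs[chrom], b.seqs[chrom]
        for pos0 in np.flatnonzero(sa != sb):
            diffs.append((chrom, int(pos0), chr(sa[pos0]), chr(sb[pos0])))
    return diffs
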