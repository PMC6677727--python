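"""Circular mtDNA coordinate system, region partition, and codon-level
substitution classification under the vertebrate mitochondrial genetic code.

Coordinates are 1-based inclusive throughout (rCRS numbering). The genome is
circular: the control region and the D-loop wrap around the origin.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

GENOME_LENGTH = 16_569

#: vertebrate mitochondrial code (NCBI translation table 2)
MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

ALLELES = ("A", "C", "G", "T")


def translate_codon(codon: str) -> str:
    """One-letter amino acid for *codon* under table 2; '*' for stop."""
    codon = codon.upper()
    if codon in MITO_TABLE.stop_codons:
        return "*"
    return MITO_TABLE.forward_table[codon]


def complement(base: str) -> str:
    return _COMPLEMENT[base.upper()]


def _expand(start: int, end: int) -> np.ndarray:
    """Positions of a 1-based inclusive interval, wrapping past the origin."""
    if start <= end:
        return np.arange(start, end + 1)
    return np.concatenate([np.arange(start, GENOME_LENGTH + 1), np.arange(1, end + 1)])


@dataclass(frozen=True)
class RegionMap:
    """Partition of the genome into control/non-control plus D-loop and
    alignment-excluded flags.

    Defaults follow rCRS conventions: control region 16,024-576 (wrapping),
    non-control 577-16,023, D-loop 16,097-191, and four excluded repetitive
    stretches.
    """

    control: tuple[tuple[int, int], ...] = ((16_024, 576),)
    noncontrol: tuple[tuple[int, int], ...] = ((577, 16_023),)
    dloop: tuple[tuple[int, int], ...] = ((16_097, 191),)
    excluded: tuple[tuple[int, int], ...] = (
        (302, 316),
        (513, 526),
        (566, 573),
        (16_181, 16_194),
    )

    def positions(self, which: str) -> np.ndarray:
        """All positions of the named interval set, ascending."""
        ivals = getattr(self, which)
        pos = np.concatenate([_expand(s, e) for s, e in ivals])
        return np.unique(pos)

    def control_mask(self) -> np.ndarray:
        """Boolean mask of length GENOME_LENGTH (index 0 = position 1)."""
        mask = np.zeros(GENOME_LENGTH, dtype=bool)
        mask[self.positions("control") - 1] = True
        return mask

    def dloop_mask(self) -> np.ndarray:
        mask = np.zeros(GENOME_LENGTH, dtype=bool)
        mask[self.positions("dloop") - 1] = True
        return mask

    def excluded_mask(self) -> np.ndarray:
        mask = np.zeros(GENOME_LENGTH, dtype=bool)
        mask[self.positions("excluded") - 1] = True
        return mask


@dataclass(frozen=True)
class RegionCall:
    region: str  # "control" | "noncontrol"
    dloop: bool
    excluded: bool


def check_position(pos: int) -> None:
    if not 1 <= pos <= GENOME_LENGTH:
        raise ValueError(f"position {pos} outside 1..{GENOME_LENGTH}")


def classify_region(pos: int, region_map: RegionMap | None = None) -> RegionCall:
    """Classify *pos* as control or noncontrol, with independent D-loop and
    excluded-region flags."""
    check_position(pos)
    rmap = region_map if region_map is not None else RegionMap()
    in_control = any(
        (s <= pos <= e) if s <= e else (pos >= s or pos <= e) for s, e in rmap.control
    )
    in_dloop = any(
        (s <= pos <= e) if s <= e else (pos >= s or pos <= e) for s, e in rmap.dloop
    )
    in_excl = any(
        (s <= pos <= e) if s <= e else (pos >= s or pos <= e) for s, e in rmap.excluded
    )
    return RegionCall("control" if in_control else "noncontrol", in_dloop, in_excl)


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene with 1-based inclusive genomic coordinates.

    ``strand`` is "H" (heavy, reads forward) or "L" (light, reverse
    complement; ND6). ``frame`` shifts the first codon start within the CDS.
    Trailing bases that do not fill a whole codon (incomplete stop codons
    completed by polyadenylation) are not part of any codon.
    """

    name: str
    start: int
    end: int
    strand: str
    frame: int = 0

    def __post_init__(self):
        if self.strand not in ("H", "L"):
            raise ValueError(f"bad strand {self.strand!r} for {self.name}")
        if self.end < self.start:
            raise ValueError(f"{self.name}: end < start (wrapping genes unsupported)")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_codons(self) -> int:
        return (self.length - self.frame) // 3

    def cds_offset(self, pos: int) -> int:
        """0-based offset of *pos* within the coding-strand sequence."""
        if not self.start <= pos <= self.end:
            raise ValueError(f"{pos} not in {self.name}")
        if self.strand == "H":
            return pos - self.start
        return self.end - pos

    def codon_index(self, pos: int) -> int | None:
        """Codon number (0-based) containing *pos*, or None if the position
        falls in the frame offset or a trailing partial codon."""
        off = self.cds_offset(pos) - self.frame
        if off < 0:
            return None
        idx = off // 3
        return idx if idx < self.n_codons else None


def load_genes(path=None) -> list[Gene]:
    """Read a gene table (TSV: gene, start, end, strand, frame). Defaults to
    the packaged 13-gene rCRS annotation."""
    if path is None:
        ref = importlib.resources.files("hetshare.data") / "mt_genes.tsv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [
        Gene(r.gene, int(r.start), int(r.end), r.strand, int(r.frame))
        for r in df.itertuples()
    ]


def load_reference(path=None) -> str:
    """Read a single-contig FASTA reference; defaults to the packaged
    synthetic 16,569 bp sequence (rCRS-length, rCRS gene coordinates)."""
    if path is None:
        ref = importlib.resources.files("hetshare.data") / "default_reference.fasta"
        with importlib.resources.as_file(ref) as p:
            rec = next(SeqIO.parse(str(p), "fasta"))
    else:
        rec = next(SeqIO.parse(str(path), "fasta"))
    return str(rec.seq).upper()


@dataclass(frozen=True)
class SubstitutionCall:
    """Classification of a single-base substitution against the coding
    annotation. ``per_gene`` holds the per-frame label for every overlapping
    gene; ``label`` is non-synonymous if ANY frame is non-synonymous."""

    label: str  # "synonymous" | "non-synonymous" | "non-coding"
    per_gene: dict = field(default_factory=dict)


class MitoGenome:
    """Reference sequence plus gene annotation; answers region and
    codon-level substitution queries."""

    def __init__(self, sequence: str | None = None, genes: list[Gene] | None = None,
                 region_map: RegionMap | None = None):
        self.sequence = (sequence or load_reference()).upper()
        self.length = len(self.sequence)
        self.genes = genes if genes is not None else load_genes()
        self.region_map = region_map if region_map is not None else RegionMap()
        self._genes_at: dict[int, list[Gene]] = {}
        for g in self.genes:
            if g.end > self.length:
                raise ValueError(f"{g.name} extends past the reference end")
            for p in range(g.start, g.end + 1):
                self._genes_at.setdefault(p, []).append(g)

    def base(self, pos: int) -> str:
        check_position_len(pos, self.length)
        return self.sequence[pos - 1]

    def genes_at(self, pos: int) -> list[Gene]:
        return self._genes_at.get(pos, [])

    def codon_at(self, gene: Gene, codon_idx: int) -> str:
        """Coding-strand codon *codon_idx* (0-based) of *gene*."""
        if not 0 <= codon_idx < gene.n_codons:
            raise IndexError(codon_idx)
        if gene.strand == "H":
            s = gene.start + gene.frame + 3 * codon_idx
            return self.sequence[s - 1 : s + 2]
        s = gene.end - gene.frame - 3 * codon_idx  # genomic pos of codon base 1
        genomic = self.sequence[s - 3 : s]  # codon bases 3,2,1 in genome order
        return "".join(complement(b) for b in reversed(genomic))

    def classify_substitution_in_gene(self, gene: Gene, pos: int, ref: str,
                                      alt: str) -> str | None:
        """Label for one gene frame, or None if *pos* is not in a complete
        codon of *gene*."""
        idx = gene.codon_index(pos)
        if idx is None:
            return None
        codon = self.codon_at(gene, idx)
        within = (gene.cds_offset(pos) - gene.frame) % 3
        ref_c, alt_c = (ref, alt) if gene.strand == "H" else (
            complement(ref), complement(alt))
        if codon[within] != ref_c:
            raise ValueError(
                f"reference mismatch at {pos} in {gene.name}: codon has "
                f"{codon[within]}, caller says {ref_c}")
        mutant = codon[:within] + alt_c + codon[within + 1 :]
        return ("synonymous" if translate_codon(mutant) == translate_codon(codon)
                else "non-synonymous")

    def annotate_substitution(self, pos: int, ref: str, alt: str) -> SubstitutionCall:
        """Classify the substitution ref→alt at *pos*.

        Raises ValueError if alt == ref or if *ref* disagrees with the
        reference sequence. Positions outside complete codons of any gene
        are non-coding. A substitution covered by overlapping genes is
        non-synonymous if non-synonymous in any frame.
        """
        check_position_len(pos, self.length)
        ref, alt = ref.upper(), alt.upper()
        if ref == alt:
            raise ValueError(f"alt equals ref ({ref}) at {pos}")
        if ref not in ALLELES or alt not in ALLELES:
            raise ValueError(f"bad alleles {ref}>{alt}")
        if self.base(pos) != ref:
            raise ValueError(
                f"ref allele {ref} at {pos} does not match reference "
                f"{self.base(pos)}")
        per_gene = {}
        for g in self.genes_at(pos):
            lbl = self.classify_substitution_in_gene(g, pos, ref, alt)
            if lbl is not None:
                per_gene[g.name] = lbl
        if not per_gene:
            return SubstitutionCall("non-coding")
        label = ("non-synonymous"
                 if any(v == "non-synonymous" for v in per_gene.values())
                 else "synonymous")
        return SubstitutionCall(label, per_gene)

    def coding_positions(self) -> np.ndarray:
        """Sorted positions that fall in a complete codon of ≥1 gene."""
        pos = sorted(
            p for p, gs in self._genes_at.items()
            if any(g.codon_index(p) is not None for g in gs)
        )
        return np.asarray(pos, dtype=int)


def check_position_len(pos: int, length: int) -> None:
    if not 1 <= pos <= length:
        raise ValueError(f"position {pos} outside 1..{length}")
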