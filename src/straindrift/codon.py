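"""Codon-level consequence annotation of substitution variants.

Handles SNVs and multi-nucleotide variants (MNVs: runs of adjacent
substitutions carried as one equal-length ref/alt pair, e.g. GC->CT)
within a coding sequence.  Translation uses the bacterial/archaeal
genetic code (NCBI table 11).  Length-changing alleles are refused
rather than silently dropped.  All external coordinates are 1-based
inclusive; minus-strand CDS are handled by reverse-complementing before
offset computation, so a genomic variant is first re-expressed in
coding orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .errors import DataError, UnsupportedVariantError

__all__ = ["CodonChange", "CdsRecord", "annotate_codon_change", "annotate_genomic_variant"]

BACTERIAL_TABLE = 11


@dataclass(frozen=True)
class CodonChange:
    gene_id: str
    strand: str
    cds_position: int  # 1-based offset of the first changed base in this codon
    residue_index: int  # 1-based codon number; == ceil(cds_position / 3)
    ref_aa: str
    alt_aa: str
    synonymous: bool

    def __post_init__(self):
        assert self.residue_index == -(-self.cds_position // 3)
        assert self.synonymous == (self.ref_aa == self.alt_aa)


@dataclass(frozen=True)
class CdsRecord:
    """A CDS as one or more genomic segments on one strand.

    ``segments`` are (start, end) 1-based inclusive, stored in ascending
    genomic order; for minus-strand genes the coding sequence is the
    reverse complement of the concatenated segments.
    """

    gene_id: str
    seqid: str
    strand: str
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise DataError(f"CDS {self.gene_id!r}: unknown strand {self.strand!r}")
        segs = tuple(sorted(self.segments))
        for (s, e) in segs:
            if s > e:
                raise DataError(f"CDS {self.gene_id!r}: segment start {s} > end {e}")
        for (_, e1), (s2, _) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise DataError(f"CDS {self.gene_id!r}: overlapping segments")
        object.__setattr__(self, "segments", segs)

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.segments)

    def contains(self, position: int, span: int = 1) -> bool:
        """True when [position, position+span-1] lies inside one segment."""
        return any(s <= position and position + span - 1 <= e for s, e in self.segments)

    def coding_sequence(self, genome: Mapping[str, str]) -> str:
        if self.seqid not in genome:
            raise DataError(f"sequence {self.seqid!r} absent from genome")
        chrom = genome[self.seqid].upper()
        joined = "".join(chrom[s - 1 : e] for s, e in self.segments)
        if self.strand == "-":
            joined = str(Seq(joined).reverse_complement())
        return joined

    def genome_to_cds(self, position: int) -> int:
        """Map a genomic coordinate to a 1-based offset in coding orientation."""
        prefix = 0
        for s, e in self.segments:
            if s <= position <= e:
                asc = prefix + position - s + 1
                if self.strand == "+":
                    return asc
                return self.length - asc + 1
            prefix += e - s + 1
        raise DataError(f"position {position} outside CDS {self.gene_id!r}")


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate(table=BACTERIAL_TABLE))


def annotate_codon_change(
    cds_sequence: str,
    cds_position: int,
    ref: str,
    alt: str,
    gene_id: str = "",
    strand: str = "+",
) -> list[CodonChange]:
    """Consequences of an equal-length substitution within a CDS.

    Returns one :class:`CodonChange` per affected codon (an MNV spanning
    a codon boundary yields several).  The reference run must match the
    CDS at ``cds_position``.
    """
    seq = cds_sequence.upper()
    ref = ref.upper()
    alt = alt.upper()
    if len(ref) != len(alt):
        raise UnsupportedVariantError(
            f"length-changing allele {ref}->{alt}; only substitutions are supported"
        )
    if cds_position < 1 or cds_position + len(ref) - 1 > len(seq):
        raise DataError(f"variant at {cds_position} (+{len(ref)}) outside CDS of length {len(seq)}")
    found = seq[cds_position - 1 : cds_position - 1 + len(ref)]
    if found != ref:
        raise DataError(
            f"reference mismatch at CDS position {cds_position}: expected {ref}, CDS has {found}"
        )
    mutated = seq[: cds_position - 1] + alt + seq[cds_position - 1 + len(ref):]
    first_codon = -(-cds_position // 3)
    last_codon = -(-(cds_position + len(ref) - 1) // 3)
    changes: list[CodonChange] = []
    for codon_i in range(first_codon, last_codon + 1):
        lo, hi = 3 * codon_i - 3, 3 * codon_i
        if hi > len(seq):
            raise DataError(
                f"codon {codon_i} incomplete (CDS length {len(seq)} not a multiple of 3)"
            )
        ref_codon, alt_codon = seq[lo:hi], mutated[lo:hi]
        pos_in_codon = max(cds_position, lo + 1)
        ref_aa, alt_aa = _translate_codon(ref_codon), _translate_codon(alt_codon)
        changes.append(
            CodonChange(gene_id, strand, pos_in_codon, codon_i, ref_aa, alt_aa, ref_aa == alt_aa)
        )
    return changes


def annotate_genomic_variant(
    cds: CdsRecord,
    genome: Mapping[str, str],
    position: int,
    ref: str,
    alt: str,
) -> list[CodonChange]:
    """Annotate a genomic substitution (plus-strand alleles, as in a VCF)
    against a CDS, re-orienting alleles for minus-strand genes."""
    if len(ref) != len(alt):
        raise UnsupportedVariantError(
            f"length-changing allele {ref}->{alt}; only substitutions are supported"
        )
    if not cds.contains(position, len(ref)):
        raise DataError(
            f"variant at {position} (+{len(ref)}) not inside a single segment of {cds.gene_id!r}"
        )
    if cds.strand == "+":
        cds_pos = cds.genome_to_cds(position)
        c_ref, c_alt = ref, alt
    else:
        cds_pos = cds.genome_to_cds(position + len(ref) - 1)
        c_ref = str(Seq(ref).reverse_complement())
        c_alt = str(Seq(alt).reverse_complement())
    coding = cds.coding_sequence(genome)
    return annotate_codon_change(coding, cds_pos, c_ref, c_alt, cds.gene_id, cds.strand)
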