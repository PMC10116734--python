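"""Transcript reference handling, coordinate conventions and variant annotation.

All internal coordinates are 0-based half-open. VCF emission converts to
1-based; BED/bedgraph stay 0-based half-open. Public ``pos`` arguments on
annotation functions are 1-based transcript coordinates, matching VCF.

The codon table is the standard genetic code (Bio.Data.CodonTable table 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

VALID_BASES = frozenset("ACGT")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, with '*' for stop codons
CODON_TABLE: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
CODON_TABLE.update({c: "*" for c in _STANDARD_TABLE.stop_codons})

SNP = "SNP"
DI_NT_MNP = "di_nt_MNP"
TRI_NT_MNP = "tri_nt_MNP"

VARIANT_TYPES = {1: SNP, 2: DI_NT_MNP, 3: TRI_NT_MNP}


class ReferenceMismatchError(ValueError):
    """Raised when a supplied REF allele disagrees with the reference sequence."""


@dataclass(frozen=True)
class TranscriptReference:
    """A single transcript with an annotated CDS.

    Parameters
    ----------
    transcript_id:
        Name used as the contig in SAM/VCF/BED output.
    sequence:
        Transcript sequence, A/C/G/T only.
    cds_start, cds_end:
        0-based half-open CDS bounds; the CDS length must be a positive
        multiple of 3.
    """

    transcript_id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(f"reference contains non-ACGT characters: {sorted(bad)}")
        cds_len = self.cds_end - self.cds_start
        if cds_len < 3 or cds_len % 3 != 0:
            raise ValueError(
                f"CDS length must be a positive multiple of 3, got {cds_len}"
            )
        if self.cds_start < 0 or self.cds_end > len(seq):
            raise ValueError("CDS bounds outside the transcript sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cds_sequence(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]

    def codon_index(self, pos0: int) -> int:
        """0-based codon index of a 0-based transcript position inside the CDS."""
        if not self.cds_start <= pos0 < self.cds_end:
            raise ValueError(f"position {pos0} outside CDS [{self.cds_start},{self.cds_end})")
        return (pos0 - self.cds_start) // 3

    def codon(self, codon_idx: int) -> str:
        start = self.cds_start + 3 * codon_idx
        if not self.cds_start <= start < self.cds_end:
            raise ValueError(f"codon index {codon_idx} outside CDS")
        return self.sequence[start : start + 3]

    def to_fasta(self, path: str) -> str:
        with open(path, "w") as fh:
            fh.write(f">{self.transcript_id}\n")
            for i in range(0, len(self.sequence), 70):
                fh.write(self.sequence[i : i + 70] + "\n")
        return path

    @classmethod
    def from_fasta(
        cls,
        fasta_path: str,
        cds_start: int,
        cds_end: int,
        transcript_id: str | None = None,
    ) -> "TranscriptReference":
        """Load a reference from FASTA with explicit CDS bounds.

        If ``transcript_id`` is None the first record is used.
        """
        for rec in SeqIO.parse(fasta_path, "fasta"):
            if transcript_id is None or rec.id == transcript_id:
                return cls(rec.id, str(rec.seq), cds_start, cds_end)
        raise KeyError(f"transcript {transcript_id!r} not found in {fasta_path}")


@dataclass(frozen=True)
class VariantAnnotation:
    """Codon-resolved annotation of a SNP or 2-3 nt MNP.

    ``pos`` is the 1-based transcript coordinate of the first changed base;
    ``cds_pos`` the 1-based CDS coordinate of the same base.
    """

    pos: int
    cds_pos: int
    ref_allele: str
    alt_allele: str
    variant_type: str
    ref_codons: tuple[str, ...]
    alt_codons: tuple[str, ...]
    aa_change: str
    multi_codon: bool
    matches_signature: bool = field(default=False, compare=False)

    @property
    def span(self) -> int:
        return len(self.ref_allele)


def _validate_alleles(ref_allele: str, alt_allele: str) -> None:
    if len(ref_allele) != len(alt_allele):
        raise ValueError("REF and ALT alleles must have equal length (substitutions only)")
    if not 1 <= len(ref_allele) <= 3:
        raise ValueError(f"allele length must be 1-3 nt, got {len(ref_allele)}")
    for allele in (ref_allele, alt_allele):
        if set(allele) - VALID_BASES:
            raise ValueError(f"allele {allele!r} contains non-ACGT characters")
    if ref_allele == alt_allele:
        raise ValueError("ALT allele equals REF allele: not a variant")


def annotate_variant(
    ref: TranscriptReference, pos: int, ref_allele: str, alt_allele: str
) -> VariantAnnotation:
    """Annotate a substitution at 1-based transcript ``pos`` against the CDS.

    The amino-acid change is computed over the full codon(s) spanned by the
    variant. A variant touching more than one codon is annotated with all
    affected codons and flagged ``multi_codon``.
    """
    ref_allele = ref_allele.upper()
    alt_allele = alt_allele.upper()
    _validate_alleles(ref_allele, alt_allele)

    start0 = pos - 1
    end0 = start0 + len(ref_allele)
    if not (ref.cds_start <= start0 and end0 <= ref.cds_end):
        raise ValueError(
            f"variant at {pos} (span {len(ref_allele)}) is not fully inside the CDS"
        )
    observed = ref.sequence[start0:end0]
    if observed != ref_allele:
        for off, (a, b) in enumerate(zip(observed, ref_allele)):
            if a != b:
                raise ReferenceMismatchError(
                    f"REF allele mismatch at transcript position {pos + off}: "
                    f"reference has {a}, allele gives {b}"
                )

    first_codon = ref.codon_index(start0)
    last_codon = ref.codon_index(end0 - 1)
    ref_codons = tuple(ref.codon(i) for i in range(first_codon, last_codon + 1))

    # splice the ALT allele into the spanned codon block
    block_start = ref.cds_start + 3 * first_codon
    block = list(ref.sequence[block_start : ref.cds_start + 3 * (last_codon + 1)])
    for off, base in enumerate(alt_allele):
        block[start0 - block_start + off] = base
    alt_block = "".join(block)
    alt_codons = tuple(alt_block[i : i + 3] for i in range(0, len(alt_block), 3))

    changes = []
    for idx, (rc, ac) in enumerate(zip(ref_codons, alt_codons), start=first_codon + 1):
        ref_aa = CODON_TABLE[rc]
        alt_aa = CODON_TABLE[ac]
        if ref_aa == alt_aa:
            continue
        changes.append(f"p.{_aa3(ref_aa)}{idx}{_aa3(alt_aa)}")
    aa_change = ",".join(changes) if changes else "p.(=)"

    return VariantAnnotation(
        pos=pos,
        cds_pos=start0 - ref.cds_start + 1,
        ref_allele=ref_allele,
        alt_allele=alt_allele,
        variant_type=VARIANT_TYPES[len(ref_allele)],
        ref_codons=ref_codons,
        alt_codons=alt_codons,
        aa_change=aa_change,
        multi_codon=len(ref_codons) > 1,
    )


def _aa3(aa1: str) -> str:
    return "Ter" if aa1 == "*" else seq3(aa1)


def matches_nnk(ref: TranscriptReference, ann: VariantAnnotation) -> bool:
    """True iff the variant is a single-codon change whose ALT codon ends in G/T.

    NNK mutagenesis replaces a whole codon with NNK (K = G or T), so the
    signature is evaluated on the alternate codon only: a variant matches
    when it alters exactly one codon and that codon's third base is G or T.
    Multi-codon variants never match (returns False, never raises).
    """
    if ann.multi_codon:
        return False
    return ann.alt_codons[0][2] in "GT"
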