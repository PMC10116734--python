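"""VCF and bedgraph serialization (pysam-backed).

Internal coordinates are 0-based half-open; records are converted to VCF's
1-based convention on the way out and back on the way in. Bedgraph output
stays 0-based half-open.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Iterable

import pysam

if TYPE_CHECKING:  # pragma: no cover
    from .call import VariantCall
    from .refdata import TranscriptReference
    from .sim import TruthRecord, VariantSpec


def _base_header(ref: "TranscriptReference") -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={ref.transcript_id},length={len(ref.sequence)}>")
    return header


TRUTH_INFO_LINES = [
    '##INFO=<ID=AC,Number=A,Type=Integer,Description="Realized edited fragment count">',
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Realized variant frequency">',
    '##INFO=<ID=TF,Number=1,Type=Float,Description="Requested target frequency">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Fragment coverage at POS">',
    '##INFO=<ID=UNPLACEABLE,Number=0,Type=Flag,Description="Insufficient eligible fragments">',
]


def write_truth_vcf(records: "list[TruthRecord]", ref: "TranscriptReference", path: str) -> str:
    header = _base_header(ref)
    for line in TRUTH_INFO_LINES:
        header.add_line(line)
    with pysam.VariantFile(path, "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (r.spec.pos, r.spec.alt_allele)):
            row = out.new_record(
                contig=ref.transcript_id,
                start=rec.spec.pos - 1,
                stop=rec.spec.pos - 1 + len(rec.spec.ref_allele),
                alleles=(rec.spec.ref_allele, rec.spec.alt_allele),
            )
            row.info["AC"] = rec.realized_count
            row.info["AF"] = rec.realized_frequency
            row.info["TF"] = rec.spec.target_frequency
            row.info["DP"] = rec.fragment_coverage
            if rec.unplaceable:
                row.info["UNPLACEABLE"] = True
            out.write(row)
    return path


def read_variant_specs(path: str) -> "list[VariantSpec]":
    """Read spike-in requests: POS/REF/ALT plus INFO/AF target frequency."""
    from .sim import VariantSpec

    specs = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            af = rec.info.get("TF", rec.info.get("AF"))
            if af is None:
                raise ValueError(f"record at {rec.pos} lacks INFO/AF target frequency")
            if isinstance(af, tuple):
                af = af[0]
            ac = rec.info.get("AC")
            if isinstance(ac, tuple):
                ac = ac[0]
            specs.append(
                VariantSpec(
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                    target_frequency=float(af),
                    target_count=int(ac) if ac is not None else None,
                )
            )
    return specs


def read_truth_entries(path: str) -> dict[tuple[int, str, str], dict]:
    """Truth VCF -> {(pos, ref, alt): {count, frequency, unplaceable}}."""
    def _scalar(v):
        return v[0] if isinstance(v, tuple) else v

    out = {}
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            out[(rec.pos, rec.ref, rec.alts[0])] = dict(
                count=_scalar(rec.info.get("AC")),
                frequency=_scalar(rec.info.get("AF")),
                coverage=_scalar(rec.info.get("DP")),
                unplaceable="UNPLACEABLE" in rec.info,
            )
    return out


CALL_INFO_LINES = [
    '##INFO=<ID=TYPE,Number=1,Type=String,Description="SNP, di_nt_MNP or tri_nt_MNP">',
    '##INFO=<ID=AC,Number=A,Type=Integer,Description="Supporting fragment count">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Fragment coverage at POS">',
    '##INFO=<ID=AF,Number=A,Type=Float,Description="AC/DP variant frequency">',
    '##INFO=<ID=CDSPOS,Number=1,Type=Integer,Description="1-based CDS coordinate">',
    '##INFO=<ID=REFCODON,Number=.,Type=String,Description="Reference codon(s)">',
    '##INFO=<ID=ALTCODON,Number=.,Type=String,Description="Alternate codon(s)">',
    '##INFO=<ID=AA,Number=1,Type=String,Description="Protein change">',
    '##INFO=<ID=NNK,Number=1,Type=Integer,Description="Matches NNK mutagenesis signature">',
    '##INFO=<ID=MULTICODON,Number=0,Type=Flag,Description="Variant spans >1 codon">',
    '##INFO=<ID=R1BQ,Number=1,Type=Float,Description="R1 median supporting base quality">',
    '##INFO=<ID=R2BQ,Number=1,Type=Float,Description="R2 median supporting base quality">',
    '##INFO=<ID=R1RP,Number=1,Type=Float,Description="R1 median supporting read position">',
    '##INFO=<ID=R2RP,Number=1,Type=Float,Description="R2 median supporting read position">',
    '##INFO=<ID=R1NM,Number=1,Type=Float,Description="R1 median edit distance">',
    '##INFO=<ID=R2NM,Number=1,Type=Float,Description="R2 median edit distance">',
    '##INFO=<ID=SPLUS,Number=1,Type=Integer,Description="Supporting fragments on + sample strand">',
    '##INFO=<ID=SMINUS,Number=1,Type=Integer,Description="Supporting fragments on - sample strand">',
]


def write_calls_vcf(
    calls: "list[VariantCall]",
    ref: "TranscriptReference",
    path: str,
    command_line: str | None = None,
) -> str:
    header = _base_header(ref)
    for line in CALL_INFO_LINES:
        header.add_line(line)
    if command_line:
        header.add_line(f"##mavecall_command={command_line}")
    with pysam.VariantFile(path, "w", header=header) as out:
        for call in sorted(calls, key=lambda c: (c.annotation.pos, c.annotation.alt_allele)):
            ann = call.annotation
            row = out.new_record(
                contig=ref.transcript_id,
                start=ann.pos - 1,
                stop=ann.pos - 1 + len(ann.ref_allele),
                alleles=(ann.ref_allele, ann.alt_allele),
            )
            info = row.info
            info["TYPE"] = ann.variant_type
            info["AC"] = call.supporting_count
            info["DP"] = call.fragment_coverage
            info["AF"] = call.frequency
            info["CDSPOS"] = ann.cds_pos
            info["REFCODON"] = ",".join(ann.ref_codons)
            info["ALTCODON"] = ",".join(ann.alt_codons)
            info["AA"] = ann.aa_change
            info["NNK"] = int(call.matches_signature)
            if ann.multi_codon:
                info["MULTICODON"] = True
            for key, val in call.summaries.items():
                info[key] = val
            info["SPLUS"] = call.strand_counts.get("+", 0)
            info["SMINUS"] = call.strand_counts.get("-", 0)
            out.write(row)
    return path


def write_bedgraph(track: "Iterable[tuple[str, int, int, int]]", path: str) -> str:
    with open(path, "w") as fh:
        for contig, start, end, depth in track:
            fh.write(f"{contig}\t{start}\t{end}\t{depth}\n")
    return path


def read_bedgraph(path: str) -> list[tuple[str, int, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            c, s, e, d = line.split()[:4]
            out.append((c, int(s), int(e), int(d)))
    return out
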