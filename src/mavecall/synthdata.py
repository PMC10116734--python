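"""Synthetic targeted-sequencing library generator.

Emulates the data a saturation-mutagenesis (MAVE) experiment produces:
paired-end reads over a coding reference, laid out either as tiled PCR
amplicons or as a RACE-like (anchored one-sided PCR) design, with
substitution-biased errors, optional UMIs and PCR duplicates, and NNK
codon-mutagenesis variant libraries. Every stochastic choice is recorded in
a provenance ledger so any emitted read can be reconstructed from
(reference, fragment table, error ledger).

Error channels
--------------
``fragment``  errors are introduced into the fragment molecule before
              "sequencing", so both mates inherit them — the analogue of
              RT/PCR errors, the component that survives mate concordance.
``read``      errors are introduced per read copy, the analogue of
              sequencer miscalls, which mate concordance removes.
``primer``    errors within synthetic primer-derived segments, the channel
              primer base-quality masking is designed to suppress.
Error bases receive base qualities from a separate (lower) distribution,
reflecting the weak BQ signal real miscalls carry.
"""

from __future__ import annotations

import gzip
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pairs import revcomp
from .refdata import CODON_TABLE, SNP, DI_NT_MNP, TRI_NT_MNP, TranscriptReference

#: the six strand-collapsed substitution classes
SUBSTITUTION_CLASSES = (
    "A>C/T>G",
    "A>G/T>C",
    "A>T/T>A",
    "C>A/G>T",
    "C>G/G>C",
    "C>T/G>A",
)

_CLASS_BY_PAIR: dict[tuple[str, str], str] = {}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
for _cls in SUBSTITUTION_CLASSES:
    _fwd = _cls.split("/")[0]
    _r, _a = _fwd.split(">")
    _CLASS_BY_PAIR[(_r, _a)] = _cls
    _CLASS_BY_PAIR[(_COMP[_r], _COMP[_a])] = _cls


def substitution_class(ref_base: str, alt_base: str) -> str:
    """Strand-collapsed class of a single-base substitution, e.g. 'C>A/G>T'."""
    return _CLASS_BY_PAIR[(ref_base, alt_base)]


@dataclass(frozen=True)
class ErrorProfile:
    """Substitution error rates and base-quality model for one library.

    ``fragment_rates`` maps each of the six substitution classes to a
    per-applicable-base probability (a C can err via C>A, C>G or C>T, so its
    total error rate is the sum of those three class rates). Rates must lie
    in [0, 0.05]. Defaults emulate the empirical bias of Illumina NC
    libraries: (C>A, G>T) and (C>T, G>A) elevated over the other classes.
    """

    fragment_rates: dict[str, float] = field(
        default_factory=lambda: {
            "A>C/T>G": 2e-5,
            "A>G/T>C": 4e-5,
            "A>T/T>A": 2e-5,
            "C>A/G>T": 4e-4,
            "C>G/G>C": 3e-5,
            "C>T/G>A": 3e-4,
        }
    )
    read_error_rate: float = 1e-4
    primer_error_rate: float = 0.0
    bq_mean: float = 38.0
    bq_sd: float = 1.2
    bq_per_cycle_decay: float = 0.015
    error_bq_mean: float = 31.0
    error_bq_sd: float = 2.5

    def __post_init__(self) -> None:
        keys = set(self.fragment_rates)
        if keys != set(SUBSTITUTION_CLASSES):
            raise ValueError(f"rates must cover exactly the classes {SUBSTITUTION_CLASSES}")
        for cls, rate in self.fragment_rates.items():
            if not 0.0 <= rate <= 0.05:
                raise ValueError(f"rate for {cls} outside [0, 0.05]: {rate}")

    @classmethod
    def error_free(cls) -> "ErrorProfile":
        return cls(
            fragment_rates={c: 0.0 for c in SUBSTITUTION_CLASSES},
            read_error_rate=0.0,
            primer_error_rate=0.0,
            bq_per_cycle_decay=0.0,
            bq_sd=0.0,
        )


@dataclass(frozen=True)
class PrimerInterval:
    """0-based half-open primer footprint on the transcript."""

    contig: str
    start: int
    end: int
    strand: str
    name: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("primer start must be < end")
        if self.strand not in "+-":
            raise ValueError("primer strand must be + or -")


def write_primer_bed(primers: list[PrimerInterval], path: str) -> str:
    with open(path, "w") as fh:
        for p in primers:
            fh.write(f"{p.contig}\t{p.start}\t{p.end}\t{p.name}\t0\t{p.strand}\n")
    return path


def read_primer_bed(path: str) -> list[PrimerInterval]:
    primers = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            primers.append(
                PrimerInterval(f[0], int(f[1]), int(f[2]), f[5], f[3] if len(f) > 3 else ".")
            )
    return primers


@dataclass(frozen=True)
class LibraryDesign:
    """Fragment layout of a targeted sequencing library.

    ``amplicon``: fragments are full PCR tiles with primers at both ends.
    ``race_like``: one gene-specific primer anchors the fragment 5' end;
    the other end varies with fragment length.
    """

    method: str  # amplicon | race_like
    tiles: tuple[tuple[int, int], ...] = ()  # amplicon fragment spans
    gsp_starts: tuple[int, ...] = ()  # RACE-like gene-specific primer starts
    primer_length: int = 20
    read_length: int = 150
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 25.0
    fragment_length_min: int = 150
    fragment_length_max: int = 250
    umi_length: int = 0
    duplication_rate: float = 0.0  # expected extra PCR copies per fragment
    with_primers: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("amplicon", "race_like"):
            raise ValueError("method must be 'amplicon' or 'race_like'")
        if self.read_length < self.primer_length and self.with_primers:
            raise ValueError("read length must be >= primer length")

    def primers(self, contig: str) -> list[PrimerInterval]:
        out: list[PrimerInterval] = []
        if not self.with_primers:
            return out
        if self.method == "amplicon":
            for i, (s, e) in enumerate(self.tiles):
                out.append(PrimerInterval(contig, s, s + self.primer_length, "+", f"tile{i}_F"))
                out.append(PrimerInterval(contig, e - self.primer_length, e, "-", f"tile{i}_R"))
        else:
            for i, s in enumerate(self.gsp_starts):
                out.append(PrimerInterval(contig, s, s + self.primer_length, "+", f"gsp{i}"))
        return out


def amplicon_design(
    ref: TranscriptReference,
    tile_length: int = 150,
    primer_length: int = 20,
    overlap: int = 30,
    **kw,
) -> LibraryDesign:
    """Tile the whole transcript with overlapping amplicons."""
    tiles = []
    step = tile_length - overlap
    start = 0
    while start + tile_length <= len(ref):
        tiles.append((start, start + tile_length))
        start += step
    if not tiles or tiles[-1][1] < len(ref):
        tiles.append((max(0, len(ref) - tile_length), len(ref)))
    return LibraryDesign(
        method="amplicon",
        tiles=tuple(tiles),
        primer_length=primer_length,
        read_length=max(tile_length, kw.pop("read_length", tile_length)),
        **kw,
    )


def full_overlap_design(window: tuple[int, int]) -> LibraryDesign:
    """Single primer-free tile with fragment length == read length.

    Both mates then cover every fragment position, so every planted variant
    is callable under strict mate concordance.
    """
    start, end = window
    return LibraryDesign(
        method="amplicon",
        tiles=((start, end),),
        read_length=end - start,
        with_primers=False,
    )


def make_reference(
    length_codons: int,
    seed: int,
    transcript_id: str = "synthetic_tx",
    utr5: int = 18,
    utr3: int = 18,
) -> TranscriptReference:
    """Random CDS of ``length_codons`` codons (ATG ... stop, no internal stops)
    flanked by short UTRs."""
    if length_codons < 10:
        raise ValueError("reference must be at least 10 codons")
    rng = np.random.default_rng(seed)
    sense_codons = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
    body = [sense_codons[i] for i in rng.integers(0, len(sense_codons), length_codons - 2)]
    stop = ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
    cds = "ATG" + "".join(body) + stop
    bases = "ACGT"
    utr5_seq = "".join(bases[i] for i in rng.integers(0, 4, utr5))
    utr3_seq = "".join(bases[i] for i in rng.integers(0, 4, utr3))
    return TranscriptReference(
        transcript_id, utr5_seq + cds + utr3_seq, utr5, utr5 + 3 * length_codons
    )


@dataclass
class SimulatedLibrary:
    fastq_r1: str
    fastq_r2: str
    fragments: pd.DataFrame  # fragment_id, start, end, umi, n_copies, flipped
    errors: pd.DataFrame  # fragment_id, copy, channel, ref_pos, ref_base, alt_base, subst_class, mate
    primers: list[PrimerInterval]
    primer_bed: str | None = None


def _draw_quals(rng, n, profile: ErrorProfile) -> np.ndarray:
    cycles = np.arange(n)
    q = rng.normal(profile.bq_mean - profile.bq_per_cycle_decay * cycles, profile.bq_sd)
    return np.clip(np.rint(q), 2, 41).astype(int)


def _error_quals(rng, n, profile: ErrorProfile) -> np.ndarray:
    q = rng.normal(profile.error_bq_mean, profile.error_bq_sd, size=n)
    return np.clip(np.rint(q), 2, 41).astype(int)


_ALT_CHOICES = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


def _inject_substitutions(rng, seq: list[str], positions: np.ndarray, rates, records, **meta):
    """Mutate ``seq`` (fragment-local list) at eligible positions per class rates."""
    for i in positions:
        base = seq[i]
        classes = [(alt, rates[substitution_class(base, alt)]) for alt in _ALT_CHOICES[base]]
        total = sum(r for _, r in classes)
        if total <= 0.0:
            continue
        u = rng.random()
        if u >= total:
            continue
        acc = 0.0
        for alt, r in classes:
            acc += r
            if u < acc:
                records.append(
                    dict(
                        ref_pos=meta["offset"] + i,
                        ref_base=base,
                        alt_base=alt,
                        subst_class=substitution_class(base, alt),
                        **{k: v for k, v in meta.items() if k != "offset"},
                    )
                )
                seq[i] = alt
                break


def _open_fq(path: str):
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def simulate_library(
    ref: TranscriptReference,
    design: LibraryDesign,
    n_fragments: int,
    profile: ErrorProfile,
    seed: int,
    out_dir: str,
    prefix: str = "library",
) -> SimulatedLibrary:
    """Simulate ``n_fragments`` sequenced fragments and write a FASTQ pair.

    With an all-zero :class:`ErrorProfile` every read is an exact substring
    of the reference (or its reverse complement).
    """
    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)
    contig = ref.transcript_id
    primers = design.primers(contig)
    primer_bed = None
    if primers:
        primer_bed = write_primer_bed(primers, os.path.join(out_dir, f"{prefix}_primers.bed"))

    fq1_path = os.path.join(out_dir, f"{prefix}_R1.fastq.gz")
    fq2_path = os.path.join(out_dir, f"{prefix}_R2.fastq.gz")
    frag_rows: list[dict] = []
    err_rows: list[dict] = []
    qual_chars = np.array([chr(33 + q) for q in range(50)])

    with _open_fq(fq1_path) as fq1, _open_fq(fq2_path) as fq2:
        for fi in range(n_fragments):
            if design.method == "amplicon":
                start, end = design.tiles[rng.integers(0, len(design.tiles))]
            else:
                start = design.gsp_starts[rng.integers(0, len(design.gsp_starts))]
                flen = int(
                    np.clip(
                        rng.normal(design.fragment_length_mean, design.fragment_length_sd),
                        design.fragment_length_min,
                        design.fragment_length_max,
                    )
                )
                end = min(start + flen, len(ref))
            frag_id = f"F{fi:06d}"
            frag = list(ref.sequence[start:end])
            flen = end - start

            # synthetic primer spans in fragment-local coordinates
            primer_local: set[int] = set()
            for p in primers:
                if p.start < end and p.end > start and (p.start == start or p.end == end):
                    primer_local.update(
                        range(max(p.start, start) - start, min(p.end, end) - start)
                    )
            template_positions = np.array(
                [i for i in range(flen) if i not in primer_local], dtype=int
            )

            # fragment-level (PCR/RT-like) errors: shared by all copies & mates
            _inject_substitutions(
                rng, frag, template_positions, profile.fragment_rates, err_rows,
                offset=start, fragment_id=frag_id, copy=-1, channel="fragment", mate="both",
            )
            if profile.primer_error_rate > 0 and primer_local:
                plocal = np.array(sorted(primer_local), dtype=int)
                hit = plocal[rng.random(len(plocal)) < profile.primer_error_rate]
                for i in hit:
                    alt = _ALT_CHOICES[frag[i]][rng.integers(0, 3)]
                    err_rows.append(
                        dict(
                            ref_pos=start + i, ref_base=frag[i], alt_base=alt,
                            subst_class=substitution_class(frag[i], alt),
                            fragment_id=frag_id, copy=-1, channel="primer", mate="both",
                        )
                    )
                    frag[i] = alt
            frag_seq = "".join(frag)
            frag_err_local = {
                r["ref_pos"] - start for r in err_rows if r["fragment_id"] == frag_id
            }

            umi = ""
            if design.umi_length:
                umi = "".join("ACGT"[b] for b in rng.integers(0, 4, design.umi_length))
            n_copies = 1 + (
                rng.poisson(design.duplication_rate) if design.duplication_rate > 0 else 0
            )
            frag_rows.append(
                dict(fragment_id=frag_id, start=start, end=end, umi=umi, n_copies=n_copies)
            )

            r1_len = min(design.read_length, flen)
            r2_len = min(design.read_length, flen)
            for ci in range(n_copies):
                name = f"{frag_id}.{ci}"
                # R1 reads the fragment 5' end on the + strand, R2 the 3' end reversed
                r1 = list(frag_seq[:r1_len])
                r2_local0 = flen - r2_len  # fragment-local start of R2 window
                r2_fwd = list(frag_seq[r2_local0:])
                if profile.read_error_rate > 0:
                    for mate, seq_l, off in (("R1", r1, 0), ("R2", r2_fwd, r2_local0)):
                        hit = np.flatnonzero(rng.random(len(seq_l)) < profile.read_error_rate)
                        for i in hit:
                            if i + off in primer_local:
                                continue
                            alt = _ALT_CHOICES[seq_l[i]][rng.integers(0, 3)]
                            err_rows.append(
                                dict(
                                    ref_pos=start + off + i, ref_base=seq_l[i], alt_base=alt,
                                    subst_class=substitution_class(seq_l[i], alt),
                                    fragment_id=frag_id, copy=ci, channel="read", mate=mate,
                                )
                            )
                            seq_l[i] = alt
                q1 = _draw_quals(rng, r1_len, profile)
                q2 = _draw_quals(rng, r2_len, profile)
                # error bases (any channel) carry lower qualities
                for i in range(r1_len):
                    if i in frag_err_local and q1[i] > 2 and frag_seq[i] != ref.sequence[start + i]:
                        q1[i] = _error_quals(rng, 1, profile)[0]
                for i in range(r2_len):
                    loc = r2_local0 + i
                    if loc in frag_err_local and frag_seq[loc] != ref.sequence[start + loc]:
                        q2[i] = _error_quals(rng, 1, profile)[0]

                r1_seq = "".join(r1)
                r2_seq = revcomp("".join(r2_fwd))[:r2_len]
                q2_out = q2[::-1]
                if umi:
                    r1_seq = umi + r1_seq
                    q1 = np.concatenate([np.full(len(umi), 37, dtype=int), q1])
                fq1.write(f"@{name}\n{r1_seq}\n+\n{''.join(qual_chars[q1])}\n")
                fq2.write(f"@{name}\n{r2_seq}\n+\n{''.join(qual_chars[q2_out])}\n")

    fragments = pd.DataFrame(
        frag_rows, columns=["fragment_id", "start", "end", "umi", "n_copies"]
    )
    errors = pd.DataFrame(
        err_rows,
        columns=[
            "fragment_id", "copy", "channel", "mate",
            "ref_pos", "ref_base", "alt_base", "subst_class",
        ],
    )
    return SimulatedLibrary(
        fastq_r1=fq1_path,
        fastq_r2=fq2_path,
        fragments=fragments,
        errors=errors,
        primers=primers,
        primer_bed=primer_bed,
    )


def random_variant_specs(
    ref: TranscriptReference,
    window: tuple[int, int],
    n_variants: int,
    seed: int,
    snp_proportion: float = 0.25,
    margin: int = 10,
    frequencies=None,
    target_count: int | None = None,
):
    """Draw distinct, minimal SNP/MNP specs inside ``window`` (0-based half-open).

    Alleles are minimal representations: the first and last allele base each
    differ from the reference, so the caller's variant key matches the spec
    exactly. SNP fraction defaults to 0.25 with di/tri splitting the rest
    evenly. ``frequencies`` may be a sequence to resample target frequencies
    from (defaults to 1e-3).
    """
    from .sim import VariantSpec  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    wstart, wend = window
    lo = max(wstart + margin, ref.cds_start)
    specs: dict[tuple[int, str, str], VariantSpec] = {}
    type_lengths = np.array([1, 2, 3])
    probs = np.array([snp_proportion, (1 - snp_proportion) / 2, (1 - snp_proportion) / 2])
    attempts = 0
    while len(specs) < n_variants:
        attempts += 1
        if attempts > 200 * n_variants:
            raise RuntimeError(
                f"could not place {n_variants} distinct variants in window {window}"
            )
        length = int(rng.choice(type_lengths, p=probs))
        hi = min(wend - margin, ref.cds_end) - length
        if hi <= lo:
            continue
        pos0 = int(rng.integers(lo, hi))
        ref_allele = ref.sequence[pos0 : pos0 + length]
        alt = [b for b in ref_allele]
        for i in range(length):
            if i in (0, length - 1):
                alt[i] = _ALT_CHOICES[alt[i]][rng.integers(0, 3)]
            elif rng.random() < 0.5:
                alt[i] = _ALT_CHOICES[alt[i]][rng.integers(0, 3)]
        alt_allele = "".join(alt)
        key = (pos0, ref_allele, alt_allele)
        if key in specs:
            continue
        if frequencies is not None:
            freq = float(frequencies[rng.integers(0, len(frequencies))])
        else:
            freq = 1e-3
        specs[key] = VariantSpec(
            pos=pos0 + 1,
            ref_allele=ref_allele,
            alt_allele=alt_allele,
            target_frequency=freq,
            target_count=target_count,
        )
    return sorted(specs.values(), key=lambda s: (s.pos, s.alt_allele))


@dataclass
class ValidationDataset:
    reference: TranscriptReference
    ref_fasta: str
    fastq_r1: str
    fastq_r2: str
    truth_vcf: str
    background_bam: str
    window: tuple[int, int]
    truth_records: list


def build_validation_dataset(
    out_dir: str,
    seed: int,
    ref: TranscriptReference | None = None,
    n_pairs: int = 10_000,
    n_variants: int = 187,
    per_variant_pairs: int = 10,
    snp_proportion: float = 0.25,
    aligner_config=None,
) -> ValidationDataset:
    """Error-free background of ``n_pairs`` read pairs with ``n_variants``
    distinct SNP/MNP variants each edited into exactly ``per_variant_pairs``
    pairs (default 10 in 10,000 -> truth frequency 1e-3).

    All fragments share one full-overlap 150-nt window inside the CDS so
    fragment coverage is exactly ``n_pairs`` at every variant position and
    every planted variant is recoverable under strict mate concordance.
    """
    from . import sim as sim_mod
    from .align import align_pairs

    os.makedirs(out_dir, exist_ok=True)
    if ref is None:
        ref = make_reference(64, seed=seed + 101)
    window_len = 150
    wstart = ref.cds_start + ((len(ref.cds_sequence) - window_len) // 2 // 3) * 3
    window = (wstart, wstart + window_len)
    need = n_variants * per_variant_pairs
    if need > n_pairs:
        raise ValueError("not enough read pairs to host all variants")

    ref_fasta = ref.to_fasta(os.path.join(out_dir, "reference.fa"))
    lib = simulate_library(
        ref,
        full_overlap_design(window),
        n_fragments=n_pairs,
        profile=ErrorProfile.error_free(),
        seed=seed + 1,
        out_dir=out_dir,
        prefix="background",
    )
    bg_bam = align_pairs(
        lib.fastq_r1, lib.fastq_r2, ref_fasta,
        os.path.join(out_dir, "background.bam"), aligner_config,
    )
    specs = random_variant_specs(
        ref, window, n_variants, seed=seed + 2,
        snp_proportion=snp_proportion, target_count=per_variant_pairs,
    )
    plan = sim_mod.plan_edits(specs, bg_bam, ref, seed=seed + 3, conversion_buffer=3)
    unplaced = [t for t in plan.truth_records if t.unplaceable]
    if unplaced:
        raise RuntimeError(
            "could not place variants: "
            + ", ".join(f"{t.spec.pos}{t.spec.ref_allele}>{t.spec.alt_allele}" for t in unplaced)
        )
    fq1 = os.path.join(out_dir, "edited_R1.fastq.gz")
    fq2 = os.path.join(out_dir, "edited_R2.fastq.gz")
    truth_vcf = os.path.join(out_dir, "truth.vcf")
    truth = sim_mod.apply_edits(plan, bg_bam, ref, fq1, fq2, truth_vcf)
    return ValidationDataset(
        reference=ref,
        ref_fasta=ref_fasta,
        fastq_r1=fq1,
        fastq_r2=fq2,
        truth_vcf=truth_vcf,
        background_bam=bg_bam,
        window=window,
        truth_records=truth,
    )
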