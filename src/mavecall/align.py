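"""External aligner and trimmer invocation.

All external commands run through a single command-template configuration so
a different aligner can be swapped in without touching the pipeline. The
default uses ``bwa mem`` for paired-end local alignment of short reads
against the transcript reference, followed by samtools-compatible sort and
index via pysam.
"""

from __future__ import annotations

import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field

import pysam


class AlignerUnavailableError(RuntimeError):
    pass


@dataclass
class AlignerConfig:
    """Command templates for indexing and paired-end alignment.

    Templates are argument lists with ``{ref}``, ``{fq1}``, ``{fq2}``
    placeholders; alignment output must be SAM on stdout.
    """

    index_cmd: tuple[str, ...] = ("bwa", "index", "{ref}")
    align_cmd: tuple[str, ...] = ("bwa", "mem", "-t", "1", "{ref}", "{fq1}", "{fq2}")
    # optional read trimmer (e.g. fastp); None disables trimming
    trim_cmd: tuple[str, ...] | None = None

    def executable(self) -> str:
        return self.align_cmd[0]

    def check_available(self) -> None:
        for cmd in (self.index_cmd[0], self.align_cmd[0]):
            if shutil.which(cmd) is None:
                raise AlignerUnavailableError(
                    f"external aligner command {cmd!r} not found on PATH"
                )


def _fill(template: tuple[str, ...], **kw: str) -> list[str]:
    return [part.format(**kw) for part in template]


def ensure_index(ref_fasta: str, config: AlignerConfig) -> None:
    config.check_available()
    # bwa index sentinel; other aligners simply re-index
    if config.index_cmd[0] == "bwa" and os.path.exists(ref_fasta + ".bwt"):
        return
    subprocess.run(
        _fill(config.index_cmd, ref=ref_fasta),
        check=True,
        capture_output=True,
    )


def align_pairs(
    fq1: str,
    fq2: str,
    ref_fasta: str,
    out_bam: str,
    config: AlignerConfig | None = None,
) -> str:
    """Align a FASTQ pair, producing a coordinate-sorted, indexed BAM."""
    config = config or AlignerConfig()
    ensure_index(ref_fasta, config)
    with tempfile.TemporaryDirectory() as tmp:
        sam_path = os.path.join(tmp, "aln.sam")
        with open(sam_path, "wb") as sam_fh:
            proc = subprocess.run(
                _fill(config.align_cmd, ref=ref_fasta, fq1=fq1, fq2=fq2),
                stdout=sam_fh,
                stderr=subprocess.PIPE,
            )
        if proc.returncode != 0:
            raise RuntimeError(
                f"alignment failed ({config.executable()}): "
                + proc.stderr.decode(errors="replace")[-2000:]
            )
        pysam.sort("-o", out_bam, sam_path, catch_stdout=False)
    pysam.index(out_bam)
    return out_bam


def write_bam(
    reads,
    header: pysam.AlignmentHeader,
    out_bam: str,
    sort: bool = True,
) -> str:
    """Write segments to BAM, optionally coordinate-sorting and indexing."""
    with tempfile.TemporaryDirectory() as tmp:
        raw = os.path.join(tmp, "raw.bam")
        with pysam.AlignmentFile(raw, "wb", header=header) as out:
            for read in reads:
                out.write(read)
        if sort:
            pysam.sort("-o", out_bam, raw, catch_stdout=False)
            pysam.index(out_bam)
        else:
            shutil.copyfile(raw, out_bam)
    return out_bam


@dataclass
class StageLog:
    """Read/fragment counts surviving each pipeline stage, in order."""

    stages: list[tuple[str, int]] = field(default_factory=list)

    def record(self, name: str, count: int) -> None:
        self.stages.append((name, count))

    def as_dict(self) -> dict[str, int]:
        return dict(self.stages)
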