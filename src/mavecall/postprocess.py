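"""Post-calling filter chain and negative-control background subtraction.

Prepares per-replicate variant tables for downstream differential-abundance
statistics (which are out of scope here: the cleaned tables export to
generic count layouts consumable by external tools).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .call import VariantCall

CRITERIA = (
    "in_target_region",
    "matches_signature",
    "single_codon",
    "min_count",
    "strand_bias",
    "rf_prediction",
    "in_all_replicates",
)


@dataclass(frozen=True)
class FilterConfig:
    """Sequential variant selection criteria.

    Defaults follow the standard chain: (1) inside the mutagenized target
    region; (2) matches the NNK signature; (3) single-codon change; (4)
    SNP count >= 2 and MNP count >= 1; (5) strand count difference <= 64
    (RACE-like only); (6) not predicted an error by the classifier in all
    replicates (probability cutoff 0.49); (7) observed in all replicates.
    """

    target_region: tuple[int, int] | None = None  # 0-based half-open
    require_signature: bool = True
    single_codon_only: bool = True
    min_snp_count: int = 2
    min_mnp_count: int = 1
    max_strand_diff: int = 64
    race_like: bool = False
    rf_cutoff: float = 0.49
    require_all_replicates: bool = True

    def __post_init__(self) -> None:
        if min(self.min_snp_count, self.min_mnp_count) < 0 or self.max_strand_diff < 0:
            raise ValueError("thresholds must be non-negative")


def calls_to_table(calls: list[VariantCall], replicate: str = "rep1") -> pd.DataFrame:
    """Flatten VariantCall objects into a per-replicate record table."""
    rows = []
    for c in calls:
        ann = c.annotation
        rows.append(
            dict(
                replicate=replicate,
                pos=ann.pos,
                ref=ann.ref_allele,
                alt=ann.alt_allele,
                variant_type=ann.variant_type,
                count=c.supporting_count,
                coverage=c.fragment_coverage,
                frequency=c.frequency,
                matches_signature=bool(c.matches_signature),
                multi_codon=bool(ann.multi_codon),
                in_cds=bool(ann.alt_codons),
                strand_plus=c.strand_counts.get("+", 0),
                strand_minus=c.strand_counts.get("-", 0),
            )
        )
    cols = [
        "replicate", "pos", "ref", "alt", "variant_type", "count", "coverage",
        "frequency", "matches_signature", "multi_codon", "in_cds",
        "strand_plus", "strand_minus",
    ]
    return pd.DataFrame(rows, columns=cols)


NC_ABSENT = "nc_absent"
NC_DOMINATED = "nc_dominated"
NC_ADJUSTED = "adjusted"


def subtract_nc_background(
    mut_table: pd.DataFrame, nc_table: pd.DataFrame
) -> pd.DataFrame:
    """Adjust frequencies by the matching NC-library variant.

    For each mutagenized call with an identical-allele NC call, records
    ``nc_adjusted_log10_frequency`` = log10(f_mut) - log10(f_nc); variants
    absent from the NC carry adjustment 0.0 flagged ``nc_absent``; variants
    whose NC frequency meets or exceeds the call frequency are flagged
    ``nc_dominated`` (fully explained by background when equal).
    """
    nc_freq = {
        (r.pos, r.ref, r.alt): r.frequency for r in nc_table.itertuples(index=False)
    }
    out = mut_table.copy()
    adjustments, flags = [], []
    for r in out.itertuples(index=False):
        f_nc = nc_freq.get((r.pos, r.ref, r.alt))
        if f_nc is None:
            adjustments.append(0.0)
            flags.append(NC_ABSENT)
        else:
            adj = math.log10(r.frequency) - math.log10(f_nc)
            adjustments.append(adj)
            flags.append(NC_ADJUSTED if f_nc < r.frequency else NC_DOMINATED)
    out["nc_adjusted_log10_frequency"] = adjustments
    out["nc_flag"] = flags
    return out


def apply_filter_chain(
    replicate_tables: list[pd.DataFrame],
    config: FilterConfig,
    error_probabilities: dict | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the seven criteria in their stated order.

    ``replicate_tables`` are per-replicate call tables (from
    :func:`calls_to_table`). ``error_probabilities`` maps
    (replicate, pos, ref, alt) -> predicted-error probability and is
    required when ``rf_cutoff`` filtering is active (criterion 6 is skipped
    when the mapping is None only if the config disables it by setting
    ``rf_cutoff`` >= 1). Returns the surviving union table plus per-
    criterion attrition counts (records removed, summing to in - out).
    """
    if not replicate_tables:
        raise ValueError("at least one replicate table is required")
    table = pd.concat(replicate_tables, ignore_index=True)
    n_replicates = table["replicate"].nunique()
    attrition: dict[str, int] = {}

    def drop(mask_keep: pd.Series, criterion: str) -> None:
        nonlocal table
        removed = int((~mask_keep).sum())
        attrition[criterion] = removed
        table = table[mask_keep].reset_index(drop=True)

    # (1) inside the mutagenized target region
    if config.target_region is not None:
        lo, hi = config.target_region
        keep = (table["pos"] - 1 >= lo) & (table["pos"] - 1 < hi)
    else:
        keep = pd.Series(True, index=table.index)
    drop(keep, "in_target_region")

    # (2) NNK mutagenesis signature
    keep = table["matches_signature"] if config.require_signature else pd.Series(
        True, index=table.index
    )
    drop(keep.astype(bool), "matches_signature")

    # (3) single-codon change
    keep = ~table["multi_codon"] if config.single_codon_only else pd.Series(
        True, index=table.index
    )
    drop(keep.astype(bool), "single_codon")

    # (4) SNP count >= min_snp_count, MNP count >= min_mnp_count
    is_snp = table["variant_type"] == "SNP"
    keep = (is_snp & (table["count"] >= config.min_snp_count)) | (
        ~is_snp & (table["count"] >= config.min_mnp_count)
    )
    drop(keep, "min_count")

    # (5) strand bias (RACE-like only)
    if config.race_like:
        diff = (table["strand_plus"] - table["strand_minus"]).abs()
        keep = diff <= config.max_strand_diff
    else:
        keep = pd.Series(True, index=table.index)
    drop(keep, "strand_bias")

    # (6) classifier predictions: drop variants predicted error in ALL replicates
    if error_probabilities is not None:
        def predicted_error(row) -> bool:
            p = error_probabilities.get((row.replicate, row.pos, row.ref, row.alt))
            return p is not None and p > config.rf_cutoff

        flags = table.apply(predicted_error, axis=1) if len(table) else pd.Series(dtype=bool)
        all_error = (
            flags.groupby([table["pos"], table["ref"], table["alt"]]).transform("all")
            if len(table)
            else flags
        )
        keep = ~all_error
    elif config.rf_cutoff < 1.0 and len(table):
        raise ValueError("criterion 6 requires error probabilities (or rf_cutoff >= 1)")
    else:
        keep = pd.Series(True, index=table.index)
    drop(keep.astype(bool), "rf_prediction")

    # (7) observed in all replicates
    if config.require_all_replicates and len(table):
        reps_per_variant = table.groupby(["pos", "ref", "alt"])["replicate"].transform(
            "nunique"
        )
        keep = reps_per_variant == n_replicates
    else:
        keep = pd.Series(True, index=table.index)
    drop(keep.astype(bool), "in_all_replicates")

    return table, attrition


def export_counts(table: pd.DataFrame, path: str) -> str:
    """Variant x replicate count matrix in a generic layout for external tools."""
    wide = table.pivot_table(
        index=["pos", "ref", "alt"], columns="replicate", values="count",
        aggfunc="first", fill_value=0,
    )
    wide.to_csv(path, sep="\t")
    return path


@dataclass
class BenchmarkResult:
    n_truth: int
    n_called: int
    n_true_positive: int

    @property
    def sensitivity(self) -> float:
        return self.n_true_positive / self.n_truth if self.n_truth else math.nan

    @property
    def precision(self) -> float:
        return self.n_true_positive / self.n_called if self.n_called else math.nan


def benchmark_calls(
    called_keys: set[tuple[int, str, str]], truth_keys: set[tuple[int, str, str]]
) -> BenchmarkResult:
    """Nucleotide-level sensitivity/precision of a call set against truth."""
    return BenchmarkResult(
        n_truth=len(truth_keys),
        n_called=len(called_keys),
        n_true_positive=len(called_keys & truth_keys),
    )
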