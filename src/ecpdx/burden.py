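"""Burden metrics: TMB, MSI score, and copy-number alteration burden.

TMB counts all somatic small-variant classes (SNV, MNV, indel) per callable
megabase.  The MSI score is the percentage of assessed microsatellite panel
sites called somatically unstable; samples at or above 3% are treated as
microsatellite unstable downstream.  CNA burden is measured against an
absolute diploid-heterozygous baseline (total 2, minor 1): any other
allele-specific state counts as altered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .core import AllelicSegment, GenomeBuild, MicrosatellitePanelResult, SomaticVariant

__all__ = ["BurdenSummary", "compute_tmb", "compute_msi_score", "compute_cna_burden",
           "summarize_burden"]

DIPLOID_STATE = (2, 1)


@dataclass(frozen=True)
class BurdenSummary:
    tmb: float            # mutations per callable Mb
    msi_score: float      # percent unstable panel sites
    pct_cna: float        # percent of segmented genome in a non-(2,1) state
    n_cna_segments: int   # altered segments after merging same-state runs


def compute_tmb(variants: list[SomaticVariant], callable_mb: float) -> float:
    """Somatic mutations per callable megabase (all variant classes)."""
    if callable_mb <= 0:
        raise ValueError("callable_mb must be positive")
    return len(variants) / callable_mb


def compute_msi_score(ms: MicrosatellitePanelResult) -> float:
    """Percent of assessed microsatellite sites somatically unstable."""
    if ms.n_assessed == 0:
        raise ValueError("no microsatellite sites assessed")
    return 100.0 * ms.n_unstable / ms.n_assessed


def _merged_runs(segments: list[AllelicSegment]) -> list[tuple[str, tuple[int, int], int, int, int]]:
    """Merge consecutive same-state segments per chromosome.

    Returns (chrom, state, run_start, run_end, covered_bp) tuples; coverage
    gaps do not break a run of identical state, and covered_bp sums member
    lengths so the result is invariant to splitting a segment in two.
    """
    out = []
    by_chrom: dict[str, list[AllelicSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in sorted(by_chrom):
        segs = sorted(by_chrom[chrom], key=lambda s: s.start_bp)
        cur = None
        for s in segs:
            if cur is not None and cur[1] == s.state:
                cur = (chrom, s.state, cur[2], s.end_bp, cur[4] + s.length_bp)
            else:
                if cur is not None:
                    out.append(cur)
                cur = (chrom, s.state, s.start_bp, s.end_bp, s.length_bp)
        if cur is not None:
            out.append(cur)
    return out


def compute_cna_burden(segments: list[AllelicSegment],
                       genome: GenomeBuild | None = None) -> tuple[float, int]:
    """(percent of segmented genome altered, number of merged altered segments).

    A segment is altered iff its (total, minor) state differs from (2, 1).
    The denominator is the total segmented length; unsegmented genome is
    excluded rather than assumed diploid.
    """
    if not segments:
        warnings.warn("no segments supplied; CNA burden reported as (0, 0)")
        return 0.0, 0
    runs = _merged_runs(segments)
    total_bp = sum(r[4] for r in runs)
    altered = [r for r in runs if r[1] != DIPLOID_STATE]
    altered_bp = sum(r[4] for r in altered)
    return 100.0 * altered_bp / total_bp, len(altered)


def summarize_burden(variants: list[SomaticVariant], callable_mb: float,
                     ms: MicrosatellitePanelResult | None,
                     segments: list[AllelicSegment],
                     genome: GenomeBuild | None = None) -> BurdenSummary:
    """All three burden axes for one sample in a single summary row."""
    pct, n = compute_cna_burden(segments, genome) if segments else (0.0, 0)
    return BurdenSummary(
        tmb=compute_tmb(variants, callable_mb),
        msi_score=compute_msi_score(ms) if ms is not None else float("nan"),
        pct_cna=pct,
        n_cna_segments=n,
    )
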