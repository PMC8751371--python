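"""Homologous-recombination-deficiency genomic scars from allele-specific
copy-number segments.

Three scar components are counted and summed, and the sum compared against
the established >=42 positivity threshold for HRD in breast/ovarian cancer:

* **HRD-LOH** — loss-of-heterozygosity regions (minor copy number 0, total
  copy number >= 1) longer than 15 Mb, excluding whole-chromosome LOH.
* **LST** (large-scale state transitions) — per chromosome arm, after
  smoothing away segments shorter than 3 Mb, the number of breakpoints
  between adjacent segments that are both at least 10 Mb but in different
  allele-specific states.
* **NtAI** (telomeric allelic imbalance) — runs of allelic imbalance
  (minor != major) that reach a chromosome end without crossing the
  centromere.

Conventions: arms are split at the centromere midpoint; merged runs measure
length as the sum of member segment lengths (invariant to splitting a
segment into same-state pieces); whole-chromosome LOH is operationalized as
a run spanning >= 90% of the chromosome.  No ploidy renormalization is
applied under whole-genome duplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .core import AllelicSegment, GenomeBuild, SampleProfile, SomaticVariant
from .signatures import ExposureEstimate

__all__ = [
    "HrdScore",
    "HrdEvidence",
    "compute_hrd_loh",
    "compute_lst",
    "compute_ntai",
    "score_hrd",
    "summarize_hrd_evidence",
    "DEFAULT_HR_GENES",
    "PARP_ASSOCIATED_GENES",
]

HRD_LOH_MIN_MB = 15.0
LST_SMOOTH_MB = 3.0
LST_MIN_SEGMENT_MB = 10.0
WHOLE_CHROM_LOH_FRACTION = 0.90
HRD_SUM_THRESHOLD = 42

DEFAULT_HR_GENES = (
    "BRCA1", "BRCA2", "PALB2", "RAD51C", "RAD51D", "BRIP1", "ATM", "CHEK2",
    "MRE11A", "NBN", "RAD51B",
)
# PARPi-sensitivity-associated genes reported alongside, not HR genes proper
PARP_ASSOCIATED_GENES = ("PTEN", "ARID1A")


@dataclass(frozen=True)
class HrdScore:
    ntai: int
    lst: int
    hrd_loh: int
    threshold: int = HRD_SUM_THRESHOLD

    @property
    def sum(self) -> int:
        return self.ntai + self.lst + self.hrd_loh

    @property
    def hrd_call(self) -> bool:
        return self.sum >= self.threshold


def _sorted_by_chrom(segments: list[AllelicSegment]) -> dict[str, list[AllelicSegment]]:
    by_chrom: dict[str, list[AllelicSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    return {c: sorted(v, key=lambda s: s.start_bp) for c, v in sorted(by_chrom.items())}


def compute_hrd_loh(segments: list[AllelicSegment], genome: GenomeBuild) -> int:
    """Count merged LOH runs with summed length > 15 Mb, excluding runs
    spanning >= 90% of their chromosome."""
    count = 0
    for chrom, segs in _sorted_by_chrom(segments).items():
        clen = genome.chromosome(chrom).length_bp
        runs: list[tuple[int, int, int]] = []  # (start, end, covered_bp)
        cur: Optional[tuple[int, int, int]] = None
        for s in segs:
            is_loh = s.minor_cn == 0 and s.total_cn >= 1
            if is_loh:
                if cur is None:
                    cur = (s.start_bp, s.end_bp, s.length_bp)
                else:
                    cur = (cur[0], s.end_bp, cur[2] + s.length_bp)
            else:
                if cur is not None:
                    runs.append(cur)
                    cur = None
        if cur is not None:
            runs.append(cur)
        for start, end, covered in runs:
            span = end - start + 1
            if covered > HRD_LOH_MIN_MB * 1e6 and span < WHOLE_CHROM_LOH_FRACTION * clen:
                count += 1
    return count


def _clip_to_arm(segs: list[AllelicSegment], arm_start: int, arm_end: int
                 ) -> list[tuple[tuple[int, int], int]]:
    """Segments intersected with [arm_start, arm_end] (1-based inclusive),
    as (state, clipped_length) in position order."""
    out = []
    for s in segs:
        lo = max(s.start_bp, arm_start)
        hi = min(s.end_bp, arm_end)
        if hi >= lo:
            out.append((s.state, hi - lo + 1))
    return out


def _smooth(pieces: list[tuple[tuple[int, int], int]],
            min_len_bp: float) -> list[tuple[tuple[int, int], int]]:
    """Iteratively merge same-state neighbours and drop sub-threshold
    segments (smallest first), re-merging after each removal."""
    pieces = list(pieces)

    def merge(p: list[tuple[tuple[int, int], int]]) -> list[tuple[tuple[int, int], int]]:
        out: list[tuple[tuple[int, int], int]] = []
        for state, ln in p:
            if out and out[-1][0] == state:
                out[-1] = (state, out[-1][1] + ln)
            else:
                out.append((state, ln))
        return out

    pieces = merge(pieces)
    while True:
        small = [i for i, (_, ln) in enumerate(pieces) if ln < min_len_bp]
        if not small or len(pieces) <= 1:
            break
        i = min(small, key=lambda j: pieces[j][1])
        del pieces[i]
        pieces = merge(pieces)
    return pieces


def compute_lst(segments: list[AllelicSegment], genome: GenomeBuild) -> int:
    """Large-scale state transitions per arm after 3 Mb smoothing: adjacent
    different-state segments that are both >= 10 Mb."""
    count = 0
    for chrom, segs in _sorted_by_chrom(segments).items():
        c = genome.chromosome(chrom)
        mid = c.centromere_mid_bp
        for arm_start, arm_end in ((1, mid), (mid + 1, c.length_bp)):
            pieces = _smooth(_clip_to_arm(segs, arm_start, arm_end), LST_SMOOTH_MB * 1e6)
            for (sa, la), (sb, lb) in zip(pieces, pieces[1:]):
                if sa != sb and la >= LST_MIN_SEGMENT_MB * 1e6 and lb >= LST_MIN_SEGMENT_MB * 1e6:
                    count += 1
    return count


def compute_ntai(segments: list[AllelicSegment], genome: GenomeBuild) -> int:
    """Telomeric allelic-imbalance runs: merged runs of imbalance
    (minor != major) that include the first or last segmented base of their
    chromosome and do not cross the centromere midpoint."""
    count = 0
    for chrom, segs in _sorted_by_chrom(segments).items():
        mid = genome.chromosome(chrom).centromere_mid_bp
        first_bp = segs[0].start_bp
        last_bp = segs[-1].end_bp
        runs: list[tuple[int, int]] = []
        cur: Optional[tuple[int, int]] = None
        for s in segs:
            if s.minor_cn != s.major_cn:
                cur = (s.start_bp, s.end_bp) if cur is None else (cur[0], s.end_bp)
            else:
                if cur is not None:
                    runs.append(cur)
                    cur = None
        if cur is not None:
            runs.append(cur)
        for start, end in runs:
            touches_end = start == first_bp or end == last_bp
            crosses_cen = start <= mid <= end
            if touches_end and not crosses_cen:
                count += 1
    return count


def score_hrd(segments: list[AllelicSegment], genome: GenomeBuild,
              threshold: int = HRD_SUM_THRESHOLD) -> HrdScore:
    """NtAI + LST + HRD-LOH with the >=42 positivity call."""
    return HrdScore(
        ntai=compute_ntai(segments, genome) if segments else 0,
        lst=compute_lst(segments, genome) if segments else 0,
        hrd_loh=compute_hrd_loh(segments, genome) if segments else 0,
        threshold=threshold,
    )


@dataclass
class HrdEvidence:
    """Combined HRD evidence: scar score, Signature-3 exposure, gene hits.

    ``hrdetect`` is reserved and always None: the published HRDetect model
    needs trained weights and rearrangement signatures outside this
    package's inputs.
    """

    hrd_score: HrdScore
    sig3_fraction: float
    hr_gene_hits: list[tuple[str, SomaticVariant, str]] = field(default_factory=list)
    associated_gene_hits: list[tuple[str, SomaticVariant, str]] = field(default_factory=list)
    hrdetect: None = None


def _zygosity(v: SomaticVariant, segments: list[AllelicSegment]) -> str:
    for s in segments:
        if s.chrom == v.chrom and s.start_bp <= v.pos <= s.end_bp:
            return "LOH" if s.minor_cn == 0 else "het"
    return "het"


def summarize_hrd_evidence(profile: SampleProfile, exposure: ExposureEstimate,
                           genome: GenomeBuild,
                           hr_gene_panel: tuple[str, ...] = DEFAULT_HR_GENES,
                           threshold: int = HRD_SUM_THRESHOLD) -> HrdEvidence:
    """Collect the HRD evidence reported per sample: the scar score, the
    Signature-3 exposure fraction, and somatic hits in HR genes (with
    PTEN/ARID1A flagged separately as PARPi-sensitivity-associated)."""
    hr_hits = []
    assoc_hits = []
    for v in profile.variants:
        if v.gene is None:
            continue
        if v.gene in hr_gene_panel:
            hr_hits.append((v.gene, v, _zygosity(v, profile.segments)))
        elif v.gene in PARP_ASSOCIATED_GENES:
            assoc_hits.append((v.gene, v, _zygosity(v, profile.segments)))
    return HrdEvidence(
        hrd_score=score_hrd(profile.segments, genome, threshold=threshold),
        sig3_fraction=exposure.weight("Signature.3"),
        hr_gene_hits=hr_hits,
        associated_gene_hits=assoc_hits,
    )
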