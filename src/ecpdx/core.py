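"""Shared domain types, genome-build table, and coordinate conventions.

All external file dialects are 1-based inclusive (MAF/SEG convention); the
package converts once at ingestion to 0-based half-open intervals and back
at write time.  Autosomes only by default: burden and scar metrics assume
a diploid background, which does not hold on X/Y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "Chromosome",
    "GenomeBuild",
    "SomaticVariant",
    "AllelicSegment",
    "MicrosatellitePanelResult",
    "SampleProfile",
    "TherapyArmSeries",
    "VolumeMeasurement",
    "Violation",
    "default_genome",
    "mini_genome",
    "validate_profile",
    "to_internal",
    "to_external",
    "VARIANT_CLASSES",
]

VARIANT_CLASSES = ("SNP", "DNP", "TNP", "INS", "DEL")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    centromere_start_bp: int
    centromere_end_bp: int

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.name}: length_bp must be positive")
        if not (0 < self.centromere_start_bp < self.centromere_end_bp < self.length_bp):
            raise ValueError(f"{self.name}: centromere must lie strictly inside the chromosome")

    @property
    def centromere_mid_bp(self) -> int:
        """Single coordinate used to split the chromosome into p and q arms."""
        return (self.centromere_start_bp + self.centromere_end_bp) // 2


@dataclass(frozen=True)
class GenomeBuild:
    name: str
    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")

    @property
    def total_length_bp(self) -> int:
        return sum(c.length_bp for c in self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")


# hg19-like autosome table.  Lengths are the GRCh37 assembly lengths;
# centromere bounds are approximate (acen band extents rounded to the
# nearest 0.1 Mb), sufficient for arm-level scar logic.
_HG19_AUTOSOMES = [
    # name, length, cen_start, cen_end
    ("1", 249_250_621, 121_500_000, 128_900_000),
    ("2", 243_199_373, 92_300_000, 95_300_000),
    ("3", 198_022_430, 90_500_000, 93_500_000),
    ("4", 191_154_276, 49_700_000, 52_700_000),
    ("5", 180_915_260, 46_400_000, 50_700_000),
    ("6", 171_115_067, 58_700_000, 61_700_000),
    ("7", 159_138_663, 58_000_000, 61_700_000),
    ("8", 146_364_022, 43_100_000, 48_100_000),
    ("9", 141_213_431, 47_300_000, 50_700_000),
    ("10", 135_534_747, 39_200_000, 42_300_000),
    ("11", 135_006_516, 51_600_000, 55_700_000),
    ("12", 133_851_895, 34_800_000, 38_200_000),
    ("13", 115_169_878, 16_000_000, 19_500_000),
    ("14", 107_349_540, 16_100_000, 19_100_000),
    ("15", 102_531_392, 15_800_000, 20_700_000),
    ("16", 90_354_753, 34_600_000, 38_600_000),
    ("17", 81_195_210, 22_200_000, 25_800_000),
    ("18", 78_077_248, 15_400_000, 19_000_000),
    ("19", 59_128_983, 24_400_000, 28_100_000),
    ("20", 63_025_520, 25_600_000, 29_400_000),
    ("21", 48_129_895, 10_900_000, 14_300_000),
    ("22", 51_304_566, 12_200_000, 17_900_000),
]


def default_genome() -> GenomeBuild:
    """Bundled hg19-like 22-autosome table (lengths + centromere bounds)."""
    return GenomeBuild(
        name="hg19-autosomes",
        chromosomes=tuple(Chromosome(n, l, cs, ce) for n, l, cs, ce in _HG19_AUTOSOMES),
    )


def mini_genome(n_chroms: int = 3, length_bp: int = 100_000_000) -> GenomeBuild:
    """Small configurable genome for tests: equal-length chromosomes with a
    centromere at 45-55% of the span."""
    chroms = tuple(
        Chromosome(str(i + 1), length_bp, int(0.45 * length_bp), int(0.55 * length_bp))
        for i in range(n_chroms)
    )
    return GenomeBuild(name=f"mini-{n_chroms}x{length_bp}", chromosomes=chroms)


def to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start_1based - 1, end_1based


def to_external(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic small variant.

    ``pos`` is 1-based; ``context3`` is the pyrimidine-normalized trinucleotide
    context and is present iff the variant is an SNP.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str
    vaf: float
    depth: int
    context3: Optional[str] = None
    gene: Optional[str] = None
    protein_change: Optional[str] = None
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.vclass not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.vclass!r}")
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.vclass == "SNP" and self.context3 is not None and len(self.context3) != 3:
            raise ValueError("context3 must be a trinucleotide")


@dataclass(frozen=True)
class AllelicSegment:
    """Allele-specific copy-number segment, 1-based inclusive span."""

    chrom: str
    start_bp: int
    end_bp: int
    total_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise ValueError(f"segment end {self.end_bp} < start {self.start_bp}")
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be nonnegative")
        if self.minor_cn > self.total_cn - self.minor_cn:
            raise ValueError(
                f"minor_cn {self.minor_cn} exceeds major allele of total {self.total_cn}"
            )

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def state(self) -> tuple[int, int]:
        return (self.total_cn, self.minor_cn)

    @property
    def major_cn(self) -> int:
        return self.total_cn - self.minor_cn


@dataclass(frozen=True)
class MicrosatellitePanelResult:
    n_assessed: int
    n_unstable: int

    def __post_init__(self) -> None:
        if self.n_assessed <= 0:
            raise ValueError("n_assessed must be positive")
        if not (0 <= self.n_unstable <= self.n_assessed):
            raise ValueError("n_unstable must lie in [0, n_assessed]")


@dataclass
class SampleProfile:
    """One tumor sample: variants, segments, microsatellite summary, metadata."""

    sample_id: str
    role: str  # "primary" | "pdx"
    callable_mb: float
    variants: list[SomaticVariant] = field(default_factory=list)
    segments: list[AllelicSegment] = field(default_factory=list)
    ms_result: Optional[MicrosatellitePanelResult] = None
    purity: Optional[float] = None  # None = unknown; never silently assume 1
    lineage: Optional[str] = None
    passage: Optional[int] = None
    patient_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in ("primary", "pdx"):
            raise ValueError(f"role must be 'primary' or 'pdx', got {self.role!r}")
        if self.callable_mb <= 0:
            raise ValueError("callable_mb must be positive")
        if self.passage is not None and self.role != "pdx":
            raise ValueError("passage only applies to PDX samples")
        if self.purity is not None and not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must lie in (0, 1]")


@dataclass(frozen=True)
class VolumeMeasurement:
    day: int
    volume_mm3: float

    def __post_init__(self) -> None:
        if self.volume_mm3 <= 0:
            raise ValueError("volume must be positive")


@dataclass(frozen=True)
class TherapyArmSeries:
    animal_id: str
    arm: str  # "vehicle" | "drug"
    measurements: tuple[VolumeMeasurement, ...]

    def __post_init__(self) -> None:
        if self.arm not in ("vehicle", "drug"):
            raise ValueError(f"arm must be 'vehicle' or 'drug', got {self.arm!r}")
        days = [m.day for m in self.measurements]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("measurement days must be strictly increasing")


@dataclass(frozen=True)
class Violation:
    """Structured record of one profile-validation failure."""

    kind: str
    where: str
    message: str


def validate_profile(profile: SampleProfile, genome: GenomeBuild) -> list[Violation]:
    """Check a profile against type invariants and genome bounds.

    Never raises; returns a (possibly empty) list of violations.  Construction
    already enforces most per-record invariants, so this focuses on
    cross-record and coordinate checks.
    """
    out: list[Violation] = []
    for v in profile.variants:
        if v.chrom not in genome:
            out.append(Violation("unknown_chrom", f"variant {v.chrom}:{v.pos}",
                                 f"chromosome {v.chrom!r} not in genome"))
            continue
        clen = genome.chromosome(v.chrom).length_bp
        if not (1 <= v.pos <= clen):
            out.append(Violation("out_of_bounds", f"variant {v.chrom}:{v.pos}",
                                 f"position {v.pos} outside [1, {clen}]"))
        if v.vclass == "SNP" and v.context3 is None:
            out.append(Violation("missing_context", f"variant {v.chrom}:{v.pos}",
                                 "SNP lacks trinucleotide context"))
    by_chrom: dict[str, list[AllelicSegment]] = {}
    for s in profile.segments:
        if s.chrom not in genome:
            out.append(Violation("unknown_chrom", f"segment {s.chrom}:{s.start_bp}-{s.end_bp}",
                                 f"chromosome {s.chrom!r} not in genome"))
            continue
        clen = genome.chromosome(s.chrom).length_bp
        if s.end_bp > clen:
            out.append(Violation("out_of_bounds", f"segment {s.chrom}:{s.start_bp}-{s.end_bp}",
                                 f"end {s.end_bp} beyond chromosome length {clen}"))
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start_bp)
        for a, b in zip(segs, segs[1:]):
            if b.start_bp <= a.end_bp:
                out.append(Violation(
                    "overlap", f"segments {chrom}:{a.start_bp}-{a.end_bp} and "
                               f"{chrom}:{b.start_bp}-{b.end_bp}",
                    "segments on one chromosome must not overlap"))
    return out
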