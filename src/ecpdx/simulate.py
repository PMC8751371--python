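"""Synthetic cohort generator.

Emulates the statistical structure the analysis assumes, so every stage is
testable without access to controlled sequencing data:

* per-subtype somatic SNV catalogs drawn from signature mixtures
  (uniform trinucleotide opportunity, Poisson mutation counts),
* microsatellite panel summaries (binomial unstable-site counts over a
  1000-site panel),
* allele-specific segment profiles realized from per-subtype event counts
  (arm gains, interstitial losses, small/large LOH, telomeric allelic
  imbalance, large-scale-transition pairs) on a diploid background, with
  optional whole-genome duplication,
* clonal trees sampled into matched primary + PDX-lineage panels with
  binomial read sampling at fixed depth,
* two-arm exponential tumor-volume curves with lognormal measurement noise.

Default preset parameters encode the subtype-defining characteristics the
classifier tests against (POLE: ~650 mutations/Mb, microsatellite stable,
quiet genome; MMRd: ~40 mutations/Mb, 10% unstable sites; CN-low: quiet on
all axes; CN-high: ~5 mutations/Mb, >25% genome altered across >15
segments, HR-proficient scar burden).  All randomness flows through one
seeded generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    AllelicSegment,
    GenomeBuild,
    MicrosatellitePanelResult,
    SampleProfile,
    SomaticVariant,
    TherapyArmSeries,
    VolumeMeasurement,
    default_genome,
    revcomp,
)
from .signatures import (
    CONTEXTS,
    SUBSTITUTIONS,
    MutationCatalog96,
    SignatureCatalog,
    synthetic_cosmic_v2_like_catalog,
)

__all__ = [
    "SubtypePreset",
    "CloneTreeSpec",
    "LineageTruth",
    "DEFAULT_PRESETS",
    "HRD_POSITIVE_PRESET",
    "simulate_sample",
    "simulate_catalog",
    "simulate_lineage_panel",
    "simulate_volume_series",
    "pdx58_like_spec",
    "DEFAULT_MS_PANEL_SIZE",
]

DEFAULT_MS_PANEL_SIZE = 1000
DEFAULT_CALLABLE_MB = 30.0


@dataclass(frozen=True)
class SubtypePreset:
    """Generative parameters for one molecular subtype."""

    label: str
    n_mutations: float                       # expected somatic SNV count
    signature_mix: dict[str, float]          # signature name -> fraction
    msi_unstable_frac: float
    segment_profile: dict[str, int]          # event kind -> count
    driver_genes: tuple[tuple[str, str], ...] = ()  # (gene, HGVS-p)
    wgd: bool = False
    ms_panel_size: int = DEFAULT_MS_PANEL_SIZE

    def __post_init__(self) -> None:
        total = sum(self.signature_mix.values())
        if self.signature_mix and abs(total - 1.0) > 1e-9:
            raise ValueError("signature_mix must sum to 1")
        if any(w < 0 for w in self.signature_mix.values()):
            raise ValueError("signature_mix weights must be nonnegative")
        if not (0.0 <= self.msi_unstable_frac <= 1.0):
            raise ValueError("msi_unstable_frac must lie in [0, 1]")


DEFAULT_PRESETS: dict[str, SubtypePreset] = {
    "POLE": SubtypePreset(
        label="POLE",
        n_mutations=19_500,  # ~650 mutations/Mb over 30 callable Mb
        signature_mix={"Signature.10": 0.8, "Signature.1": 0.2},
        msi_unstable_frac=0.005,
        segment_profile={"loss": 2, "loh_small": 1},
        driver_genes=(("POLE", "p.Pro286Arg"), ("PTEN", "p.Arg130Gln")),
    ),
    "MMRd": SubtypePreset(
        label="MMRd",
        n_mutations=1_200,  # ~40 mutations/Mb
        signature_mix={"Signature.6": 0.55, "Signature.15": 0.25, "Signature.1": 0.20},
        msi_unstable_frac=0.10,
        segment_profile={"loss": 2, "loh_small": 1},
        driver_genes=(
            ("PTEN", "p.Arg130fs"), ("ARID1A", "p.Gln456fs"),
            ("RPL22", "p.Lys15fs"), ("MSH6", "p.Phe1088fs"),
        ),
    ),
    "CN-low": SubtypePreset(
        label="CN-low",
        n_mutations=120,  # ~4 mutations/Mb
        signature_mix={"Signature.1": 0.6, "Signature.5": 0.4},
        msi_unstable_frac=0.005,
        segment_profile={"loss": 2, "loh_small": 1},
        driver_genes=(("PTEN", "p.Arg130Gly"), ("PIK3CA", "p.His1047Arg")),
    ),
    "CN-high": SubtypePreset(
        label="CN-high",
        n_mutations=150,  # ~5 mutations/Mb
        signature_mix={"Signature.2": 0.45, "Signature.1": 0.30, "Signature.13": 0.25},
        msi_unstable_frac=0.005,
        segment_profile={"gain": 10, "telomeric_ai": 3, "lst_pair": 1,
                         "loss": 4, "loh_small": 4},
        driver_genes=(("TP53", "p.Arg273His"),),
    ),
}

# HRD-positive control: plants ~56 qualifying scar events (12 large LOH,
# ~36 LSTs, 8 telomeric AI), well above the >=42 threshold.
HRD_POSITIVE_PRESET = SubtypePreset(
    label="CN-high",
    n_mutations=150,
    signature_mix={"Signature.1": 0.45, "Signature.3": 0.30, "Signature.2": 0.25},
    msi_unstable_frac=0.005,
    segment_profile={"loh_large": 12, "telomeric_ai": 8, "lst_pair": 2},
    driver_genes=(("TP53", "p.Arg273His"), ("BRCA1", "p.Gln1756fs")),
)


# ---------------------------------------------------------------------------
# segment realization

def _arms(genome: GenomeBuild) -> list[tuple[str, int, int]]:
    """(chrom, arm_start, arm_end) for every arm, 1-based inclusive."""
    arms = []
    for c in genome.chromosomes:
        mid = c.centromere_mid_bp
        arms.append((c.name, 1, mid))
        arms.append((c.name, mid + 1, c.length_bp))
    return arms


# per-kind: (state override on diploid, length window in Mb, placement)
_EVENT_KINDS = {
    "gain": ((4, 2), None, "arm"),            # whole-arm balanced duplication
    "loss": ((1, 0), (5.0, 9.0), "interstitial"),
    "loh_small": ((2, 0), (5.0, 9.0), "interstitial"),
    "loh_large": ((2, 0), (20.0, 30.0), "interstitial"),
    "telomeric_ai": ((3, 1), (15.0, 25.0), "telomeric"),
    "lst_pair": ((3, 1), (12.0, 18.0), "interstitial"),
}
_MARGIN_BP = 10_000_000  # flank kept diploid inside the arm around an event


def _realize_segments(profile: dict[str, int], genome: GenomeBuild,
                      wgd: bool, rng: np.random.Generator) -> list[AllelicSegment]:
    """Place each planted event on its own chromosome arm.

    Arm gains take the largest arms deterministically; interstitial and
    telomeric events are placed randomly on remaining arms that can hold
    the event plus diploid margins.  One event per arm keeps every planted
    scar/burden count exact by construction.
    """
    arms = sorted(_arms(genome), key=lambda a: -(a[2] - a[1] + 1))
    free = list(arms)
    events: list[tuple[str, int, int, tuple[int, int]]] = []

    for _ in range(profile.get("gain", 0)):
        if not free:
            raise ValueError("not enough arms for the requested events")
        chrom, lo, hi = free.pop(0)  # largest free arm
        events.append((chrom, lo, hi, _EVENT_KINDS["gain"][0]))

    random_events = []
    for kind, n in profile.items():
        if kind == "gain":
            continue
        if kind not in _EVENT_KINDS:
            raise ValueError(f"unknown segment event kind {kind!r}")
        random_events.extend([kind] * n)
    # place longest event classes first so they still find a qualifying arm
    random_events.sort(key=lambda k: -_EVENT_KINDS[k][1][1])
    for kind in random_events:
        state, (lo_mb, hi_mb), placement = _EVENT_KINDS[kind]
        length = int(rng.uniform(lo_mb, hi_mb) * 1e6)
        need = length + (2 * _MARGIN_BP if placement == "interstitial" else _MARGIN_BP)
        candidates = [i for i, (c, lo, hi) in enumerate(free) if hi - lo + 1 >= need]
        if not candidates:
            raise ValueError(f"no free arm can hold a {kind} event")
        i = int(rng.choice(candidates))
        chrom, lo, hi = free.pop(i)
        if placement == "telomeric":
            c = genome.chromosome(chrom)
            if lo == 1:  # p arm: start at the chromosome start
                start, end = 1, length
            else:        # q arm: end at the chromosome end
                start, end = c.length_bp - length + 1, c.length_bp
        else:
            offset = int(rng.integers(_MARGIN_BP, (hi - lo + 1) - length - _MARGIN_BP + 1))
            start = lo + offset
            end = start + length - 1
        events.append((chrom, start, end, state))

    # carve events out of the diploid background, chromosome by chromosome
    segs: list[AllelicSegment] = []
    for c in genome.chromosomes:
        chrom_events = sorted([e for e in events if e[0] == c.name], key=lambda e: e[1])
        cursor = 1
        for _, start, end, state in chrom_events:
            if start > cursor:
                segs.append(AllelicSegment(c.name, cursor, start - 1, 2, 1))
            segs.append(AllelicSegment(c.name, start, end, state[0], state[1]))
            cursor = end + 1
        if cursor <= c.length_bp:
            segs.append(AllelicSegment(c.name, cursor, c.length_bp, 2, 1))
    if wgd:
        segs = [AllelicSegment(s.chrom, s.start_bp, s.end_bp,
                               2 * s.total_cn, 2 * s.minor_cn) for s in segs]
    return segs


# ---------------------------------------------------------------------------
# SNV generation

def _mixture_spectrum(signature_mix: dict[str, float],
                      catalog: SignatureCatalog) -> np.ndarray:
    spec = np.zeros(96)
    for name, w in signature_mix.items():
        if w < 0:
            raise ValueError(f"negative mix weight for {name}")
        spec += w * catalog[name]
    return spec / spec.sum()


def simulate_catalog(signature_mix: dict[str, float], n_snvs: int,
                     signature_catalog: SignatureCatalog | None = None,
                     seed: int = 0) -> MutationCatalog96:
    """Multinomial 96-channel catalog drawn from a signature mixture."""
    cat = signature_catalog or synthetic_cosmic_v2_like_catalog()
    if n_snvs == 0:
        return MutationCatalog96(counts=np.zeros(96))
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_snvs, _mixture_spectrum(signature_mix, cat))
    return MutationCatalog96(counts=counts.astype(float))


def _channel_to_alleles(channel: int, purine_strand: bool) -> tuple[str, str, str]:
    """(ref, alt, context3) for a 96-channel index, optionally reported on
    the purine strand (build_catalog maps it back)."""
    sub = SUBSTITUTIONS[channel // 16]
    ctx = CONTEXTS[channel % 16]
    ref, alt = sub[0], sub[2]
    context = ctx[0] + ref + ctx[1]
    if purine_strand:
        return revcomp(ref), revcomp(alt), revcomp(context)
    return ref, alt, context


def _draw_positions(n: int, genome: GenomeBuild,
                    rng: np.random.Generator) -> list[tuple[str, int]]:
    lengths = np.array([c.length_bp for c in genome.chromosomes], dtype=float)
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(lengths), size=n, p=probs)
    out = []
    for i in chrom_idx:
        c = genome.chromosomes[int(i)]
        out.append((c.name, int(rng.integers(1, c.length_bp + 1))))
    return out


def simulate_sample(preset: SubtypePreset, genome: GenomeBuild | None = None,
                    callable_mb: float = DEFAULT_CALLABLE_MB,
                    purity: float = 1.0, depth: int = 100,
                    seed: int = 0,
                    signature_catalog: SignatureCatalog | None = None,
                    sample_id: str | None = None,
                    role: str = "pdx") -> SampleProfile:
    """Draw one sample from a subtype preset.

    SNV count ~ Poisson(n_mutations); channels from the signature mixture
    under uniform trinucleotide opportunity; positions uniform on the
    autosomes; VAFs binomial at the given depth around purity/2 (clonal
    heterozygous variants on a diploid background); preset drivers injected
    with their gene and protein-change labels (frameshift drivers become
    1-bp deletions and stay out of the 96-channel catalog).
    """
    if depth < 30:
        raise ValueError("depth must be >= 30")
    if not (0.0 < purity <= 1.0):
        raise ValueError("purity must lie in (0, 1]")
    genome = genome or default_genome()
    cat = signature_catalog or synthetic_cosmic_v2_like_catalog()
    rng = np.random.default_rng(seed)
    sid = sample_id or f"{preset.label}-s{seed}"

    n = int(rng.poisson(preset.n_mutations)) if preset.n_mutations > 0 else 0
    variants: list[SomaticVariant] = []
    if n > 0:
        spectrum = _mixture_spectrum(preset.signature_mix, cat)
        channels = rng.choice(96, size=n, p=spectrum)
        positions = _draw_positions(n, genome, rng)
        purine = rng.random(n) < 0.5
        alts = rng.binomial(depth, purity / 2.0, size=n)
        for j in range(n):
            ref, alt, ctx = _channel_to_alleles(int(channels[j]), bool(purine[j]))
            chrom, pos = positions[j]
            variants.append(SomaticVariant(
                chrom=chrom, pos=pos, ref=ref, alt=alt, vclass="SNP",
                vaf=float(alts[j]) / depth, depth=depth, context3=ctx,
                id=f"{sid}:m{j}"))
    for k, (gene, pchange) in enumerate(preset.driver_genes):
        chrom, pos = _draw_positions(1, genome, rng)[0]
        alt_reads = int(rng.binomial(depth, purity / 2.0))
        vaf = max(alt_reads, 1) / depth  # drivers are always detected
        if "fs" in pchange:
            v = SomaticVariant(chrom=chrom, pos=pos, ref="A", alt="-",
                               vclass="DEL", vaf=vaf, depth=depth,
                               gene=gene, protein_change=pchange,
                               id=f"{sid}:d{k}")
        else:
            v = SomaticVariant(chrom=chrom, pos=pos, ref="C", alt="T",
                               vclass="SNP", vaf=vaf, depth=depth,
                               context3="ACA", gene=gene, protein_change=pchange,
                               id=f"{sid}:d{k}")
        variants.append(v)

    segments = _realize_segments(preset.segment_profile, genome, preset.wgd, rng)
    ms = MicrosatellitePanelResult(
        n_assessed=preset.ms_panel_size,
        n_unstable=int(rng.binomial(preset.ms_panel_size, preset.msi_unstable_frac)))
    return SampleProfile(
        sample_id=sid, role=role, callable_mb=callable_mb, variants=variants,
        segments=segments, ms_result=ms, purity=purity)


# ---------------------------------------------------------------------------
# clonal lineage panels

@dataclass(frozen=True)
class CloneTreeSpec:
    """Planted clonal structure: clones with private mutation counts and
    per-sample cellular prevalences obeying the sum rule."""

    clones: tuple[dict, ...]  # {id, parent_id (None for root), n_private_mutations}
    prevalence: dict[str, dict[str, float]]  # sample_id -> clone_id -> cp

    def __post_init__(self) -> None:
        roots = [c["id"] for c in self.clones if c.get("parent_id") is None]
        if len(roots) != 1:
            raise ValueError("clone tree must have exactly one root")
        ids = {c["id"] for c in self.clones}
        for sid, prevs in self.prevalence.items():
            for cid, p in prevs.items():
                if cid not in ids:
                    raise ValueError(f"prevalence for unknown clone {cid!r}")
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"prevalence {p} outside [0, 1]")
        for sid in self.prevalence:
            for c in self.clones:
                kids = [k for k in self.clones if k.get("parent_id") == c["id"]]
                child_sum = sum(self.prevalence[sid].get(k["id"], 0.0) for k in kids)
                if child_sum > self.prevalence[sid].get(c["id"], 0.0) + 1e-9:
                    raise ValueError(
                        f"sum rule violated in sample {sid!r} at clone {c['id']!r}")

    @property
    def root_id(self) -> str:
        return next(c["id"] for c in self.clones if c.get("parent_id") is None)


@dataclass
class LineageTruth:
    """Planted truth emitted alongside a simulated panel."""

    clone_of: dict[str, str]     # mutation id -> clone id
    spec: CloneTreeSpec
    purities: dict[str, float]
    seed: int


def pdx58_like_spec(n_truncal: int = 150) -> CloneTreeSpec:
    """Three-clone scenario with one divergent PDX lineage: lineage A carries
    twice the truncal mutation count privately, so it shares ~1/3 of its
    substitutions with the primary tumor; lineage B stays close to the
    primary."""
    return CloneTreeSpec(
        clones=(
            {"id": "truncal", "parent_id": None, "n_private_mutations": n_truncal},
            {"id": "cloneA", "parent_id": "truncal", "n_private_mutations": 2 * n_truncal},
            {"id": "cloneB", "parent_id": "truncal", "n_private_mutations": n_truncal},
        ),
        prevalence={
            "primary": {"truncal": 1.0, "cloneA": 0.0, "cloneB": 0.6},
            "PDX-A": {"truncal": 1.0, "cloneA": 1.0, "cloneB": 0.0},
            "PDX-B": {"truncal": 1.0, "cloneA": 0.0, "cloneB": 1.0},
        },
    )


def simulate_lineage_panel(tree: CloneTreeSpec,
                           genome: GenomeBuild | None = None,
                           depth: int = 100, seed: int = 0,
                           purities: dict[str, float] | float = 1.0,
                           signature_mix: dict[str, float] | None = None,
                           signature_catalog: SignatureCatalog | None = None,
                           callable_mb: float = DEFAULT_CALLABLE_MB
                           ) -> tuple[list[SampleProfile], LineageTruth]:
    """Sample a planted clone tree into matched primary + PDX profiles.

    Every clone's private mutations are shared identities across samples;
    per sample, alt reads ~ Binomial(depth, purity * prevalence / 2) on a
    diploid background, and mutations with zero sampled alt reads are absent
    from that sample's table.
    """
    genome = genome or default_genome()
    cat = signature_catalog or synthetic_cosmic_v2_like_catalog()
    mix = signature_mix or {"Signature.1": 0.6, "Signature.5": 0.4}
    rng = np.random.default_rng(seed)
    sample_ids = list(tree.prevalence)
    if isinstance(purities, (int, float)):
        purities = {sid: float(purities) for sid in sample_ids}

    spectrum = _mixture_spectrum(mix, cat)
    muts: list[tuple[str, str, int, str, str, str]] = []  # id, chrom, pos, ref, alt, ctx
    clone_of: dict[str, str] = {}
    for clone in tree.clones:
        n = int(clone["n_private_mutations"])
        channels = rng.choice(96, size=n, p=spectrum)
        positions = _draw_positions(n, genome, rng)
        for j in range(n):
            ref, alt, ctx = _channel_to_alleles(int(channels[j]), False)
            mid = f"{clone['id']}:m{j}"
            muts.append((mid, positions[j][0], positions[j][1], ref, alt, ctx))
            clone_of[mid] = clone["id"]

    samples: list[SampleProfile] = []
    for i, sid in enumerate(sample_ids):
        purity = purities[sid]
        variants = []
        for mid, chrom, pos, ref, alt, ctx in muts:
            prev = tree.prevalence[sid].get(clone_of[mid], 0.0)
            # multiplicity 1 on a diploid background:
            # vaf = purity * prev / (purity*2 + (1-purity)*2) = purity * prev / 2
            p_alt = purity * prev / 2.0
            alt_reads = int(rng.binomial(depth, p_alt)) if p_alt > 0 else 0
            if alt_reads == 0:
                continue
            variants.append(SomaticVariant(
                chrom=chrom, pos=pos, ref=ref, alt=alt, vclass="SNP",
                vaf=alt_reads / depth, depth=depth, context3=ctx, id=mid))
        role = "primary" if i == 0 else "pdx"
        lineage = None if role == "primary" else chr(ord("A") + i - 1)
        samples.append(SampleProfile(
            sample_id=sid, role=role, callable_mb=callable_mb,
            variants=variants, purity=purity, lineage=lineage,
            passage=None if role == "primary" else 1, patient_id="panel"))
    return samples, LineageTruth(clone_of=clone_of, spec=tree,
                                 purities=purities, seed=seed)


# ---------------------------------------------------------------------------
# tumor volume series

def simulate_volume_series(n_per_arm: int, growth_rate_vehicle: float,
                           growth_rate_drug: float, noise_sd: float,
                           days: list[int], seed: int = 0,
                           v0_range: tuple[float, float] = (150.0, 250.0)
                           ) -> list[TherapyArmSeries]:
    """Exponential growth V(t) = V0 exp(r t) with multiplicative lognormal
    measurement noise after baseline.

    Baseline volumes are drawn once per animal index and shared between the
    two arms (a paired design), so equal growth rates at zero noise give a
    TGI of exactly 0.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not days:
        raise ValueError("days must be nonempty")
    rng = np.random.default_rng(seed)
    v0s = rng.uniform(v0_range[0], v0_range[1], size=n_per_arm)
    out = []
    for arm, rate in (("vehicle", growth_rate_vehicle), ("drug", growth_rate_drug)):
        for i in range(n_per_arm):
            meas = []
            for j, d in enumerate(sorted(days)):
                v = v0s[i] * np.exp(rate * d)
                if j > 0 and noise_sd > 0:
                    v *= np.exp(rng.normal(0.0, noise_sd))
                meas.append(VolumeMeasurement(day=int(d), volume_mm3=float(v)))
            out.append(TherapyArmSeries(animal_id=f"{arm}-{i}", arm=arm,
                                        measurements=tuple(meas)))
    return out
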