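"""Four-way molecular subtype classification for endometrial carcinoma /
carcinosarcoma samples, in the TCGA style: POLE (ultramutated), MMRd
(hypermutated, microsatellite unstable), CN-high (copy-number driven,
typically TP53-mutant serous/carcinosarcoma), CN-low (residual class).

Decision order is POLE -> MMRd -> CN-high -> CN-low.  A hypermutated,
microsatellite-unstable sample carrying a POLE variant *outside* the
exonuclease domain is therefore labeled MMRd, and the POLE hit is reported
as evidence only.  TP53 status is likewise evidence, never a criterion.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, asdict

from .burden import BurdenSummary
from .core import SomaticVariant
from .signatures import ExposureEstimate, SignatureCatalog, dominant_etiology

__all__ = [
    "SubtypeThresholds",
    "SubtypeCall",
    "detect_pole_exonuclease",
    "classify",
    "annotate_drivers",
    "parse_protein_change",
    "DEFAULT_DRIVER_PANEL",
    "POLE_EXONUCLEASE_DOMAIN",
]

# POLE proofreading (exonuclease) domain, amino-acid window (configurable)
POLE_EXONUCLEASE_DOMAIN = (268, 471)

DEFAULT_DRIVER_PANEL = (
    "TP53", "POLE", "PTEN", "ARID1A", "PIK3CA", "KRAS", "RPL22",
    "MSH2", "MSH6", "MLH1", "PMS2",
)

_AA3 = ("Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser "
        "Thr Trp Tyr Val Ter").split()
_HGVSP_RE = re.compile(
    r"^p\.\(?([A-Z][a-z]{2}|[A-Z*])(\d+)(.*?)\)?$"
)


def parse_protein_change(hgvsp: str) -> tuple[int, str] | None:
    """(codon, consequence class) from a short HGVS-p string, or None.

    Classes: missense, nonsense, frameshift, splice, synonymous, inframe,
    other.  Accepts one- and three-letter amino-acid codes.
    """
    if not hgvsp:
        return None
    s = hgvsp.strip()
    if "splice" in s.lower():
        return None
    m = _HGVSP_RE.match(s)
    if not m:
        return None
    ref_aa, codon, rest = m.group(1), int(m.group(2)), m.group(3)
    if ref_aa not in _AA3 and not (len(ref_aa) == 1 and ref_aa.isupper()):
        return None
    rest = rest.strip()
    low = rest.lower()
    if "fs" in low:
        kind = "frameshift"
    elif rest in ("*", "Ter") or low.endswith("ter") or rest.endswith("*"):
        kind = "nonsense"
    elif low.startswith("del") or low.startswith("ins") or low.startswith("dup"):
        kind = "inframe"
    elif rest == "=" or rest == ref_aa:
        kind = "synonymous"
    elif re.fullmatch(r"[A-Z][a-z]{2}|[A-Z]", rest):
        kind = "missense"
    else:
        kind = "other"
    return codon, kind


def detect_pole_exonuclease(variants: list[SomaticVariant],
                            domain: tuple[int, int] = POLE_EXONUCLEASE_DOMAIN
                            ) -> tuple[bool, bool]:
    """(exonuclease-domain missense present, other POLE coding variant present)."""
    exo = other = False
    for v in variants:
        if v.gene != "POLE":
            continue
        parsed = parse_protein_change(v.protein_change or "")
        if parsed is None:
            warnings.warn(
                f"unparseable POLE protein change {v.protein_change!r}; "
                "counted as non-exonuclease")
            other = True
            continue
        codon, kind = parsed
        if kind == "missense" and domain[0] <= codon <= domain[1]:
            exo = True
        elif kind != "synonymous":
            other = True
    return exo, other


@dataclass(frozen=True)
class SubtypeThresholds:
    """Thresholds of the classification rule; defaults follow the printed
    subtype-defining bounds (MSI >= 3%, MMRd TMB > 20/Mb, CN-high TMB <= 10/Mb
    with > 25% genome altered and > 15 segments)."""

    msi_cut: float = 3.0
    tmb_mmrd: float = 20.0
    tmb_cnhigh: float = 10.0
    pct_cna: float = 25.0
    n_seg: int = 15
    pole_tmb_min: float = 100.0
    pole_domain: tuple[int, int] = POLE_EXONUCLEASE_DOMAIN
    dominance: float = 0.30


@dataclass
class SubtypeCall:
    label: str  # POLE | MMRd | CN-high | CN-low
    evidence: dict
    thresholds_used: SubtypeThresholds


def classify(burden: BurdenSummary, exposure: ExposureEstimate | None,
             variants: list[SomaticVariant],
             thresholds: SubtypeThresholds | None = None,
             signature_catalog: SignatureCatalog | None = None) -> SubtypeCall:
    """Apply the four-way decision rule; evidence is populated on every branch.

    1. POLE   — exonuclease-domain missense AND TMB > pole_tmb_min
    2. MMRd   — MSI score >= msi_cut AND TMB > tmb_mmrd
    3. CN-high — pct_cna > pct_cna AND n_cna_segments > n_seg AND TMB <= tmb_cnhigh
    4. CN-low — residual
    """
    th = thresholds or SubtypeThresholds()
    for name in ("tmb", "msi_score", "pct_cna", "n_cna_segments"):
        val = getattr(burden, name)
        if val is None or val != val:  # NaN check
            raise ValueError(f"classification metric missing: {name}")
    exo, other = detect_pole_exonuclease(variants, domain=th.pole_domain)
    tp53 = any(v.gene == "TP53" for v in variants)
    mmr_hits = sorted({v.gene for v in variants
                       if v.gene in ("MLH1", "MSH2", "MSH6", "PMS2")})
    dom = (dominant_etiology(exposure, signature_catalog, threshold=th.dominance)
           if exposure is not None else None)
    if exo and burden.tmb > th.pole_tmb_min:
        label = "POLE"
    elif burden.msi_score >= th.msi_cut and burden.tmb > th.tmb_mmrd:
        label = "MMRd"
    elif (burden.pct_cna > th.pct_cna and burden.n_cna_segments > th.n_seg
          and burden.tmb <= th.tmb_cnhigh):
        label = "CN-high"
    else:
        label = "CN-low"
    evidence = {
        "tmb": burden.tmb,
        "msi_score": burden.msi_score,
        "pct_cna": burden.pct_cna,
        "n_cna_segments": burden.n_cna_segments,
        "dominant_etiology": dom,
        "pole_exonuclease_mut": exo,
        "pole_other_mut": other,
        "tp53_mut": tp53,
        "mmr_gene_hits": mmr_hits,
    }
    return SubtypeCall(label=label, evidence=evidence, thresholds_used=th)


def annotate_drivers(variants: list[SomaticVariant],
                     gene_panel: tuple[str, ...] = DEFAULT_DRIVER_PANEL
                     ) -> list[tuple[str, SomaticVariant, str]]:
    """Panel hits as (gene, variant, consequence class).

    The class is a protein-altering heuristic read off the HGVS-p string
    (frameshift/nonsense/missense/inframe/splice); variants without a
    parseable protein change are classed 'other'.
    """
    out = []
    for v in variants:
        if v.gene not in gene_panel:
            continue
        if v.protein_change and "splice" in v.protein_change.lower():
            out.append((v.gene, v, "splice"))
            continue
        parsed = parse_protein_change(v.protein_change or "")
        out.append((v.gene, v, parsed[1] if parsed else "other"))
    return out
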