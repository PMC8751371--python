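"""End-to-end orchestration: per-sample characterization and cohort runs.

``characterize_sample`` runs one profile through burden metrics, catalog
construction, signature refitting, HRD scar scoring and subtype
classification, returning a flat report row.  ``run_pipeline`` applies it to
every sample in a sheet, runs the heterogeneity analysis on multi-sample
patients, and writes deterministic outputs (report TSV, heterogeneity
tables, resolved-config snapshot).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .burden import summarize_burden
from .core import GenomeBuild, SampleProfile, default_genome
from .heterogeneity import (
    build_panel,
    cluster_prevalences,
    estimate_purity,
    euler_regions,
    infer_clone_tree,
)
from .hrd import summarize_hrd_evidence
from .io import SampleSheet, load_profile, write_report
from .signatures import (
    SignatureCatalog,
    build_catalog,
    dominant_etiology,
    refit_exposures,
    synthetic_cosmic_v2_like_catalog,
)
from .subtype import SubtypeThresholds, classify

__all__ = ["RunConfig", "characterize_sample", "run_pipeline"]

logger = logging.getLogger("ecpdx")


@dataclass
class RunConfig:
    """All pipeline thresholds and seeds in one round-trippable object."""

    msi_cut: float = 3.0
    tmb_mmrd: float = 20.0
    tmb_cnhigh: float = 10.0
    pct_cna: float = 25.0
    n_seg: int = 15
    pole_tmb_min: float = 100.0
    pole_domain: tuple[int, int] = (268, 471)
    sig_cutoff: float = 0.15
    dominance: float = 0.30
    hrd_threshold: int = 42
    cluster_min_fraction: float = 0.05
    cluster_k_max: int = 8
    detect_vaf: float = 0.05
    detect_depth: int = 10
    purity_min_depth: int = 30
    tree_tolerance: float = 0.05
    wgd_adjust: str = "none"  # reserved; no ploidy renormalization of AI
    seed: int = 0
    genome: str = "hg19-autosomes"

    def subtype_thresholds(self) -> SubtypeThresholds:
        return SubtypeThresholds(
            msi_cut=self.msi_cut, tmb_mmrd=self.tmb_mmrd,
            tmb_cnhigh=self.tmb_cnhigh, pct_cna=self.pct_cna, n_seg=self.n_seg,
            pole_tmb_min=self.pole_tmb_min,
            pole_domain=tuple(self.pole_domain), dominance=self.dominance)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["pole_domain"] = list(d["pole_domain"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "pole_domain" in d:
            d["pole_domain"] = tuple(d["pole_domain"])
        return cls(**d)


def characterize_sample(profile: SampleProfile, genome: GenomeBuild | None = None,
                        config: RunConfig | None = None,
                        signature_catalog: SignatureCatalog | None = None) -> dict:
    """Burden + signatures + HRD + subtype for one sample, as a report row."""
    cfg = config or RunConfig()
    genome = genome or default_genome()
    sig_cat = signature_catalog or synthetic_cosmic_v2_like_catalog()
    burden = summarize_burden(profile.variants, profile.callable_mb,
                              profile.ms_result, profile.segments, genome)
    catalog = build_catalog(profile.variants)
    exposure = None
    if catalog.total > 0:
        exposure = refit_exposures(catalog, sig_cat, cutoff=cfg.sig_cutoff)
    # no microsatellite panel: classified as MS-stable, score reported blank
    clf_burden = burden
    if burden.msi_score != burden.msi_score:
        clf_burden = dataclasses.replace(burden, msi_score=0.0)
    call = classify(clf_burden, exposure, profile.variants,
                    thresholds=cfg.subtype_thresholds(),
                    signature_catalog=sig_cat)
    if exposure is not None:
        evidence = summarize_hrd_evidence(profile, exposure, genome,
                                          threshold=cfg.hrd_threshold)
        hrd = evidence.hrd_score
        sig3 = evidence.sig3_fraction
        exp_str = ";".join(f"{k}:{v:.4f}" for k, v in sorted(exposure.weights.items()))
        dom = dominant_etiology(exposure, sig_cat, threshold=cfg.dominance)
    else:
        from .hrd import score_hrd
        hrd = score_hrd(profile.segments, genome, threshold=cfg.hrd_threshold)
        sig3, exp_str, dom = 0.0, "", None
    return {
        "sample_id": profile.sample_id, "role": profile.role,
        "lineage": profile.lineage, "passage": profile.passage,
        "tmb": burden.tmb, "msi_score": burden.msi_score,
        "pct_cna": burden.pct_cna, "n_cna_segments": burden.n_cna_segments,
        "exposures": exp_str, "dominant_etiology": dom,
        "ntai": hrd.ntai, "lst": hrd.lst, "hrd_loh": hrd.hrd_loh,
        "hrd_sum": hrd.sum, "hrd_call": hrd.hrd_call,
        "sig3_fraction": sig3, "subtype": call.label,
        "pole_exonuclease_mut": call.evidence["pole_exonuclease_mut"],
        "pole_other_mut": call.evidence["pole_other_mut"],
        "tp53_mut": call.evidence["tp53_mut"],
        "mmr_gene_hits": ";".join(call.evidence["mmr_gene_hits"]),
    }


def _heterogeneity_outputs(samples: list[SampleProfile], cfg: RunConfig,
                           out_dir: Path, patient: str) -> None:
    panel = build_panel(samples, detect_vaf=cfg.detect_vaf,
                        detect_depth=cfg.detect_depth)
    regions = euler_regions(panel)
    with open(out_dir / f"euler_{patient}.tsv", "w") as fh:
        fh.write("samples\tn_mutations\n")
        for pattern in sorted(regions):
            fh.write(f"{'+'.join(pattern) or '(none)'}\t{regions[pattern]}\n")
    purities = {}
    for s in samples:
        if s.purity is not None:
            purities[s.sample_id] = s.purity
        else:
            purities[s.sample_id] = estimate_purity(
                s.variants, s.segments or None, min_depth=cfg.purity_min_depth)
    try:
        clusters = cluster_prevalences(
            panel, purities, min_fraction=cfg.cluster_min_fraction,
            k_max=cfg.cluster_k_max, seed=cfg.seed)
    except ValueError as e:
        logger.warning("patient %s: clustering skipped (%s)", patient, e)
        return
    sample_ids = panel.sample_ids
    with open(out_dir / f"clusters_{patient}.tsv", "w") as fh:
        fh.write("cluster_id\tn_mutations\tfraction\tminor\t"
                 + "\t".join(f"cp_{s}" for s in sample_ids) + "\n")
        for c in clusters:
            fh.write(f"{c.cluster_id}\t{len(c.members)}\t"
                     f"{c.fraction_of_substitutions:.6g}\t{c.minor}\t"
                     + "\t".join(f"{c.prevalence[s]:.6g}" for s in sample_ids) + "\n")
    top = [c for c in clusters if not c.minor]
    if 1 < len(top) <= 8:
        try:
            trees = infer_clone_tree(top, tolerance=cfg.tree_tolerance)
        except ValueError as e:
            logger.warning("patient %s: tree inference failed (%s)", patient, e)
            return
        with open(out_dir / f"trees_{patient}.tsv", "w") as fh:
            fh.write("tree_rank\tparent\tchild\tslack\n")
            for rank, t in enumerate(trees):
                for p, ch in t.edges:
                    fh.write(f"{rank}\t{p}\t{ch}\t{t.slack:.6g}\n")


def run_pipeline(sheet: SampleSheet, config: RunConfig | None = None,
                 out_dir: str | Path = ".", genome: GenomeBuild | None = None
                 ) -> list[dict]:
    """Characterize every sample in a sheet and write all report files.

    Reruns with the same inputs and config produce byte-identical outputs.
    """
    cfg = config or RunConfig()
    genome = genome or default_genome()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sig_cat = synthetic_cosmic_v2_like_catalog()
    rows = []
    by_patient: dict[str, list[SampleProfile]] = {}
    if not sheet.entries:
        logger.warning("empty sample sheet: writing header-only report")
    for entry in sheet.entries:
        try:
            profile = load_profile(entry)
            rows.append(characterize_sample(profile, genome, cfg, sig_cat))
        except Exception as e:
            raise RuntimeError(
                f"stage characterize failed for sample {entry.sample_id}: {e}") from e
        if profile.patient_id:
            by_patient.setdefault(profile.patient_id, []).append(profile)
    write_report(rows, out / "report.tsv")
    for patient, samples in sorted(by_patient.items()):
        if len(samples) >= 2:
            try:
                _heterogeneity_outputs(samples, cfg, out, patient)
            except Exception as e:
                raise RuntimeError(
                    f"stage heterogeneity failed for patient {patient}: {e}") from e
    cfg.to_yaml(out / "resolved_config.yaml")
    logger.info("ecpdx %s: %d samples characterized", __version__, len(rows))
    return rows
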