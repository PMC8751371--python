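#!/usr/bin/env python
"""Generate the synthetic study cohort: one sample per molecular subtype
preset (POLE, MMRd, CN-low, CN-high) plus an HRD-positive control, written
in the package's MAF/SEG/TSV dialects with planted-truth JSON next to each
sample."""

import json
from pathlib import Path

from ecpdx.io import SampleSheet, SampleSheetEntry, write_ms_summary, write_sample_sheet, write_segments_seg, write_variants_maf
from ecpdx.simulate import DEFAULT_PRESETS, HRD_POSITIVE_PRESET, simulate_sample

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    entries = []
    presets = dict(DEFAULT_PRESETS)
    presets["HRD-control"] = HRD_POSITIVE_PRESET
    for name, preset in presets.items():
        prof = simulate_sample(preset, seed=SEED, sample_id=f"{name}-s{SEED}")
        write_variants_maf(prof.variants, OUT / f"{prof.sample_id}.maf.tsv")
        write_segments_seg(prof.segments, OUT / f"{prof.sample_id}.seg.tsv")
        write_ms_summary(prof.ms_result, OUT / f"{prof.sample_id}.ms.tsv")
        (OUT / f"{prof.sample_id}.truth.json").write_text(json.dumps({
            "preset": name, "seed": SEED, "purity": 1.0,
            "signature_mix": preset.signature_mix,
            "msi_unstable_frac": preset.msi_unstable_frac,
            "segment_profile": preset.segment_profile}, indent=2) + "\n")
        entries.append(SampleSheetEntry(
            sample_id=prof.sample_id, role="pdx",
            variants_path=f"{prof.sample_id}.maf.tsv",
            segments_path=f"{prof.sample_id}.seg.tsv",
            ms_path=f"{prof.sample_id}.ms.tsv",
            callable_mb=prof.callable_mb, purity=1.0))
        print(f"{prof.sample_id}: {len(prof.variants)} variants, "
              f"{len(prof.segments)} segments")
    write_sample_sheet(SampleSheet(entries=entries), OUT / "samples.tsv")
    print(f"cohort written to {OUT}")


if __name__ == "__main__":
    main()
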