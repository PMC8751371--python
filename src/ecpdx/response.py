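"""Two-arm PDX tumor-volume analysis: relative volume change, tumor growth
inhibition (TGI), and a RECIST-style category.

TGI = 100 * (1 - dT/dC), where dT and dC are the mean end-minus-baseline
volume changes of the drug and vehicle arms.  The RECIST-style category is
read from the drug arm's mean relative volume change: PR at <= -30%, PD at
>= +20%, SD between.  Classical RECIST thresholds apply to the sum of lesion
diameters; mouse studies often apply them to volumes directly.  Both
conventions are exposed (``diameter_equivalent`` applies a cube-root
transform before thresholding) with the volume convention as default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import TherapyArmSeries

__all__ = ["ResponseSummary", "summarize_response", "permutation_test_final_volumes"]

RECIST_PR_THRESHOLD = -30.0
RECIST_PD_THRESHOLD = 20.0


@dataclass(frozen=True)
class ResponseSummary:
    mean_rel_change_vehicle: float  # percent
    mean_rel_change_drug: float     # percent
    tgi_percent: float | None       # None when the vehicle arm did not grow
    category: str                   # PR | SD | PD
    end_day: int
    n_vehicle: int
    n_drug: int


def _endpoints(series: TherapyArmSeries, end_day: int) -> tuple[float, float]:
    """(baseline, end) volumes; the end is the measurement at end_day or the
    last one before it."""
    v0 = series.measurements[0].volume_mm3
    upto = [m for m in series.measurements if m.day <= end_day]
    if not upto:
        raise ValueError(
            f"animal {series.animal_id}: no measurement at or before day {end_day}")
    return v0, upto[-1].volume_mm3


def summarize_response(series: list[TherapyArmSeries], end_day: int,
                       diameter_equivalent: bool = False) -> ResponseSummary:
    """Summarize a two-arm experiment at the end-of-study day."""
    arms = {"vehicle": [], "drug": []}
    for s in series:
        arms[s.arm].append(_endpoints(s, end_day))
    if not arms["vehicle"] or not arms["drug"]:
        raise ValueError("both a vehicle and a drug arm are required")

    def rel_changes(pairs):
        arr = np.asarray(pairs)
        v0, ve = arr[:, 0], arr[:, 1]
        if diameter_equivalent:
            v0, ve = np.cbrt(v0), np.cbrt(ve)
        return 100.0 * (ve - v0) / v0

    rc_vehicle = float(rel_changes(arms["vehicle"]).mean())
    rc_drug = float(rel_changes(arms["drug"]).mean())
    dC = float(np.mean([e - b for b, e in arms["vehicle"]]))
    dT = float(np.mean([e - b for b, e in arms["drug"]]))
    if dC <= 0:
        warnings.warn("vehicle arm did not grow on average; TGI undefined")
        tgi = None
    else:
        tgi = 100.0 * (1.0 - dT / dC)
    if rc_drug <= RECIST_PR_THRESHOLD:
        category = "PR"
    elif rc_drug >= RECIST_PD_THRESHOLD:
        category = "PD"
    else:
        category = "SD"
    return ResponseSummary(
        mean_rel_change_vehicle=rc_vehicle,
        mean_rel_change_drug=rc_drug,
        tgi_percent=tgi,
        category=category,
        end_day=end_day,
        n_vehicle=len(arms["vehicle"]),
        n_drug=len(arms["drug"]),
    )


def permutation_test_final_volumes(series: list[TherapyArmSeries], end_day: int,
                                   n_permutations: int = 10_000,
                                   seed: int = 0) -> float:
    """Two-sided permutation test on end-of-study volumes between arms.

    A stand-in for repeated-measures mixed-effects testing, provided for
    convenience; it uses only the final volumes.
    """
    finals, labels = [], []
    for s in series:
        finals.append(_endpoints(s, end_day)[1])
        labels.append(s.arm == "drug")
    finals = np.asarray(finals)
    labels = np.asarray(labels)
    if labels.all() or not labels.any():
        raise ValueError("both arms are required")
    obs = abs(finals[labels].mean() - finals[~labels].mean())
    rng = np.random.default_rng(seed)
    count = 0
    n_drug = int(labels.sum())
    for _ in range(n_permutations):
        perm = rng.permutation(len(finals))
        sel = np.zeros(len(finals), dtype=bool)
        sel[perm[:n_drug]] = True
        if abs(finals[sel].mean() - finals[~sel].mean()) >= obs - 1e-12:
            count += 1
    return count / n_permutations
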