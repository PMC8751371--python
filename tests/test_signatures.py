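"""Catalog construction and signature refitting, including the simplex
grid-search oracle and mixture-recovery checks."""

import itertools

import numpy as np
import pytest

from ecpdx.core import SomaticVariant
from ecpdx.signatures import (
    CHANNELS,
    ExposureEstimate,
    MutationCatalog96,
    build_catalog,
    channel_index,
    dominant_etiology,
    refit_exposures,
)
from ecpdx.simulate import simulate_catalog


def _snv(ref, alt, ctx):
    return SomaticVariant("1", 100, ref, alt, "SNP", 0.5, 60, context3=ctx)


class TestBuildCatalog:
    def test_pyrimidine_snv_lands_in_its_channel(self):
        cat = build_catalog([_snv("C", "A", "ACA")])
        assert cat.counts[channel_index("C>A", "ACA")] == 1
        assert cat.total == 1

    def test_purine_snv_reverse_complements_to_same_channel(self):
        # G>T at TGT is C>A at ACA on the opposite strand
        a = build_catalog([_snv("C", "A", "ACA")])
        b = build_catalog([_snv("G", "T", "TGT")])
        assert np.array_equal(a.counts, b.counts)

    def test_empty_input_and_non_snvs_ignored(self):
        indel = SomaticVariant("1", 5, "A", "-", "DEL", 0.5, 60)
        cat = build_catalog([indel])
        assert cat.total == 0

    def test_inconsistent_context_skipped_and_counted(self):
        cat = build_catalog([_snv("C", "A", "ATA")])  # middle base is not C
        assert cat.total == 0 and cat.n_skipped == 1

    def test_channel_order_is_substitution_major(self):
        assert CHANNELS[0] == "A[C>A]A"
        assert CHANNELS[16] == "A[C>G]A"
        assert CHANNELS[95] == "T[T>G]T"


def _grid_search(obs, matrix, step=0.01):
    """Exhaustive simplex search over <=3 signatures (independent oracle)."""
    n = matrix.shape[0]
    best, best_sse = None, np.inf
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    if n == 2:
        combos = ((a, 1.0 - a) for a in ticks)
    else:
        combos = ((a, b, 1.0 - a - b) for a in ticks for b in ticks
                  if a + b <= 1.0 + 1e-12)
    for w in combos:
        w = np.clip(np.asarray(w), 0, None)
        sse = float(((w @ matrix - obs) ** 2).sum())
        if sse < best_sse:
            best, best_sse = w, sse
    return best, best_sse


class TestRefit:
    def test_identity_mixture_recovered(self, sig_catalog):
        cat = simulate_catalog({"Signature.10": 1.0}, 1000, sig_catalog, seed=1)
        exp = refit_exposures(cat, sig_catalog)
        assert exp.weight("Signature.10") >= 0.95

    def test_empty_catalog_rejected(self, sig_catalog):
        with pytest.raises(ValueError, match="empty spectrum"):
            refit_exposures(MutationCatalog96(np.zeros(96)), sig_catalog)

    def test_equal_four_way_mixture_has_no_dominant_signature(self, sig_catalog):
        mix = {f"Signature.{k}": 0.25 for k in (1, 2, 5, 13)}
        cat = simulate_catalog(mix, 5000, sig_catalog, seed=1)
        exp = refit_exposures(cat, sig_catalog)
        assert exp.max_weight < 0.30
        assert dominant_etiology(exp, sig_catalog) is None

    def test_quarter_signature3_refits_inside_printed_band(self, sig_catalog):
        mix = {"Signature.1": 0.5, "Signature.2": 0.25, "Signature.3": 0.25}
        cat = simulate_catalog(mix, 3000, sig_catalog, seed=1)
        exp = refit_exposures(cat, sig_catalog)
        assert 0.20 <= exp.weight("Signature.3") <= 0.30

    def test_weights_scale_invariant(self, sig_catalog):
        cat = simulate_catalog({"Signature.1": 0.6, "Signature.13": 0.4},
                               2000, sig_catalog, seed=7)
        e1 = refit_exposures(cat, sig_catalog)
        e2 = refit_exposures(MutationCatalog96(cat.counts * 5), sig_catalog)
        for k in e1.weights:
            assert e1.weights[k] == pytest.approx(e2.weights.get(k, 0.0), abs=1e-9)

    def test_retained_weights_respect_cutoff_and_sum_to_one(self, sig_catalog):
        cat = simulate_catalog({"Signature.1": 0.5, "Signature.2": 0.3,
                                "Signature.13": 0.2}, 4000, sig_catalog, seed=3)
        exp = refit_exposures(cat, sig_catalog, cutoff=0.15)
        assert all(w >= 0.15 for w in exp.weights.values())
        assert sum(exp.weights.values()) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("names,weights,seed", [
        (("Signature.1", "Signature.2"), (0.7, 0.3), 11),
        (("Signature.1", "Signature.2", "Signature.13"), (0.5, 0.3, 0.2), 12),
        (("Signature.3", "Signature.10", "Signature.6"), (0.4, 0.35, 0.25), 13),
    ])
    def test_matches_simplex_grid_search_oracle(self, sig_catalog, names,
                                                weights, seed):
        sub = sig_catalog.subset(list(names))
        cat = simulate_catalog(dict(zip(names, weights)), 4000, sub, seed=seed)
        obs = cat.spectrum()
        exp = refit_exposures(cat, sub, cutoff=0.15)
        _, oracle_sse = _grid_search(obs, sub.matrix)
        assert exp.residual_sse <= oracle_sse + 1e-6

    def test_recovery_of_planted_mixtures_over_seeds(self, sig_catalog):
        mixes = [
            {"Signature.1": 0.6, "Signature.13": 0.4},
            {"Signature.2": 0.4, "Signature.5": 0.35, "Signature.10": 0.25},
            {"Signature.3": 0.3, "Signature.6": 0.3, "Signature.1": 0.4},
        ]
        errs = []
        for seed in range(20):
            mix = mixes[seed % len(mixes)]
            cat = simulate_catalog(mix, 5000, sig_catalog, seed=100 + seed)
            exp = refit_exposures(cat, sig_catalog)
            errs.extend(abs(exp.weight(k) - w) for k, w in mix.items())
        assert np.mean(errs) <= 0.05

    def test_final_sse_not_worse_than_best_single_signature(self, sig_catalog):
        cat = simulate_catalog({"Signature.1": 0.5, "Signature.10": 0.5},
                               3000, sig_catalog, seed=5)
        obs = cat.spectrum()
        exp = refit_exposures(cat, sig_catalog)
        best_single = min(((sig_catalog.matrix - obs) ** 2).sum(axis=1))
        assert exp.residual_sse <= best_single + 1e-12


class TestDominantEtiology:
    def test_pole_dominant(self, sig_catalog):
        exp = ExposureEstimate({"Signature.10": 0.8, "Signature.1": 0.2},
                               0.0, 1000, 0.15)
        assert dominant_etiology(exp, sig_catalog) == "POLE"

    def test_all_below_threshold_gives_none(self, sig_catalog):
        exp = ExposureEstimate({f"Signature.{k}": 0.25 for k in (1, 2, 5, 13)},
                               0.0, 1000, 0.15)
        assert dominant_etiology(exp, sig_catalog) is None

    def test_apobec_dominant(self, sig_catalog):
        exp = ExposureEstimate({"Signature.2": 0.45, "Signature.1": 0.3,
                                "Signature.5": 0.25}, 0.0, 1000, 0.15)
        assert dominant_etiology(exp, sig_catalog) == "APOBEC"
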