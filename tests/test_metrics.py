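import math

import numpy as np
import pytest

from conftest import make_pair

from tssgrid.annotation import PairSet
from tssgrid.expansion import RegionAverage
from tssgrid.metrics import (
    METRIC_NAMES,
    MetricsPanel,
    canonical_regions,
    derive_metrics,
    metrics_panel,
    pair_index_summary,
    replicate_concordance,
    replicate_stats,
)
from tssgrid.signal import GenomicSignal


def panel_from_log2(values: dict, pair_index=1, stratum="all", reasons=None) -> MetricsPanel:
    return MetricsPanel(regions={}, derived=dict(values), reasons=dict(reasons or {}),
                        pair_index=pair_index, stratum=stratum)


class TestCanonicalRegions:
    def test_region_bounds(self):
        r = canonical_regions()
        assert (r["A"].x0, r["A"].y0, r["A"].x1, r["A"].y1) == (0, -20_000, 200, -10_000)
        assert (r["Af"].x0, r["Af"].y0, r["Af"].x1, r["Af"].y1) == (300, -20_000, 1000, -10_000)
        assert (r["B"].x0, r["B"].y0, r["B"].x1, r["B"].y1) == (0, -900, 200, -200)
        assert (r["Bf"].x0, r["Bf"].y0, r["Bf"].x1, r["Bf"].y1) == (300, -900, 1000, -200)
        assert (r["C"].x0, r["C"].y0, r["C"].x1, r["C"].y1) == (0, 0, 200, 200)
        assert (r["D"].x0, r["D"].y0, r["D"].x1, r["D"].y1) == (300, 0, 1000, 200)
        assert (r["E"].x0, r["E"].y0, r["E"].x1, r["E"].y1) == (10_000, 0, 20_000, 200)


def pairs_spanning_all_regions(chrom_len=200_000):
    """Distances chosen so every canonical region is defined."""
    pairs = [
        make_pair(30_000, 30_100, gene_id="prox"),      # C
        make_pair(60_000, 60_500, gene_id="inter"),     # B, Bf, D
        make_pair(120_000, 135_000, gene_id="distal"),  # A, Af, E, D? (no: d=15k -> A/Af/E)
    ]
    return PairSet(pairs, pair_index=1)


class TestMetricsPanel:
    def test_constant_unit_signal_gives_unit_t_and_zero_metrics(self):
        sig = GenomicSignal({"chr1": np.ones(200_000)})
        panel = metrics_panel(sig, pairs_spanning_all_regions())
        for label, ra in panel.regions.items():
            assert ra.defined and ra.value == 1.0, label
        assert set(panel.derived) == set(METRIC_NAMES)
        assert all(v == 0.0 for v in panel.derived.values())

    def test_derived_ratios_from_constructed_t_values(self):
        regions = {lab: RegionAverage(val, 100, True) for lab, val in
                   {"A": 1.0, "Af": 0.5, "B": 0.25, "Bf": 0.5, "C": 2.0, "D": 3.0, "E": 1.0}.items()}
        derived, reasons = derive_metrics(regions)
        assert derived["proximal_cooperativity"] == pytest.approx(1.0)  # log2(2/1)
        assert derived["upstream_effects"] == pytest.approx(-2.0)       # log2(0.25)
        assert derived["downstream_effects"] == pytest.approx(math.log2(3.0))
        assert derived["positional_dominance"] == pytest.approx(0.0)
        assert derived["persistence_distal"] == pytest.approx(-1.0)
        assert derived["persistence_nondistal"] == pytest.approx(1.0)
        assert derived["signal_dominance"] == pytest.approx(0.0)
        assert derived["persistence_dominance"] == pytest.approx(2.0)
        assert reasons == {}

    def test_all_ratios_recomputable_from_stored_t_values(self, rng):
        vals = {lab: float(v) for lab, v in zip("A Af B Bf C D E".split(),
                                                rng.lognormal(0, 1, 7))}
        regions = {lab: RegionAverage(v, 10, True) for lab, v in vals.items()}
        derived, _ = derive_metrics(regions)
        assert derived["positional_dominance"] + derived["upstream_effects"] == pytest.approx(
            math.log2(vals["E"] * vals["B"] / (vals["A"] * vals["A"]))
        )

    def test_short_distance_pairs_leave_distal_regions_undefined(self):
        sig = GenomicSignal({"chr1": np.ones(100_000)})
        panel = metrics_panel(sig, PairSet([make_pair(50_000, 50_500)], 1))
        assert not panel.regions["A"].defined
        assert "persistence_distal" not in panel.derived
        assert panel.reasons["persistence_distal"].startswith("undefined:T_A")

    def test_scale_invariance_of_derived_metrics(self, rng):
        arr = rng.random(200_000) + 0.05
        pairs = pairs_spanning_all_regions()
        p1 = metrics_panel(GenomicSignal({"chr1": arr}), pairs)
        p2 = metrics_panel(GenomicSignal({"chr1": arr * 37.5}), pairs)
        for name in METRIC_NAMES:
            assert abs(p1.derived[name] - p2.derived[name]) < 1e-9

    def test_empty_pair_set_rejected(self):
        sig = GenomicSignal({"chr1": np.ones(100)})
        with pytest.raises(ValueError):
            metrics_panel(sig, PairSet([], 1))


class TestReplicateStats:
    def test_identical_replicates_have_zero_noise(self):
        p = panel_from_log2({"upstream_effects": 2.0})  # metric ratio m = 4
        stats, _ = replicate_stats(p, panel_from_log2({"upstream_effects": 2.0}))
        assert stats["upstream_effects"].mean == 2.0
        assert stats["upstream_effects"].noise == 0.0

    def test_closed_form_mean_and_noise(self):
        # m1 = 8, m2 = 2 -> log2 values 3 and 1 -> mean 2, noise 1
        stats, _ = replicate_stats(
            panel_from_log2({"signal_dominance": 3.0}),
            panel_from_log2({"signal_dominance": 1.0}),
        )
        assert stats["signal_dominance"].mean == 2.0
        assert stats["signal_dominance"].noise == 1.0

    def test_mean_plus_minus_noise_reconstructs_replicates(self, rng):
        m1 = {name: float(v) for name, v in zip(METRIC_NAMES, rng.normal(0, 2, len(METRIC_NAMES)))}
        m2 = {name: float(v) for name, v in zip(METRIC_NAMES, rng.normal(0, 2, len(METRIC_NAMES)))}
        stats, _ = replicate_stats(panel_from_log2(m1), panel_from_log2(m2))
        for name in METRIC_NAMES:
            assert stats[name].mean + stats[name].noise == pytest.approx(m1[name], rel=1e-15, abs=1e-15)
            assert stats[name].mean - stats[name].noise == pytest.approx(m2[name], rel=1e-15, abs=1e-15)

    def test_metric_absent_in_one_replicate_is_reported_with_reason(self):
        p1 = panel_from_log2({"upstream_effects": 1.0})
        p2 = panel_from_log2({}, reasons={"upstream_effects": "nonpositive:T_B"})
        stats, reasons = replicate_stats(p1, p2)
        assert "upstream_effects" not in stats
        assert "rep2:nonpositive:T_B" in reasons["upstream_effects"]

    def test_mismatched_panels_rejected(self):
        with pytest.raises(ValueError):
            replicate_stats(panel_from_log2({}, pair_index=1), panel_from_log2({}, pair_index=2))


class TestConcordance:
    def test_monotone_transform_gives_perfect_rho(self):
        q1 = {f"g{i}": float(i) for i in range(10)}
        q2 = {g: 2 * v for g, v in q1.items()}
        rho, passed = replicate_concordance(q1, q2)
        assert rho == pytest.approx(1.0) and passed

    def test_reversed_ranking_fails(self):
        q1 = {f"g{i}": float(i) for i in range(10)}
        q2 = {f"g{i}": float(9 - i) for i in range(10)}
        rho, passed = replicate_concordance(q1, q2)
        assert rho == pytest.approx(-1.0) and not passed

    def test_independent_rankings_fail_the_gate(self, rng):
        perm1 = rng.permutation(1000).astype(float)
        perm2 = rng.permutation(1000).astype(float)
        q1 = {f"g{i}": v for i, v in enumerate(perm1)}
        q2 = {f"g{i}": v for i, v in enumerate(perm2)}
        rho, passed = replicate_concordance(q1, q2)
        assert abs(rho) < 0.2 and not passed

    def test_too_few_shared_genes_rejected(self):
        with pytest.raises(ValueError):
            replicate_concordance({"a": 1, "b": 2}, {"a": 1, "b": 2})


class TestPairIndexSummary:
    def test_identical_distal_panels_average_to_common_value(self):
        panels = [panel_from_log2({"proximal_cooperativity": 1.5}, pair_index=k)
                  for k in range(3, 11)]
        df = pair_index_summary(panels)
        row = df[(df.metric == "proximal_cooperativity") & (df.group == "pairs_3_10")]
        assert row.log2_value.item() == 1.5 and row.n.item() == 8

    def test_mean_of_two_distal_indices(self):
        panels = [panel_from_log2({"upstream_effects": 1.0}, pair_index=3),
                  panel_from_log2({"upstream_effects": 3.0}, pair_index=4)]
        df = pair_index_summary(panels)
        row = df[(df.metric == "upstream_effects") & (df.group == "pairs_3_10")]
        assert row.log2_value.item() == 2.0

    def test_missing_metric_at_one_index_reduces_n(self):
        panels = [panel_from_log2({"upstream_effects": 1.0}, pair_index=3),
                  panel_from_log2({}, pair_index=4,
                                  reasons={"upstream_effects": "undefined:T_A"}),
                  panel_from_log2({"upstream_effects": 2.0}, pair_index=5)]
        df = pair_index_summary(panels)
        row = df[(df.metric == "upstream_effects") & (df.group == "pairs_3_10")]
        assert row.log2_value.item() == 1.5 and row.n.item() == 2

    def test_pair_one_and_two_rows_present_per_stratum(self):
        panels = [panel_from_log2({"upstream_effects": -1.0}, pair_index=1, stratum="high"),
                  panel_from_log2({"upstream_effects": -0.5}, pair_index=2, stratum="high")]
        df = pair_index_summary(panels)
        assert set(df.group) == {"pair_1", "pair_2"}
        assert set(df.stratum) == {"high"}
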