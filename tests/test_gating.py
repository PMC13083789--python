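"""Gate mechanics, composition accounting and sort outcomes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isletsort import (
    CellClass,
    EventTable,
    GateSpec,
    apply_gate,
    apply_sequential,
    composition,
    dual_sort_gates,
    sort_outcome,
    top_fraction_threshold,
)
from isletsort.errors import ConfigurationError
from isletsort.gating import positive_split_cutoff


def _table(values, labels=None, channels=("CD133",)):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values.reshape(-1, 1)
    return EventTable(channels=list(channels), intensities=values, labels=labels)


class TestGateSpec:
    def test_kind_field_consistency_enforced(self):
        with pytest.raises(ConfigurationError):
            GateSpec("CD133", "top_fraction", fraction=1.5)
        with pytest.raises(ConfigurationError):
            GateSpec("CD133", "top_fraction")
        with pytest.raises(ConfigurationError):
            GateSpec("CD133", "threshold")
        with pytest.raises(ConfigurationError):
            GateSpec("CD133", "positive_split", fraction=0.2)

    def test_dict_round_trip(self):
        for g in (*dual_sort_gates(),
                  GateSpec("GCG", "threshold", cutoff=100.0, direction="below")):
            assert GateSpec.from_dict(g.to_dict()) == g


class TestTopFraction:
    def test_methods_setting_selects_exact_fifth(self, rng):
        values = rng.permutation(np.linspace(1, 1000, 1000))
        out = apply_gate(_table(values), GateSpec("CD133", "top_fraction", fraction=0.20))
        assert out.n_events == 200
        assert sorted(out.channel_values("CD133")) == sorted(values)[-200:]

    def test_fraction_one_keeps_everything(self, rng):
        values = rng.lognormal(2, 0.4, 37)
        assert top_fraction_threshold(values, 1.0) == values.min()
        out = apply_gate(_table(values), GateSpec("CD133", "top_fraction", fraction=1.0))
        assert out.n_events == 37

    def test_ties_break_by_intensity_then_original_order(self):
        out = apply_gate(_table([1, 2, 2, 3]),
                         GateSpec("CD133", "top_fraction", fraction=0.5))
        # the 3 and the earlier-indexed 2 survive
        assert out.event_id.tolist() == [1, 3]

    @settings(derandomize=True, max_examples=150)
    @given(
        n=st.integers(1, 200),
        fraction=st.floats(0.001, 1.0, exclude_min=False),
        seed=st.integers(0, 2**20),
    )
    def test_cardinality_exactness(self, n, fraction, seed):
        values = np.random.default_rng(seed).lognormal(2, 0.5, n)
        out = apply_gate(_table(values),
                         GateSpec("CD133", "top_fraction", fraction=fraction))
        assert out.n_events == math.ceil(fraction * n)


class TestThresholdAndSplit:
    def test_vacuous_threshold_is_identity(self, rng):
        values = rng.lognormal(2, 0.3, 50)
        out = apply_gate(_table(values),
                         GateSpec("CD133", "threshold", cutoff=values.min() / 2))
        assert out.n_events == 50
        assert np.array_equal(out.event_id, np.arange(50))

    def test_threshold_idempotent(self, rng):
        values = rng.lognormal(2, 0.5, 100)
        gate = GateSpec("CD133", "threshold", cutoff=float(np.median(values)))
        once = apply_gate(_table(values), gate)
        twice = apply_gate(once, gate)
        assert np.array_equal(once.event_id, twice.event_id)

    def test_below_direction_complements_above(self, rng):
        values = rng.lognormal(2, 0.5, 60)
        cut = float(np.median(values))
        above = apply_gate(_table(values), GateSpec("CD133", "threshold", cutoff=cut))
        below = apply_gate(_table(values),
                           GateSpec("CD133", "threshold", cutoff=cut, direction="below"))
        ids = sorted(above.event_id.tolist() + below.event_id.tolist())
        assert ids == list(range(60))

    def test_positive_split_recovers_mode_membership(self, rng):
        # two well-separated log-normal modes: the split must equal
        # ground-truth high-mode membership
        lo = 10.0 ** rng.normal(1.0, 0.15, 400)
        hi = 10.0 ** rng.normal(2.6, 0.15, 600)
        values = np.concatenate([lo, hi])
        out = apply_gate(_table(values, channels=("CD49a",)),
                         GateSpec("CD49a", "positive_split"))
        assert sorted(out.event_id.tolist()) == list(range(400, 1000))

    def test_manual_cutoff_overrides_heuristic(self):
        values = np.array([1.0, 2.0, 100.0, 200.0])
        out = apply_gate(_table(values),
                         GateSpec("CD133", "positive_split", cutoff=150.0))
        assert out.event_id.tolist() == [3]

    def test_split_cutoff_lies_in_the_gap(self, rng):
        lo = 10.0 ** rng.normal(1.0, 0.15, 300)
        hi = 10.0 ** rng.normal(2.6, 0.15, 300)
        cut = positive_split_cutoff(np.concatenate([lo, hi]))
        assert lo.max() < cut < hi.min()

    def test_unknown_channel_rejected(self):
        with pytest.raises(KeyError):
            apply_gate(_table([1.0]), GateSpec("CD49a", "threshold", cutoff=1.0))

    def test_positive_split_needs_gate_override_not_error_on_single(self):
        out = apply_gate(_table([5.0]), GateSpec("CD133", "positive_split"))
        assert out.n_events == 1  # a lone value counts as positive


class TestSequential:
    def test_identity_gates_return_input(self, rng):
        values = rng.lognormal(2, 0.4, 30)
        g = GateSpec("CD133", "threshold", cutoff=values.min() / 2)
        out = apply_sequential(_table(values), [g, g])
        assert np.array_equal(out.event_id, np.arange(30))

    def test_empty_intermediate_short_circuits(self, rng):
        values = rng.lognormal(2, 0.4, 10)
        kill = GateSpec("CD133", "threshold", cutoff=values.max() * 2)
        out = apply_sequential(
            _table(values), [kill, GateSpec("CD133", "top_fraction", fraction=0.5)]
        )
        assert out.n_events == 0

    def test_gate_order_changes_survivors(self):
        # disjoint populations on two channels: a conditional top-half gate
        # gives a different survivor set depending on which gate runs first
        intensities = np.array([
            [10.0, 1.0],
            [20.0, 2.0],
            [1.0, 10.0],
            [2.0, 20.0],
        ])
        t = _table(intensities, channels=("CD133", "CD49a"))
        top_cd133 = GateSpec("CD133", "top_fraction", fraction=0.5)
        top_cd49a = GateSpec("CD49a", "top_fraction", fraction=0.5)
        ab = apply_sequential(t, [top_cd133, top_cd49a])
        ba = apply_sequential(t, [top_cd49a, top_cd133])
        assert ab.event_id.tolist() == [1]
        assert ba.event_id.tolist() == [3]

    def test_dual_gate_removes_ductal_contaminants(self, day7_table):
        cd133_only = apply_gate(day7_table,
                                GateSpec("CD133", "top_fraction", fraction=0.20))
        dual = apply_sequential(day7_table, dual_sort_gates())
        ductal_133 = composition(cd133_only).fraction(CellClass.DUCTAL)
        ductal_dual = composition(dual).fraction(CellClass.DUCTAL)
        assert ductal_dual < ductal_133
        assert composition(dual).fraction(CellClass.BETA) > \
            composition(day7_table).fraction(CellClass.BETA)

    def test_appending_gates_never_grows_class_counts(self, day7_table):
        gates = dual_sort_gates()
        prev = day7_table
        for g in gates:
            nxt = apply_gate(prev, g)
            for cls in CellClass:
                assert (np.count_nonzero(nxt.labels == cls.value)
                        <= np.count_nonzero(prev.labels == cls.value))
            prev = nxt


class TestOracleEquivalence:
    def test_gates_match_per_event_brute_force(self, rng):
        # every gate kind against naive per-event rule application
        for _ in range(60):
            n = int(rng.integers(1, 30))
            values = 10.0 ** rng.normal(2, 0.6, n)
            t = _table(values)

            frac = float(rng.uniform(0.05, 1.0))
            k = math.ceil(frac * n)
            order = sorted(range(n), key=lambda i: (-values[i], i))
            expect = sorted(order[:k])
            got = apply_gate(t, GateSpec("CD133", "top_fraction", fraction=frac))
            assert got.event_id.tolist() == expect

            cut = float(rng.uniform(values.min(), values.max()))
            expect = [i for i in range(n) if values[i] >= cut]
            got = apply_gate(t, GateSpec("CD133", "threshold", cutoff=cut))
            assert got.event_id.tolist() == expect

            split_cut = positive_split_cutoff(values)
            expect = [i for i in range(n) if values[i] >= split_cut]
            got = apply_gate(t, GateSpec("CD133", "positive_split"))
            assert got.event_id.tolist() == expect


class TestCompositionAndOutcome:
    def test_direct_count(self):
        labels = ["beta"] * 4 + ["other"] * 6
        comp = composition(_table(np.arange(1, 11), labels=labels))
        assert comp.fraction(CellClass.BETA) == pytest.approx(0.4)
        assert comp.n == 10

    def test_empty_table_composition_undefined(self):
        comp = composition(
            EventTable(channels=["CD133"], intensities=np.zeros((0, 1)), labels=[])
        )
        assert comp.n == 0 and comp.fractions is None
        with pytest.raises(ValueError):
            comp.fraction(CellClass.BETA)

    def test_unlabeled_table_rejected(self):
        with pytest.raises(ValueError):
            composition(_table([1.0, 2.0]))

    def test_fractions_match_weights_on_default_simulation(
        self, day7_table, default_config
    ):
        comp = composition(day7_table)
        for cls in CellClass:
            w = default_config.weights[cls]
            se = np.sqrt(w * (1 - w) / day7_table.n_events)
            assert abs(comp.fraction(cls) - w) < 3 * se

    def test_identity_sort_outcome(self, rng):
        labels = ["beta"] * 5 + ["ductal"] * 5
        t = _table(rng.lognormal(2, 0.3, 10), labels=labels)
        out = sort_outcome(t, t)
        assert out.yield_fraction == 1.0
        assert out.enrichment[CellClass.BETA] == pytest.approx(1.0)
        assert out.enrichment[CellClass.DELTA] is None  # absent pre-sort

    def test_hand_counted_enrichment(self):
        labels = ["beta"] * 5 + ["alpha_poly"] * 5
        pre = _table(np.arange(1.0, 11.0), labels=labels)
        post = pre.select(np.arange(5))  # the 5 beta events
        out = sort_outcome(pre, post)
        assert out.yield_fraction == pytest.approx(0.5)
        assert out.enrichment[CellClass.BETA] == pytest.approx(2.0)
        assert out.enrichment[CellClass.ALPHA_POLY] == pytest.approx(0.0)

    def test_non_subset_rejected(self, rng):
        a = _table(rng.lognormal(2, 0.3, 5), labels=["beta"] * 5)
        b = EventTable(channels=["CD133"], intensities=np.ones((2, 1)),
                       labels=["beta"] * 2, event_id=np.array([100, 101]))
        with pytest.raises(ValueError, match="subset"):
            sort_outcome(a, b)

    def test_dual_gate_enriches_beta_depletes_alpha(self, day7_table):
        dual = apply_sequential(day7_table, dual_sort_gates())
        out = sort_outcome(day7_table, dual)
        assert out.enrichment[CellClass.BETA] > 1.0
        assert out.enrichment[CellClass.ALPHA_POLY] < 1.0
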