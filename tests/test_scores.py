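import math
import random

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cascade_ne import (
    DockingScoreTable,
    PathwayNetwork,
    TransformConfig,
    line_value,
    load_scores,
    network_efficiency,
    reference_energies,
    reweight_for_compound,
)

from conftest import random_digraph


def make_table(rows):
    return DockingScoreTable.from_frame(
        pd.DataFrame(rows, columns=["compound", "target", "binding_energy"])
    )


class TestLoadScores:
    def test_positive_energy_clamped(self, tmp_path):
        p = tmp_path / "scores.csv"
        p.write_text("compound,target,binding_energy\nc1,thrombin,1.2\n")
        table = load_scores(p)
        assert table.frame["binding_energy"].iloc[0] == 0.0
        assert table.n_clamped == 1

    def test_negative_energy_unchanged(self, tmp_path):
        p = tmp_path / "scores.csv"
        p.write_text("compound,target,binding_energy\nc1,thrombin,-7.5\n")
        table = load_scores(p)
        assert table.frame["binding_energy"].iloc[0] == -7.5
        assert table.n_clamped == 0

    def test_duplicate_rows_rejected(self, tmp_path):
        p = tmp_path / "scores.csv"
        p.write_text(
            "compound,target,binding_energy\nc1,thrombin,-7.5\nc1,thrombin,-2.0\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_scores(p)

    def test_missing_column(self, tmp_path):
        p = tmp_path / "scores.csv"
        p.write_text("compound,binding_energy\nc1,-7.5\n")
        with pytest.raises(ValueError, match="target"):
            load_scores(p)

    def test_non_numeric_energy_names_row(self, tmp_path):
        p = tmp_path / "scores.csv"
        p.write_text("compound,target,binding_energy\nc1,thrombin,oops\n")
        with pytest.raises(ValueError, match="non-numeric"):
            load_scores(p)

    def test_tsv_accepted(self, tmp_path):
        p = tmp_path / "scores.tsv"
        p.write_text("compound\ttarget\tbinding_energy\nc1\tthrombin\t-3\n")
        assert load_scores(p).compounds == ["c1"]


class TestReferenceEnergies:
    def test_per_target_minimum(self):
        table = make_table(
            [("c1", "x", -3.0), ("c2", "x", -9.0), ("c3", "x", 0.0)]
        )
        refs = reference_energies(table)
        assert refs["x"] == -9.0

    def test_degenerate_target_flagged(self):
        table = make_table([("c1", "y", 0.0), ("c2", "y", 0.0)])
        refs = reference_energies(table)
        assert "y" in refs.degenerate

    def test_independent_per_target(self):
        table = make_table(
            [("c1", "x", -3.0), ("c1", "y", -5.0), ("c2", "x", -8.0),
             ("c2", "y", -1.0)]
        )
        refs = reference_energies(table)
        # brute-force minima per group
        assert refs["x"] == -8.0 and refs["y"] == -5.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            reference_energies(make_table([]))


class TestLineValue:
    def test_reference_ligand_gives_200(self):
        lv = line_value(-9.0, -9.0)
        assert lv == pytest.approx(10 ** 2.3)
        assert float(f"{lv:.3g}") == 200.0

    def test_zero_energy_floored_to_baseline(self):
        assert line_value(0.0, -9.0) == 10.0

    def test_half_reference(self):
        assert line_value(-4.5, -9.0) == pytest.approx(10 ** 1.15)

    def test_floor_disabled(self):
        cfg = TransformConfig(lv_floor=None)
        assert line_value(0.0, -9.0, cfg) == pytest.approx(1.0)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            line_value(-1.0, 0.0)

    def test_positive_energy_rejected(self):
        with pytest.raises(ValueError):
            line_value(0.5, -9.0)

    @given(st.floats(min_value=0.0, max_value=9.0))
    @settings(max_examples=60, derandomize=True)
    def test_bounded_between_floor_and_200(self, mag):
        lv = line_value(-mag, -9.0)
        assert 10.0 <= lv <= 10 ** 2.3 + 1e-9

    @given(
        st.floats(min_value=0.0, max_value=8.9),
        st.floats(min_value=0.01, max_value=0.1),
    )
    @settings(max_examples=60, derandomize=True)
    def test_monotone_in_energy_magnitude(self, mag, delta):
        assert line_value(-(mag + delta), -9.0) >= line_value(-mag, -9.0)


class TestReweighting:
    def test_reference_compound_stretches_all_out_edges(self):
        net = PathwayNetwork(
            [("t", "a", 10.0), ("t", "b", 10.0), ("a", "b", 10.0)]
        )
        table = make_table([("c1", "t", -9.0)])
        refs = reference_energies(table)
        out = reweight_for_compound(net, table, refs, "c1")
        assert out.line_value("t", "a") == pytest.approx(10 ** 2.3)
        assert out.line_value("t", "b") == pytest.approx(10 ** 2.3)
        assert out.line_value("a", "b") == 10.0

    def test_all_zero_scores_leave_network_unchanged(self):
        net = PathwayNetwork([("t", "a", 10.0), ("a", "b", 10.0)])
        table = make_table([("c1", "t", 0.0), ("c2", "t", -5.0)])
        refs = reference_energies(table)
        out = reweight_for_compound(net, table, refs, "c1")
        assert out == net

    def test_input_network_unmodified(self):
        net = PathwayNetwork([("t", "a", 10.0)])
        table = make_table([("c1", "t", -9.0)])
        reweight_for_compound(net, table, reference_energies(table), "c1")
        assert net.line_value("t", "a") == 10.0

    def test_two_targets_reweighted_independently(self):
        # manual assignment on a 5-node toy
        net = PathwayNetwork(
            [("t1", "m", 10.0), ("t2", "m", 10.0), ("m", "z", 10.0),
             ("z", "t1", 10.0)]
        )
        table = make_table(
            [("c1", "t1", -9.0), ("c1", "t2", -4.5),
             ("c2", "t1", -9.0), ("c2", "t2", -9.0)]
        )
        refs = reference_energies(table)
        out = reweight_for_compound(net, table, refs, "c1")
        assert out.line_value("t1", "m") == pytest.approx(10 ** 2.3)
        assert out.line_value("t2", "m") == pytest.approx(10 ** 1.15)
        assert out.line_value("m", "z") == 10.0
        assert out.line_value("z", "t1") == 10.0

    def test_absent_target_skipped(self, caplog):
        net = PathwayNetwork([("t", "a", 10.0)])
        table = make_table([("c1", "t", -9.0), ("c1", "ghost", -9.0)])
        refs = reference_energies(table)
        with caplog.at_level("WARNING", logger="cascade_ne.scores"):
            out = reweight_for_compound(net, table, refs, "c1")
        assert "ghost" in caplog.text
        assert out.line_value("t", "a") == pytest.approx(10 ** 2.3)

    @pytest.mark.parametrize("seed", range(10))
    def test_touches_exactly_scored_targets_out_edges(self, seed):
        rng = random.Random(seed)
        net = random_digraph(rng, weights=(10.0,))
        nodes = sorted(net.nodes)
        targets = rng.sample(nodes, min(3, len(nodes)))
        table = make_table(
            [(f"c", t, rng.uniform(-9.0, -1.0)) for t in targets]
        )
        refs = reference_energies(table)
        out = reweight_for_compound(net, table, refs, "c")
        expected_touched = {
            (u, v) for t in targets for u, v in net.out_edges(t)
        }
        changed = {
            (e.source, e.target)
            for e in out.edges()
            if e.line_value != 10.0
        }
        # every changed edge is an out-edge of a scored target; out-edges
        # whose LV lands on the floor stay at 10, hence subset
        assert changed <= expected_touched
        for u, v in expected_touched:
            lv = out.line_value(u, v)
            scored = [t for t in targets if u == t]
            assert lv == pytest.approx(
                max(
                    line_value(
                        table.frame.set_index("target")["binding_energy"][u],
                        refs[u],
                    ),
                    10.0,
                )
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_reweighted_ne_never_exceeds_baseline(self, seed):
        rng = random.Random(100 + seed)
        net = random_digraph(rng, weights=(10.0,))
        nodes = sorted(net.nodes)
        table = make_table(
            [("c", t, rng.uniform(-9.0, 0.0)) for t in
             rng.sample(nodes, min(4, len(nodes)))]
        )
        refs = reference_energies(table)
        if refs.degenerate == set(refs.energies):
            pytest.skip("all references degenerate for this draw")
        out = reweight_for_compound(net, table, refs, "c")
        assert (
            network_efficiency(out).ne
            <= network_efficiency(net).ne + 1e-12
        )
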