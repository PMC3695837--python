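import io
import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from envpath.annotate import Annotation
from envpath.errors import CatalogError, EnvPathError
from envpath.pathways import (
    ConfusionTable,
    PathwayDefinition,
    confusion,
    export_pathway_tables,
    f_measure,
    infer_pathways,
    pathway_recovery,
    perf_stats,
    predicted_set,
    read_pathway_catalog,
    write_pathway_catalog,
)


def ann(orf_id, ecs):
    return Annotation(orf_id, "x", frozenset(ecs), "db", 1, None)


def pwy(pid, reactions, keys=()):
    return PathwayDefinition(pid, pid, frozenset(reactions), frozenset(keys))


class TestInferPathways:
    CAT = [pwy("p1", ["1.1.1.1", "2.2.2.2"], ["1.1.1.1"])]

    def test_full_coverage_predicted(self):
        preds = infer_pathways([ann("o1", ["1.1.1.1"]), ann("o2", ["2.2.2.2"])], self.CAT)
        assert preds[0].predicted and preds[0].coverage == 1.0

    def test_no_coverage(self):
        preds = infer_pathways([], self.CAT)
        assert not preds[0].predicted and preds[0].coverage == 0.0

    def test_key_reaction_required(self):
        cat = [pwy("p", ["a", "b", "c", "d", "e"], keys=["a"])]
        anns = [ann(f"o{i}", [e]) for i, e in enumerate(["b", "c", "d"])]  # 0.6 coverage
        preds = infer_pathways(anns, cat, tau=0.5)
        assert not preds[0].predicted
        preds = infer_pathways(anns, cat, tau=0.5, require_key=False)
        assert preds[0].predicted

    def test_orfs_per_reaction(self):
        preds = infer_pathways([ann("o1", ["1.1.1.1"]), ann("o2", ["1.1.1.1"])], self.CAT)
        assert preds[0].orfs_per_reaction["1.1.1.1"] == {"o1", "o2"}
        assert preds[0].orfs_per_reaction["2.2.2.2"] == frozenset()

    def test_empty_reaction_set_rejected(self):
        with pytest.raises(CatalogError):
            pwy("bad", [])

    @given(
        st.sets(st.sampled_from(["a", "b", "c", "d", "e", "f"]), max_size=6),
        st.floats(min_value=0.05, max_value=0.95),
    )
    @settings(max_examples=60, deadline=None)
    def test_raising_tau_is_monotone(self, covered, tau):
        cat = [pwy("p", ["a", "b", "c", "d", "e", "f"])]
        anns = [ann(f"o{i}", [e]) for i, e in enumerate(sorted(covered))]
        lo = infer_pathways(anns, cat, tau=tau)[0].predicted
        hi = infer_pathways(anns, cat, tau=min(tau + 0.3, 1.0))[0].predicted
        assert not (hi and not lo)


class TestExportTables:
    def test_row_counts(self, tmp_path):
        cat = [pwy("p1", ["a", "b", "c"]), pwy("p2", ["d"])]
        preds = infer_pathways([ann("o1", ["a"])], cat)
        p_path, r_path = tmp_path / "p.txt", tmp_path / "r.txt"
        export_pathway_tables(preds, cat, p_path, r_path)
        p_lines = [l for l in p_path.read_text().splitlines() if not l.startswith("#")]
        r_lines = [l for l in r_path.read_text().splitlines() if not l.startswith("#")]
        assert len(p_lines) == 2
        assert len(r_lines) == 4  # 3 reactions + 1 reaction

    def test_empty_predictions_header_only(self, tmp_path):
        p_path, r_path = tmp_path / "p.txt", tmp_path / "r.txt"
        export_pathway_tables([], [], p_path, r_path)
        assert p_path.read_text().startswith("#")
        assert len(p_path.read_text().splitlines()) == 1

    def test_catalog_round_trip(self, tmp_path):
        cat = [pwy("p1", ["1.1.1.1", "2.2.2.2"], ["1.1.1.1"]), pwy("p2", ["3.3.3.3"])]
        path = tmp_path / "cat.tsv"
        write_pathway_catalog(cat, path)
        again = read_pathway_catalog(path)
        assert again == cat


class TestConfusion:
    def test_perfect(self):
        t = confusion({"a"}, {"a"}, {"a", "b"})
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 0, 0, 1)

    def test_disjoint(self):
        universe = {str(i) for i in range(20)}
        pred = {str(i) for i in range(5)}
        gold = {str(i) for i in range(5, 10)}
        t = confusion(pred, gold, universe)
        assert (t.tp, t.fp, t.fn, t.tn) == (0, 5, 5, 10)

    def test_empty_pred(self):
        t = confusion(set(), {"a", "b"}, {"a", "b", "c"})
        assert (t.tp, t.fp, t.fn, t.tn) == (0, 0, 2, 1)

    def test_outside_universe_errors(self):
        with pytest.raises(EnvPathError):
            confusion({"x"}, set(), {"a"})
        with pytest.raises(EnvPathError):
            confusion(set(), {"x"}, {"a"})


def naive_stats(tp, fp, fn, tn):
    """Independent re-derivation used as the oracle for perf_stats."""
    def div(n, d):
        return n / d if d else 0.0

    p = div(tp, tp + fp)
    s = div(tp, tp + fn)
    return {
        "precision": p,
        "sensitivity": s,
        "specificity": div(tn, tn + fp),
        "accuracy": div(tp + tn, tp + fp + fn + tn),
        "f_measure": div(2 * p * s, p + s),
        "matthews": div(
            tp * tn - fp * fn,
            math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)),
        ),
    }


class TestPerfStats:
    def test_perfect_table(self):
        stats = perf_stats(ConfusionTable(1, 0, 0, 1))
        assert stats.precision == stats.sensitivity == stats.specificity == 1.0
        assert stats.accuracy == stats.f_measure == stats.matthews == 1.0

    def test_paper_f_measures(self):
        assert round(f_measure(0.95, 0.81), 2) == 0.87
        assert round(f_measure(0.96, 0.31), 2) == 0.47

    def test_all_zero_errors(self):
        with pytest.raises(EnvPathError):
            perf_stats(ConfusionTable(0, 0, 0, 0))

    def test_zero_over_zero_is_zero(self):
        stats = perf_stats(ConfusionTable(0, 0, 0, 5))
        assert stats.precision == 0.0 and stats.sensitivity == 0.0
        assert stats.f_measure == 0.0 and stats.matthews == 0.0

    def test_matches_oracle_small_tables(self):
        for tp, fp, fn in itertools.product(range(8), repeat=3):
            for tn in range(8):
                if tp + fp + fn + tn == 0:
                    continue
                stats = perf_stats(ConfusionTable(tp, fp, fn, tn))
                oracle = naive_stats(tp, fp, fn, tn)
                for key, value in oracle.items():
                    assert getattr(stats, key) == pytest.approx(value), (tp, fp, fn, tn, key)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=100, deadline=None)
    def test_f_measure_below_arithmetic_mean(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        stats = perf_stats(ConfusionTable(tp, fp, fn, tn))
        assert stats.f_measure <= (stats.precision + stats.sensitivity) / 2 + 1e-12
        assert -1 <= stats.matthews <= 1
        for value in (stats.precision, stats.sensitivity, stats.specificity, stats.accuracy):
            assert 0 <= value <= 1


class TestPathwayRecovery:
    def test_perfect(self):
        assert pathway_recovery({"a"}, {"a"}) == 100.0

    def test_partial(self):
        gold = {str(i) for i in range(10)}
        pred = {str(i) for i in range(8)}
        assert pathway_recovery(pred, gold) == 80.0

    def test_empty_pred(self):
        assert pathway_recovery(set(), {"a"}) == 0.0

    def test_empty_gold_errors(self):
        with pytest.raises(EnvPathError):
            pathway_recovery({"a"}, set())
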