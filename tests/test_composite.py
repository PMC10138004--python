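"""Composite panels: normalization, geometric-mean scores, sensitivity."""

import numpy as np
import pandas as pd
import pytest

from hydrorqa import (
    AnalysisConfig,
    SimConfig,
    Coupling,
    build_panel,
    generate,
    geometric_mean_score,
    length_sensitivity,
    min_max_normalize,
    normalize_panels,
    render_heatmap,
)
from hydrorqa.composite import INDEX_COLUMNS, CouplingPanel


def panel_from_table(rows):
    return CouplingPanel(("ST1", "pH"), pd.DataFrame(rows))


def make_row(station, factor, **idx):
    base = {"station": station, "factor": factor,
            "rr": 0.1, "det": 0.5, "lam": 0.5, "mdl": 3.0, "mi": 0.2}
    base.update(idx)
    return base


QUICK = AnalysisConfig(
    epsilon_fraction=0.1, max_delay=20, max_dim=5,
    fnn_max_points=500, param_scope="panel",
)


class TestNormalization:
    def test_column_maps_to_unit_interval(self):
        p = panel_from_table(
            [make_row("ST1", "a", rr=2.0), make_row("ST1", "b", rr=4.0),
             make_row("ST1", "c", rr=6.0)]
        )
        norm = min_max_normalize(p)
        np.testing.assert_allclose(norm.normalized["rr"], [0.0, 0.5, 1.0])

    def test_constant_column_becomes_all_ones(self):
        p = panel_from_table([make_row("ST1", "a"), make_row("ST1", "b")])
        norm = min_max_normalize(p)
        assert (norm.normalized[INDEX_COLUMNS] == 1.0).all().all()
        assert (norm.scores == 1.0).all()

    def test_random_panels_hit_zero_and_one(self, rng):
        rows = [
            make_row("ST1", f"f{k}", rr=v, det=rng.random(), mi=rng.random())
            for k, v in enumerate(rng.random(6))
        ]
        norm = min_max_normalize(panel_from_table(rows))
        for col in ("rr", "det", "mi"):  # the columns drawn at random
            vals = norm.normalized[col]
            assert vals.min() == 0.0 and vals.max() == 1.0
        for col in ("lam", "mdl"):  # constant across rows -> all ones
            assert (norm.normalized[col] == 1.0).all()

    def test_floor_lifts_zeros(self):
        p = panel_from_table(
            [make_row("ST1", "a", rr=0.0), make_row("ST1", "b", rr=1.0)]
        )
        norm = min_max_normalize(p, floor=0.05)
        assert norm.normalized["rr"].min() == 0.05

    def test_global_scope_pools_rows(self):
        p1 = panel_from_table([make_row("ST1", "a", rr=0.0), make_row("ST1", "b", rr=1.0)])
        p2 = panel_from_table([make_row("ST2", "a", rr=3.0), make_row("ST2", "b", rr=5.0)])
        g1, g2 = normalize_panels([p1, p2], scope="global")
        # global min 0, max 5: ST2 rows map to 0.6 and 1.0
        np.testing.assert_allclose(g2.normalized["rr"], [0.6, 1.0])
        np.testing.assert_allclose(g1.normalized["rr"], [0.0, 0.2])


class TestGeometricMean:
    def test_all_ones_is_one(self):
        assert geometric_mean_score([1, 1, 1, 1, 1]) == 1.0

    def test_any_zero_annihilates(self):
        assert geometric_mean_score([1, 1, 0, 1, 1]) == 0.0

    def test_constant_vector_is_idempotent(self):
        assert geometric_mean_score([0.3] * 5) == pytest.approx(0.3)

    def test_monotone_in_each_index(self):
        low = geometric_mean_score([0.5, 0.5, 0.2, 0.5, 0.5])
        high = geometric_mean_score([0.5, 0.5, 0.6, 0.5, 0.5])
        assert high > low

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            geometric_mean_score([0.5, -0.1, 0.5, 0.5, 0.5])


class TestBuildPanel:
    def test_self_candidate_dominates_raw_indices(self, small_dataset):
        target = ("ST1", "pH")
        candidates = [("ST1", "pH"), ("ST1", "Do"), ("ST2", "Temp")]
        panel = build_panel(target, candidates, small_dataset, QUICK)
        t = panel.table.set_index("factor")
        self_row = panel.table[
            (panel.table["station"] == "ST1") & (panel.table["factor"] == "pH")
        ].iloc[0]
        others = panel.table.drop(self_row.name)
        for col in ("rr", "det", "mi"):
            assert self_row[col] >= others[col].max()

    def test_single_candidate_panel_has_defined_score(self, small_dataset):
        panel = min_max_normalize(
            build_panel(("ST1", "pH"), [("ST2", "pH")], small_dataset, QUICK)
        )
        assert panel.scores.iloc[0] == 1.0  # degenerate normalization convention

    def test_empty_candidates_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="at least one candidate"):
            build_panel(("ST1", "pH"), [], small_dataset, QUICK)

    def test_ranking_breaks_ties_lexicographically(self):
        p = min_max_normalize(
            panel_from_table([make_row("ST1", "b"), make_row("ST1", "a")])
        )
        ranked = p.ranking()
        assert list(ranked["factor"]) == ["a", "b"]  # equal scores -> name order

    def test_params_cache_is_reused(self, small_dataset):
        cache = {}
        build_panel(("ST1", "pH"), [("ST2", "pH")], small_dataset, QUICK, params_cache=cache)
        first = dict(cache)
        build_panel(("ST1", "pH"), [("ST2", "pH")], small_dataset, QUICK, params_cache=cache)
        assert cache == first and ("ST1", "pH") in cache


class TestLengthSensitivity:
    def test_full_against_itself_is_perfect(self, small_dataset):
        sens = length_sensitivity(
            small_dataset, ("ST1", "pH"),
            [("ST2", "pH"), ("ST1", "Do"), ("ST1", "Temp")],
            lengths=(None,), config=QUICK,
        )
        assert sens.spearman[small_dataset.n_samples] == 1.0

    def test_truncation_beyond_record_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="exceeds"):
            length_sensitivity(
                small_dataset, ("ST1", "pH"), [("ST2", "pH")],
                lengths=(10_000,), config=QUICK,
            )

    def test_scores_indexed_by_candidate(self, small_dataset):
        sens = length_sensitivity(
            small_dataset, ("ST1", "pH"),
            [("ST2", "pH"), ("ST1", "Temp")],
            lengths=(400, None), config=QUICK,
        )
        assert sens.lengths == [400, 600]
        assert set(sens.scores.index) == {("ST2", "pH"), ("ST1", "Temp")}


class TestHeatmap:
    def test_renders_png(self, small_dataset, tmp_path):
        panel = min_max_normalize(
            build_panel(("ST1", "pH"), [("ST1", "Do"), ("ST1", "Temp")],
                        small_dataset, QUICK)
        )
        path = tmp_path / "heat.png"
        render_heatmap(panel, path)
        assert path.stat().st_size > 0

    def test_unnormalized_panel_rejected(self):
        p = panel_from_table([make_row("ST1", "a")])
        with pytest.raises(ValueError, match="normalize"):
            render_heatmap(p, "unused.png")
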