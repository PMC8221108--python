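"""Aggregation and group-comparison tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from clearmorph.io import SampleMetadata
from clearmorph.stats import (
    InsufficientDataError,
    compare_groups,
    ipsi_contra_ratio,
    shape_scatter_table,
    summarize_sample,
    volume_frequency_distribution,
)


def _records(n, vol=300.0, e_pro=0.2, e_ob=0.5, rng=None):
    vols = np.full(n, vol) if rng is None else rng.normal(vol, 40, n)
    return pd.DataFrame(
        {
            "volume_um3": vols,
            "sphericity": np.full(n, 0.9),
            "e_prolate": np.full(n, e_pro),
            "e_oblate": np.full(n, e_ob),
        }
    )


def _md(side="ipsilateral", animal="a1", **kw):
    defaults = dict(sex="male", condition="SNI", tissue="DRG")
    defaults.update(kw)
    return SampleMetadata(sample_id=f"{animal}-{side}", side=side, animal_id=animal, **defaults)


class TestSummarize:
    def test_density_arithmetic_exact(self):
        s = summarize_sample(_records(120), 2e6, _md())
        assert s.density_per_1e6um3 == pytest.approx(60.0)
        assert s.n_cells == 120

    def test_empty_records_flagged(self):
        s = summarize_sample(_records(0), 1e6, _md())
        assert s.n_cells == 0
        assert np.isnan(s.mean_cell_volume_um3)
        assert s.histogram_freq.size == 0
        assert "no_cells" in s.flags

    def test_histogram_normalized(self, rng):
        s = summarize_sample(_records(500, rng=rng), 1e6, _md(), histogram_bins=15)
        assert s.histogram_freq.sum() == pytest.approx(1.0)
        assert len(s.histogram_edges_um3) == 16

    def test_nonpositive_tissue_volume_rejected(self):
        with pytest.raises(ValueError):
            summarize_sample(_records(5), 0.0, _md())

    def test_density_matches_ground_truth_on_synthetic_sample(self, clean_scene):
        from clearmorph.morphometry import measure_all
        from clearmorph.segmentation import SegmentationParams, segment_cells, subtract_background

        spec, stack, truth = clean_scene
        lv = segment_cells(subtract_background(stack, 10.0), SegmentationParams())
        recs = pd.DataFrame([r.to_dict() for r in measure_all(lv)])
        s = summarize_sample(recs, truth.tissue_volume_um3, _md())
        true_density = len(truth.cells()) / truth.tissue_volume_um3 * 1e6
        assert s.density_per_1e6um3 == pytest.approx(true_density, rel=0.05)


class TestRatio:
    def test_three_to_one(self):
        ipsi = summarize_sample(_records(90), 1e6, _md("ipsilateral"))
        contra = summarize_sample(_records(30), 1e6, _md("contralateral"))
        r = ipsi_contra_ratio(ipsi, contra)
        assert r.count_ratio == pytest.approx(3.0)
        assert r.mean_volume_ratio == pytest.approx(1.0)

    def test_identical_summaries_ratio_one(self):
        ipsi = summarize_sample(_records(40), 1e6, _md("ipsilateral"))
        contra = summarize_sample(_records(40), 1e6, _md("contralateral"))
        assert ipsi_contra_ratio(ipsi, contra).count_ratio == pytest.approx(1.0)

    def test_zero_contra_flagged_not_infinite(self):
        ipsi = summarize_sample(_records(10), 1e6, _md("ipsilateral"))
        contra = summarize_sample(_records(0), 1e6, _md("contralateral"))
        r = ipsi_contra_ratio(ipsi, contra)
        assert np.isnan(r.count_ratio)
        assert "contra_zero_count" in r.flags

    def test_mismatched_pair_rejected(self):
        ipsi = summarize_sample(_records(10), 1e6, _md("ipsilateral", animal="a1"))
        contra = summarize_sample(_records(10), 1e6, _md("contralateral", animal="a2"))
        with pytest.raises(ValueError, match="animal"):
            ipsi_contra_ratio(ipsi, contra)


class TestHistogramTable:
    def test_single_cell_single_bin(self):
        t = volume_frequency_distribution({"g": _records(1)}, bins=5)
        assert t["frequency"].sum() == pytest.approx(1.0)
        assert (t["frequency"] == 1.0).sum() == 1

    def test_same_distribution_converges(self, rng):
        a = _records(4000, rng=rng)
        b = _records(4000, rng=rng)
        t = volume_frequency_distribution({"a": a, "b": b}, bins=10)
        wide = t.pivot(index="group", columns="bin_left_um3", values="frequency")
        assert np.abs(wide.loc["a"] - wide.loc["b"]).max() < 0.05

    def test_empty_group_zero_row_flagged(self):
        t = volume_frequency_distribution({"a": _records(5), "b": _records(0)}, bins=4)
        b = t[t["group"] == "b"]
        assert b["frequency"].sum() == 0.0
        assert b["empty"].all()


class TestCompareGroups:
    def _obs(self, values_by_group, factor="grp"):
        rows = []
        for g, vals in values_by_group.items():
            for v in vals:
                rows.append({factor: g, "value": v})
        return pd.DataFrame(rows)

    def test_identical_groups_not_significant(self):
        obs = self._obs({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        (comp,) = compare_groups(obs, "value", "grp")
        assert comp.test == "t_test"
        assert comp.p_value == pytest.approx(1.0)
        assert not comp.significant

    def test_constant_identical_groups_p_one(self):
        obs = self._obs({"a": [5.0, 5.0], "b": [5.0, 5.0]})
        (comp,) = compare_groups(obs, "value", "grp")
        assert comp.p_value == 1.0

    def test_large_shift_detected(self, rng):
        obs = self._obs({"a": rng.normal(0, 1, 8), "b": rng.normal(5, 1, 8)})
        (comp,) = compare_groups(obs, "value", "grp")
        assert comp.significant

    def test_one_way_anova_with_bonferroni(self, rng):
        obs = self._obs({"a": rng.normal(0, 1, 6), "b": rng.normal(0, 1, 6), "c": rng.normal(6, 1, 6)})
        (comp,) = compare_groups(obs, "value", "grp")
        assert comp.test == "anova_1way"
        assert comp.significant
        assert len(comp.contrasts) == 3
        for k in comp.contrasts:
            assert k.p_adj >= k.p_raw
            assert k.significant == (k.p_adj < comp.alpha)
        sig = {frozenset(k.groups): k.significant for k in comp.contrasts}
        assert sig[frozenset(("a", "c"))] and sig[frozenset(("b", "c"))]
        assert not sig[frozenset(("a", "b"))]

    def test_two_way_anova_terms_and_contrasts(self, rng):
        rows = []
        for sex in ("male", "female"):
            for side in ("ipsilateral", "contralateral"):
                shift = 6.0 if (sex, side) == ("male", "ipsilateral") else 0.0
                for v in rng.normal(shift, 1, 4):
                    rows.append({"sex": sex, "side": side, "value": v})
        obs = pd.DataFrame(rows)
        comps = compare_groups(obs, "value", ["sex", "side"])
        assert [c.term for c in comps] == ["sex", "side", "sex:side"]
        assert comps[2].significant  # interaction drives the pattern
        contrasts = comps[0].contrasts
        assert len(contrasts) == 6  # all pairwise cells, one Bonferroni family
        target = {k.significant for k in contrasts if "male:ipsilateral" in k.groups}
        assert target == {True}

    def test_single_group_rejected(self):
        obs = self._obs({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(InsufficientDataError, match="two groups"):
            compare_groups(obs, "value", "grp")

    def test_insufficient_cell_names_the_cell(self):
        obs = self._obs({"a": [1.0, 2.0], "b": [1.0]})
        with pytest.raises(InsufficientDataError, match="'b'"):
            compare_groups(obs, "value", "grp")


class TestScatterTable:
    def test_empty_groups_empty_table(self):
        t = shape_scatter_table({"a": _records(0)})
        assert len(t) == 0
        assert list(t.columns) == ["group", "e_oblate", "e_prolate", "sphericity"]

    def test_row_count_equals_total_cells(self):
        t = shape_scatter_table({"a": _records(7), "b": _records(4)})
        assert len(t) == 11

    def test_group_means_ordered_as_constructed(self):
        t = shape_scatter_table(
            {"sham": _records(30, e_ob=0.3), "SNI": _records(30, e_ob=0.7)}
        )
        means = t.groupby("group")["e_oblate"].mean()
        assert means["SNI"] > means["sham"]
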