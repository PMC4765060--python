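import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bigih.core_io import CONTRA, IPSI, AnalysisConfig, ConfigError, InputError
from bigih.expression_prep import (
    detection_call,
    detection_calls_from_probes,
    discrimination_scores,
    select_changed_genes,
    signed_fold_change,
    wilcoxon_signed_rank_right_p,
)


def brute_force_right_p(diffs) -> float:
    """Independent oracle: enumerate all sign assignments explicitly."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    hits = sum(np.dot(signs, ranks) >= w_obs - 1e-12
               for signs in itertools.product((0, 1), repeat=d.size))
    return hits / 2.0 ** d.size


class TestDiscriminationScores:
    @pytest.mark.parametrize("pm, mm, expected", [
        ([100], [100], [0.0]),
        ([100], [0], [1.0]),
        ([200, 150], [100, 50], [1 / 3, 1 / 2]),
    ])
    def test_examples(self, pm, mm, expected):
        assert discrimination_scores(pm, mm) == pytest.approx(expected)

    def test_zero_intensity_pairs_excluded(self):
        with pytest.warns(UserWarning, match="zero-intensity"):
            r = discrimination_scores([100, 0], [50, 0])
        assert r == pytest.approx([1 / 3])
        with pytest.raises(InputError):
            discrimination_scores([0], [0])

    def test_bounded(self, rng):
        pm = rng.uniform(0, 1000, 50)
        mm = rng.uniform(0.1, 1000, 50)
        r = discrimination_scores(pm, mm)
        assert np.all(np.abs(r) <= 1)


class TestDetectionCall:
    def test_strong_signal_is_present_with_exact_p(self):
        # 11 identical positive scores: only the all-positive assignment
        # reaches the observed rank sum, so p = 2^-11
        call, p = detection_call([0.5] * 11, tau=0.015)
        assert p == pytest.approx(2 ** -11)
        assert call == "present"

    def test_threshold_bracketing_gives_marginal(self):
        call, p = detection_call([0.5] * 11, tau=0.015,
                                 alpha1=0.0001, alpha2=0.001)
        assert p == pytest.approx(2 ** -11)
        assert call == "marginal"

    def test_symmetric_scores_are_absent(self):
        call, p = detection_call([-0.3, 0.3, -0.2, 0.2], tau=0.0)
        assert p >= 0.5
        assert call == "absent"

    def test_degenerate_all_equal_tau(self):
        with pytest.warns(UserWarning, match="degenerate"):
            call, p = detection_call([0.015] * 5, tau=0.015)
        assert (call, p) == ("absent", 1.0)

    def test_invariant_under_permutation(self, rng):
        scores = rng.uniform(-1, 1, 9)
        p1 = detection_call(scores, tau=0.0)[1]
        p2 = detection_call(rng.permutation(scores), tau=0.0)[1]
        assert p1 == p2

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(min_value=-1, max_value=1, width=32,
                              allow_nan=False), min_size=1, max_size=12))
    def test_exact_p_matches_enumeration_oracle(self, scores):
        d = np.asarray(scores) - 0.015
        assert wilcoxon_signed_rank_right_p(d) == pytest.approx(
            brute_force_right_p(d))

    def test_probe_table_interface(self):
        probes = pd.DataFrame({
            "gene": ["g1"] * 22, "sample": ["s1"] * 11 + ["s2"] * 11,
            "pm": [300.0] * 11 + [100.0] * 11,
            "mm": [100.0] * 11 + [100.0] * 11,
        })
        calls = detection_calls_from_probes(probes)
        by = calls.set_index("sample")["call"]
        assert by["s1"] == "present"
        assert by["s2"] == "absent"


class TestSignedFoldChange:
    @pytest.mark.parametrize("a, b, expected", [
        (100, 50, 2.0), (50, 100, -2.0), (100, 100, 1.0)])
    def test_examples(self, a, b, expected):
        assert signed_fold_change(a, b) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=1e-3, max_value=1e6),
           st.floats(min_value=1e-3, max_value=1e6))
    def test_antisymmetry_and_identity(self, a, b):
        fc = signed_fold_change(a, b)
        assert abs(fc) >= 1
        if a != b:
            assert signed_fold_change(b, a) == pytest.approx(-fc)

    def test_nonpositive_mean_is_error(self):
        with pytest.raises(InputError):
            signed_fold_change(0.0, 1.0)


class TestSelectChangedGenes:
    def test_selection_with_presence(self, small_matrix, all_present_calls):
        sel = select_changed_genes(small_matrix, all_present_calls)
        ipsi = sel[IPSI].set_index("gene")
        contra = sel[CONTRA].set_index("gene")
        # UPGENE: +2.5 ipsi (kept), +1.5 contra (below cutoff)
        assert ipsi.loc["UPGENE", "signed_fc"] == pytest.approx(2.5)
        assert "UPGENE" not in contra.index
        # DOWNGENE: -2 ipsi (boundary kept: "2-fold or more"), -4 contra
        assert ipsi.loc["DOWNGENE", "signed_fc"] == pytest.approx(-2.0)
        assert contra.loc["DOWNGENE", "signed_fc"] == pytest.approx(-4.0)
        assert "FLATGENE" not in ipsi.index

    def test_presence_rule_drops_gene_absent_on_both_sides(
            self, small_matrix, all_present_calls):
        calls = all_present_calls.copy()
        mask = (calls["gene"] == "DOWNGENE") & calls["sample"].isin(
            ["ipsi_2", "contra_3"])
        calls.loc[mask, "call"] = "absent"
        sel = select_changed_genes(small_matrix, calls)
        assert "DOWNGENE" not in set(sel[IPSI]["gene"])
        assert "DOWNGENE" not in set(sel[CONTRA]["gene"])
        # present in all ipsi samples is enough for BOTH sides
        calls2 = all_present_calls.copy()
        mask2 = (calls2["gene"] == "DOWNGENE") & calls2["sample"].isin(
            ["contra_3"])
        calls2.loc[mask2, "call"] = "marginal"  # marginal does not count
        sel2 = select_changed_genes(small_matrix, calls2)
        assert "DOWNGENE" in set(sel2[CONTRA]["gene"])

    def test_raising_cutoff_is_monotone(self, small_matrix, all_present_calls):
        lo = select_changed_genes(small_matrix, all_present_calls,
                                  AnalysisConfig(fold_change_cutoff=2.0))
        hi = select_changed_genes(small_matrix, all_present_calls,
                                  AnalysisConfig(fold_change_cutoff=3.0))
        for side in (IPSI, CONTRA):
            assert set(hi[side]["gene"]) <= set(lo[side]["gene"])

    def test_missing_naive_group_is_config_error(self, small_matrix):
        groups = {s: (IPSI if g == "naive" else g)
                  for s, g in small_matrix.groups.items()}
        from bigih.core_io import ExpressionMatrix
        m = ExpressionMatrix(values=small_matrix.values, groups=groups)
        with pytest.raises(ConfigError, match="naive"):
            select_changed_genes(m, None)
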