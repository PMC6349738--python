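"""Transformation selection, Tukey-Kramer, compact letter display."""

import io
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from epgkit.io import read_metadata
from epgkit.stats import (group_compare, piepho_letters, select_transform,
                          tukey_kramer)


def letters_satisfy_display_property(labels, sig, letters):
    for i, j in combinations(range(len(labels)), 2):
        share = bool(set(letters[labels[i]]) & set(letters[labels[j]]))
        if share == bool(sig[i, j]):
            return False
    return True


class TestSelectTransform:
    def test_lognormal_sample_selects_log(self):
        rng = np.random.default_rng(10)
        x = np.exp(rng.normal(0, 1, size=500))
        spec = select_transform(x)
        assert -0.25 <= spec.lam <= 0.25
        assert not spec.arcsine_first and spec.shift == 0

    def test_gaussian_sample_selects_near_identity(self):
        rng = np.random.default_rng(11)
        x = rng.normal(100, 5, size=500)
        spec = select_transform(x)
        assert 0.5 <= spec.lam <= 1.75

    def test_zeros_produce_recorded_shift(self):
        x = np.array([0.0, 0.0, 2.0, 4.0, 8.0, 16.0])
        spec = select_transform(x)
        assert spec.shift == 1.0  # half the smallest positive value
        assert np.all(np.isfinite(spec.apply(x)))

    def test_proportion_typed_arcsine_first(self):
        rng = np.random.default_rng(12)
        x = 100 * rng.beta(2, 5, size=100)
        spec = select_transform(x, proportion_typed=True)
        assert spec.arcsine_first
        expected = np.arcsin(np.sqrt(x / 100)) + spec.shift
        if spec.lam == 0:
            expected = np.log(expected)
        else:
            expected = (expected**spec.lam - 1) / spec.lam
        assert np.allclose(spec.apply(x), expected)

    @pytest.mark.parametrize("bad, match", [
        ([3.0, 3.0, 3.0, 3.0], "degenerate"),
        ([1.0, 2.0, -1.0, 4.0], "negative"),
        ([1.0, 2.0], ">=4"),
    ])
    def test_error_contracts(self, bad, match):
        with pytest.raises(ValueError, match=match):
            select_transform(bad)

    def test_shapiro_statistic_reported(self):
        rng = np.random.default_rng(13)
        spec = select_transform(rng.lognormal(0, 0.5, 200))
        assert 0.9 < spec.shapiro_w <= 1.0


class TestTukeyKramer:
    def test_identical_groups_p_one(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        p = tukey_kramer({"a": v, "b": v.copy()})
        assert p.loc["a", "b"] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(p, p.T) and np.all(np.diag(p) == 1)

    def test_separated_means_tiny_variance(self):
        rng = np.random.default_rng(14)
        groups = {lab: mu + 1e-6 * rng.normal(size=5)
                  for lab, mu in [("a", 0), ("b", 10), ("c", 20)]}
        p = tukey_kramer(groups)
        off = p.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.all(off < 1e-6)

    def test_two_balanced_groups_reduce_to_pooled_t(self):
        rng = np.random.default_rng(15)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        p_tk = tukey_kramer({"a": a, "b": b}).loc["a", "b"]
        p_t = sps.ttest_ind(a, b, equal_var=True).pvalue
        assert p_tk == pytest.approx(p_t, rel=1e-6)

    def test_matches_statsmodels_with_unequal_n(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(16)
        sizes = {"a": 6, "b": 9, "c": 14, "d": 5}
        shifts = {"a": 0.0, "b": 0.8, "c": 1.6, "d": 0.4}
        groups = {k: shifts[k] + rng.normal(size=n) for k, n in sizes.items()}
        ours = tukey_kramer(groups)
        data = np.concatenate(list(groups.values()))
        labs = np.concatenate([[k] * sizes[k] for k in groups])
        res = pairwise_tukeyhsd(data, labs)
        table = pd.DataFrame(res._results_table.data[1:],
                             columns=res._results_table.data[0])
        for _, row in table.iterrows():
            assert ours.loc[row["group1"], row["group2"]] == pytest.approx(
                float(row["p-adj"]), abs=2e-4)

    def test_small_group_error_names_group(self):
        with pytest.raises(ValueError, match="tiny"):
            tukey_kramer({"ok": np.arange(4.0), "tiny": np.array([1.0])})


class TestPiephoLetters:
    def test_no_significant_pairs_single_letter(self):
        sig = np.zeros((3, 3), bool)
        assert piepho_letters(["x", "y", "z"], sig) == {
            "x": "a", "y": "a", "z": "a"}

    def test_chain_of_three(self):
        # only (1,3) significant -> a, ab, b
        sig = np.zeros((3, 3), bool)
        sig[0, 2] = sig[2, 0] = True
        letters = piepho_letters(["g1", "g2", "g3"], sig)
        assert letters == {"g1": "a", "g2": "ab", "g3": "b"}

    def test_four_groups_partial_separation(self):
        # significant pairs (1,4) and (2,4); 3 bridges both sides
        sig = np.zeros((4, 4), bool)
        for i, j in [(0, 3), (1, 3)]:
            sig[i, j] = sig[j, i] = True
        labels = ["g1", "g2", "g3", "g4"]
        letters = piepho_letters(labels, sig)
        assert letters_satisfy_display_property(labels, sig, letters)
        assert set(letters["g3"]) & set(letters["g4"])
        assert set(letters["g3"]) & set(letters["g1"])

    def test_discontinuous_letters_appear(self):
        # disjoint significant pairs force a string like "ac"
        sig = np.zeros((4, 4), bool)
        for i, j in [(0, 1), (2, 3)]:
            sig[i, j] = sig[j, i] = True
        labels = list("wxyz")
        letters = piepho_letters(labels, sig)
        assert letters_satisfy_display_property(labels, sig, letters)
        assert any(_is_discontinuous(s) for s in letters.values())

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_display_property_random_matrices(self, k):
        rng = np.random.default_rng(17 + k)
        labels = [f"g{i}" for i in range(k)]
        for _ in range(60):
            sig = np.zeros((k, k), bool)
            for i, j in combinations(range(k), 2):
                sig[i, j] = sig[j, i] = rng.random() < 0.4
            letters = piepho_letters(labels, sig)
            assert letters_satisfy_display_property(labels, sig, letters)
            assert all(letters[lab] for lab in labels)

    def test_asymmetric_matrix_rejected(self):
        sig = np.zeros((3, 3), bool)
        sig[0, 1] = True
        with pytest.raises(ValueError, match="symmetric"):
            piepho_letters(["a", "b", "c"], sig)


def _is_discontinuous(s: str) -> bool:
    order = "abcdefghijklmnopqrstuvwxyz"
    if len(s) < 2:
        return False
    idx = [order.index(c) for c in s]
    return any(b - a > 1 for a, b in zip(idx, idx[1:]))


def _meta_for(groups: dict[str, int]):
    rows = ["insect_id,file,status,group"]
    ids = []
    for g, n in groups.items():
        for i in range(n):
            rows.append(f"{g}_{i},{g}_{i}.tsv,completed,{g}")
            ids.append(f"{g}_{i}")
    return read_metadata(io.StringIO("\n".join(rows) + "\n")), ids


class TestGroupCompare:
    def test_identical_groups_share_letter(self):
        rng = np.random.default_rng(18)
        meta, ids = _meta_for({"a": 10, "b": 10})
        table = pd.DataFrame({"p": rng.lognormal(1, 0.3, 20)}, index=ids)
        table.index.name = "insect_id"
        (cmp_,) = group_compare(table, meta, "group")
        assert cmp_.skipped is None
        letters = cmp_.summary["letter"]
        assert set(letters["a"]) & set(letters["b"])

    def test_strong_effect_gets_distinct_letters(self):
        rng = np.random.default_rng(19)
        meta, ids = _meta_for({"a": 12, "b": 12})
        vals = np.concatenate([rng.lognormal(0, 0.2, 12),
                               rng.lognormal(3, 0.2, 12)])
        table = pd.DataFrame({"p": vals}, index=ids)
        table.index.name = "insect_id"
        (cmp_,) = group_compare(table, meta, "group")
        letters = cmp_.summary["letter"]
        assert not (set(letters["a"]) & set(letters["b"]))

    def test_letters_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(20)
        k, n = 4, 9
        meta, ids = _meta_for({f"g{i}": n for i in range(k)})
        shifts = np.repeat([0.0, 0.5, 2.0, 2.2], n)
        vals = shifts + rng.normal(0, 0.4, k * n)
        sig1 = tukey_kramer({f"g{i}": vals[i * n:(i + 1) * n]
                             for i in range(k)}).to_numpy() < 0.05
        sig2 = tukey_kramer({f"g{i}": (3.5 * vals + 11)[i * n:(i + 1) * n]
                             for i in range(k)}).to_numpy() < 0.05
        labels = [f"g{i}" for i in range(k)]
        np.fill_diagonal(sig1, False)
        np.fill_diagonal(sig2, False)
        assert piepho_letters(labels, sig1) == piepho_letters(labels, sig2)

    def test_whole_group_missing_reports_skip(self):
        meta, ids = _meta_for({"a": 5, "b": 5})
        vals = [1.0, 2.0, 3.0, 2.5, 1.5] + [np.nan] * 5
        table = pd.DataFrame({"p": vals}, index=ids)
        table.index.name = "insect_id"
        (cmp_,) = group_compare(table, meta, "group")
        assert cmp_.skipped is not None and "b" in cmp_.skipped

    def test_unknown_factor_rejected(self):
        meta, ids = _meta_for({"a": 4, "b": 4})
        table = pd.DataFrame({"p": np.arange(8.0)}, index=ids)
        with pytest.raises(ValueError, match="factor"):
            group_compare(table, meta, "wire")


def test_familywise_error_rate_near_alpha():
    """k = 4 identical groups, repeated nulls: the share of runs whose
    letter display separates any pair should sit near the familywise
    alpha = 0.05."""
    rng = np.random.default_rng(99)
    k, n, reps = 4, 10, 400
    labels = [f"g{i}" for i in range(k)]
    hits = 0
    for _ in range(reps):
        groups = {lab: rng.normal(size=n) for lab in labels}
        sig = tukey_kramer(groups).to_numpy() < 0.05
        np.fill_diagonal(sig, False)
        letters = piepho_letters(labels, sig)
        if len(set(letters.values())) > 1:
            hits += 1
    assert 0.01 <= hits / reps <= 0.12
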