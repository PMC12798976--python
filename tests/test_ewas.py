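"""Per-probe screening statistics, region summaries and Venn overlaps."""

import numpy as np
import pandas as pd
import pytest

from methclock.ewas import (
    overlap_sets,
    region_proportions,
    screen_binary,
    screen_numeric,
)
from methclock.io import BetaMatrix, ProbeAnnotation
from conftest import make_beta


class TestScreenNumeric:
    def test_worked_example(self):
        beta = BetaMatrix(list("abcd"), ["cg1"],
                          np.array([[0.1], [0.2], [0.3], [0.5]]))
        res = screen_numeric(beta, [1, 2, 3, 4], p_threshold=0.05)
        row = res.table.loc["cg1"]
        assert row["r"] == pytest.approx(0.9827076, abs=1e-6)
        assert row["z"] == pytest.approx(7.5055, abs=1e-3)
        assert row["p"] == pytest.approx(0.01729, abs=1e-4)
        assert bool(row["significant"])

    def test_perfect_correlation_capped_not_infinite(self):
        trait = np.array([1.0, 2.0, 3.0, 4.0])
        beta = BetaMatrix(list("abcd"), ["cg1"], (trait[:, None] / 10))
        res = screen_numeric(beta, trait)
        row = res.table.loc["cg1"]
        assert row["r"] == pytest.approx(1.0)
        assert np.isfinite(row["z"]) and row["z"] > 1e5
        assert row["p"] < 1e-10

    def test_trait_reversal_antisymmetry(self, rng):
        beta = make_beta(rng.uniform(0, 1, size=(10, 20)))
        trait = rng.uniform(0, 16, 10)
        a = screen_numeric(beta, trait).table
        b = screen_numeric(beta, -trait).table
        np.testing.assert_allclose(a["r"], -b["r"], atol=1e-12)
        np.testing.assert_allclose(a["z"], -b["z"], atol=1e-9)
        np.testing.assert_allclose(a["p"], b["p"], atol=1e-12)

    def test_matches_bruteforce_formulas(self, rng):
        """Vectorized path agrees with per-probe textbook computation to 1e-10."""
        from oracles import pearson_t_pvalue

        beta = make_beta(rng.uniform(0, 1, size=(25, 100)))
        trait = rng.uniform(0, 16, 25)
        res = screen_numeric(beta, trait).table
        for j, probe in enumerate(beta.probe_ids):
            r, t, p = pearson_t_pvalue(beta.values[:, j], trait)
            assert res.loc[probe, "r"] == pytest.approx(r, abs=1e-10)
            assert res.loc[probe, "z"] == pytest.approx(t, abs=1e-10)
            assert res.loc[probe, "p"] == pytest.approx(p, abs=1e-10)

    def test_constant_probe_missing_stats(self):
        beta = make_beta(np.column_stack([np.full(6, 0.5),
                                          np.linspace(0.1, 0.6, 6)]))
        res = screen_numeric(beta, np.arange(6.0)).table
        assert np.isnan(res.iloc[0][["r", "z", "p"]].astype(float)).all()
        assert not res.iloc[0]["significant"]

    def test_constant_trait_all_missing(self):
        beta = make_beta(np.random.default_rng(0).uniform(0, 1, (5, 4)))
        res = screen_numeric(beta, np.full(5, 3.0)).table
        assert res["p"].isna().all()

    def test_pairwise_complete_counts(self):
        vals = np.linspace(0.1, 0.9, 9).reshape(9, 1).repeat(2, axis=1)
        vals[0, 0] = np.nan
        beta = make_beta(vals)
        res = screen_numeric(beta, np.arange(9.0)).table
        assert res["n_used"].tolist() == [8, 9]


class TestScreenBinary:
    def test_worked_pooled_example(self):
        beta = BetaMatrix(list("abcd"), ["cg1"],
                          np.array([[0.1], [0.2], [0.8], [0.9]]))
        res = screen_binary(beta, ["g1", "g1", "g2", "g2"], p_threshold=0.05)
        row = res.table.loc["cg1"]
        assert row["r"] == pytest.approx(0.7)
        assert row["z"] == pytest.approx(9.8995, abs=1e-4)
        assert row["p"] == pytest.approx(0.01005, abs=1e-5)

    def test_identical_groups_null(self):
        half = np.linspace(0.2, 0.8, 4).reshape(4, 1)
        beta = make_beta(np.vstack([half, half]))
        res = screen_binary(beta, ["a"] * 4 + ["b"] * 4).table
        assert res.loc[beta.probe_ids[0], "r"] == 0.0
        assert res.loc[beta.probe_ids[0], "z"] == 0.0
        assert res.loc[beta.probe_ids[0], "p"] == pytest.approx(1.0)

    def test_label_swap_antisymmetry(self, rng):
        beta = make_beta(rng.uniform(0, 1, size=(12, 30)))
        labels = ["f"] * 6 + ["m"] * 6
        swapped = ["m"] * 6 + ["f"] * 6
        a = screen_binary(beta, labels).table
        b = screen_binary(beta, swapped).table
        np.testing.assert_allclose(a["r"], -b["r"], atol=1e-12)
        np.testing.assert_allclose(a["z"], -b["z"], atol=1e-9)

    def test_welch_runs_with_variance_floor(self):
        vals = np.array([[0.5], [0.5], [0.6], [0.7]])  # group1 zero variance
        beta = make_beta(vals)
        res = screen_binary(beta, ["a", "a", "b", "b"], variance="welch").table
        assert np.isfinite(res.iloc[0]["z"])

    def test_power_monotone_in_slope(self):
        """Detection rate of planted age CpGs grows with the planted slope."""
        from methclock.simulate import SimConfig, generate_dataset
        from methclock.ewas import screen_numeric

        rates = []
        for slope in (0.01, 0.04, 0.12):
            cfg = SimConfig(n_samples=40, n_probes=600, n_age_cpgs=100,
                            n_sex_cpgs=0, n_disease_cpgs=0, noise_sd=0.15,
                            age_slope_range=(slope, slope),
                            tissue_weights=(1.0, 0, 0), seed=21)
            beta, sheet, _, truth = generate_dataset(cfg)
            res = screen_numeric(beta, sheet.data["age_years"].to_numpy(),
                                 p_threshold=1e-3)
            hits = set(res.significant_probes) & set(truth.probes_of("age"))
            rates.append(len(hits) / 100)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > rates[0]


class TestRegionProportions:
    def _annot(self, probes, regions):
        return ProbeAnnotation(pd.DataFrame({
            "probe_id": probes,
            "chrom": "chrA1",
            "pos": np.arange(1, len(probes) + 1),
            "gene": "G",
            "region": regions,
        }))

    def _result(self, probes, z, significant):
        from methclock.ewas import EwasResult

        table = pd.DataFrame({"r": z, "z": z, "p": 0.0001,
                              "significant": significant, "n_used": 10},
                             index=pd.Index(probes, name="probe_id"))
        return EwasResult(table, "numeric", 1e-3)

    def test_all_hyper_promoter(self):
        probes = [f"cg{i}" for i in range(4)]
        res = self._result(probes, [1.0] * 4, [True] * 4)
        annot = self._annot(probes, ["promoter"] * 4)
        out = region_proportions(res, annot)
        assert out.loc["promoter", "n_hyper"] == 4
        assert out.loc["promoter", "hyper_fraction"] == 1.0

    def test_mixed_fraction(self):
        probes = [f"cg{i}" for i in range(4)]
        res = self._result(probes, [1.0, 2.0, 0.5, -1.0], [True] * 4)
        out = region_proportions(res, self._annot(probes, ["exon"] * 4))
        assert out.loc["exon", "hyper_fraction"] == 0.75

    def test_empty_region_nan_fraction(self):
        probes = ["cg0", "cg1"]
        res = self._result(probes, [1.0, -1.0], [True, False])
        annot = self._annot(probes, ["exon", "intron"])
        out = region_proportions(res, annot)
        assert np.isnan(out.loc["intron", "hyper_fraction"])
        assert out.loc["intron", "n_background"] == 1

    def test_invariant_to_probe_order(self, rng):
        probes = [f"cg{i}" for i in range(20)]
        z = rng.normal(size=20)
        regions = rng.choice(["promoter", "exon", "intron"], 20)
        res = self._result(probes, z, [True] * 20)
        a = region_proportions(res, self._annot(probes, regions))
        perm = rng.permutation(20)
        res_p = self._result([probes[i] for i in perm], z[perm], [True] * 20)
        b = region_proportions(res_p, self._annot(probes, regions))
        pd.testing.assert_frame_equal(a, b)


class TestOverlapSets:
    def test_three_set_enumeration(self):
        out = overlap_sets({"s1": {"A", "B", "C"}, "s2": {"B", "C", "D"},
                            "s3": {"C"}})
        assert out.region_counts[("s1", "s2", "s3")] == 1
        assert out.region_counts[("s1", "s2")] == 1      # {B}
        assert out.region_counts[("s2",)] == 1           # {D}
        assert out.intersection["probe_id"].tolist() == ["C"]

    def test_disjoint_sets(self):
        out = overlap_sets({"a": {"X"}, "b": {"Y"}})
        assert out.region_counts[("a", "b")] == 0
        assert len(out.intersection) == 0

    def test_subset_relation(self):
        out = overlap_sets({"big": {"A", "B"}, "small": {"A"}})
        assert out.region_counts[("small",)] == 0
        assert out.region_counts[("big", "small")] == 1

    def test_direction_concordance_from_series(self):
        s1 = pd.Series([2.0, -1.0], index=["A", "B"])
        s2 = pd.Series([0.5, 1.0], index=["A", "B"])
        out = overlap_sets({"liver": s1, "blood": s2})
        conc = out.intersection.set_index("probe_id")["concordant"]
        assert bool(conc["A"]) is True
        assert bool(conc["B"]) is False

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            overlap_sets({"only": {"A"}})
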