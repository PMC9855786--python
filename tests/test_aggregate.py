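"""Aggregation formulas: TPM totals, per-diet means, shares, intervals."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tdgfquant as tq
from tdgfquant.aggregate import (
    METHOD_16S,
    METHOD_RNASEQ,
    NORM_DISTINGUISHED,
    NORM_WHOLE,
    per_sample_frame,
)


def _abundance_table(sample_id, tpm_by_contig):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tq.AbundanceTable(
            sample_id=sample_id,
            data=pd.DataFrame(
                {
                    "length": 500.0,
                    "eff_length": 351.0,
                    "est_counts": 1.0,
                    "tpm": pd.Series(tpm_by_contig, dtype=float),
                },
            ).rename_axis("target_id"),
        )


def _meta(diet_by_sample):
    return tq.SampleMetadata(
        data=pd.DataFrame(
            {
                "subject_id": list(diet_by_sample),
                "diet": list(diet_by_sample.values()),
            },
            index=pd.Index(list(diet_by_sample), name="sample_id"),
        )
    )


class TestTdgfTpmPerSample:
    def test_simple_sum(self):
        table = _abundance_table("s1", {"c1": 10.0, "c2": 20.0, "c3": 5.0})
        totals = tq.tdgf_tpm_per_sample(table, {"but1": {"c1", "c2"}})
        assert totals == {"but1": 30.0}

    def test_empty_retained_set(self):
        table = _abundance_table("s1", {"c1": 10.0})
        assert tq.tdgf_tpm_per_sample(table, {"but1": set()}) == {"but1": 0.0}

    def test_missing_contig_counts_zero_with_warning(self):
        table = _abundance_table("s1", {"c1": 10.0})
        with pytest.warns(UserWarning, match="absent"):
            totals = tq.tdgf_tpm_per_sample(table, {"but1": {"c1", "ghost"}})
        assert totals == {"but1": 10.0}

    def test_matches_bruteforce_on_seeded_table(self):
        rng = np.random.default_rng(9)
        contigs = [f"c{i:02d}" for i in range(50)]
        tpm = dict(zip(contigs, rng.random(50) * 1e4))
        table = _abundance_table("s1", tpm)
        retained = {"t": set(rng.choice(contigs, size=17, replace=False))}
        totals = tq.tdgf_tpm_per_sample(table, retained)
        expected = 0.0
        for c in sorted(retained["t"]):
            expected += tpm[c]
        assert totals["t"] == expected


class TestWholeCommunityMeans:
    def test_single_sample_identity(self, catalog):
        tpm = pd.DataFrame(
            {"acet1": [30.0], "but1": [0.0], "muc2": [0.0], "sulfat1": [0.0]},
            index=["s1"],
        )
        res = tq.group_abundance_rnaseq(tpm, _meta({"s1": "F"}), catalog)
        by_group = {r.group_id: r for r in res}
        assert by_group["acetogens"].mean == 30.0
        assert by_group["acetogens"].n == 1

    def test_mean_over_three_mice(self, catalog):
        tpm = pd.DataFrame(
            {
                "acet1": [30.0, 60.0, 90.0],
                "but1": [0.0] * 3,
                "muc2": [0.0] * 3,
                "sulfat1": [0.0] * 3,
            },
            index=["s1", "s2", "s3"],
        )
        meta = _meta({"s1": "F", "s2": "F", "s3": "F"})
        res = tq.group_abundance_rnaseq(tpm, meta, catalog)
        acet = next(r for r in res if r.group_id == "acetogens")
        assert acet.mean == 60.0
        assert acet.values == (30.0, 60.0, 90.0)

    def test_16s_sums_member_taxa(self, catalog):
        df = pd.DataFrame(
            {"m1": [0.1, 0.2]},
            index=["Collinsella aerofaciens", "Marvinbryantia formatexigens"],
        )
        table = tq.TaxonAbundanceTable(data=df)
        res = tq.group_abundance_16s(table, _meta({"m1": "F"}), catalog)
        acet = next(r for r in res if r.group_id == "acetogens")
        assert acet.mean == pytest.approx(0.30000000000000004)

    def test_taxon_in_two_groups_counts_twice(self, catalog, tmp_path):
        # craft a catalog where one taxon is both an acetogen and a
        # butyrate producer
        config = tmp_path / "cat.yaml"
        config.write_text(
            """
groups:
  - {group_id: acetogens, member_taxa: [Shared taxon]}
  - {group_id: butyrate_producers, member_taxa: [Shared taxon, Other taxon]}
tdgfs:
  - {tdgf_id: acet1, group_id: acetogens}
  - {tdgf_id: but1, group_id: butyrate_producers}
"""
        )
        fasta = tmp_path / "p.fasta"
        fasta.write_text(">acet1\nMKWVLAAQERTY\n>but1\nMHWNDEQRSTVL\n")
        cat = tq.load_catalog(config, fasta)
        table = tq.TaxonAbundanceTable(
            data=pd.DataFrame({"m1": [0.4, 0.1]},
                              index=["Shared taxon", "Other taxon"])
        )
        values = tq.group_values_16s(table, cat)
        assert values.loc["m1", "acetogens"] == 0.4
        assert values.loc["m1", "butyrate_producers"] == 0.5

    def test_randomized_fixture_matches_bruteforce(self, catalog):
        rng = np.random.default_rng(21)
        samples = [f"s{i}" for i in range(9)]
        diets = dict(zip(samples, ["F"] * 3 + ["R"] * 3 + ["FR"] * 3))
        tpm = pd.DataFrame(
            rng.random((9, 4)) * 1e5,
            index=samples,
            columns=["acet1", "but1", "muc2", "sulfat1"],
        )
        res = tq.group_abundance_rnaseq(tpm, _meta(diets), catalog)
        tdgf_of = {g: catalog.single_tdgf(g).id for g in catalog.groups}
        for r in res:
            expected_vals = [
                float(tpm.loc[s, tdgf_of[r.group_id]])
                for s in sorted(s for s, d in diets.items() if d == r.diet)
            ]
            total = 0.0
            for v in expected_vals:
                total += v
            assert r.values == tuple(expected_vals)
            assert r.mean == total / len(expected_vals)


class TestDistinguishedNormalization:
    def test_single_sample_ratio(self, catalog):
        values = pd.DataFrame(
            {
                "acetogens": [30.0],
                "butyrate_producers": [70.0],
                "mucin_degraders": [0.0],
                "sulfate_reducers": [0.0],
            },
            index=["s1"],
        )
        res = tq.normalize_to_distinguished(values, _meta({"s1": "F"}),
                                            METHOD_RNASEQ)
        by_group = {r.group_id: r.mean for r in res}
        assert by_group == {
            "acetogens": 0.3,
            "butyrate_producers": 0.7,
            "mucin_degraders": 0.0,
            "sulfate_reducers": 0.0,
        }

    def test_equal_groups_give_quarter_shares(self, catalog):
        values = pd.DataFrame(
            {g: [5.0] for g in catalog.groups}, index=["s1"]
        )
        res = tq.normalize_to_distinguished(values, _meta({"s1": "R"}),
                                            METHOD_RNASEQ)
        assert all(r.mean == 0.25 for r in res)

    def test_all_zero_sample_names_sample(self, catalog):
        values = pd.DataFrame({g: [0.0] for g in catalog.groups}, index=["sZ"])
        with pytest.raises(ValueError, match="sZ"):
            tq.normalize_to_distinguished(values, _meta({"sZ": "F"}),
                                          METHOD_RNASEQ)

    def test_seeded_fixture_shares_sum_to_one_and_match_bruteforce(self):
        rng = np.random.default_rng(33)
        samples = [f"s{i}" for i in range(6)]
        diets = dict(zip(samples, ["F", "F", "F", "R", "R", "R"]))
        groups = ["g1", "g2", "g3", "g4"]
        values = pd.DataFrame(rng.random((6, 4)) * 100, index=samples,
                              columns=groups)
        res = tq.normalize_to_distinguished(values, _meta(diets), "rnaseq_tdgf")
        # per-sample shares sum to 1
        per_sample = per_sample_frame(res).pivot(
            index="sample_id", columns="group_id", values="value"
        )
        assert np.allclose(per_sample.sum(axis=1), 1.0, atol=1e-12)
        # per-diet mean shares sum to 1 and match naive recomputation
        for diet in ("F", "R"):
            mean_sum = sum(r.mean for r in res if r.diet == diet)
            assert abs(mean_sum - 1.0) < 1e-12
        for r in res:
            diet_samples = sorted(s for s, d in diets.items() if d == r.diet)
            shares = []
            for s in diet_samples:
                denom = 0.0
                for g in sorted(groups):
                    denom += float(values.loc[s, g])
                shares.append(float(values.loc[s, r.group_id]) / denom)
            total = 0.0
            for v in shares:
                total += v
            assert r.values == tuple(shares)
            assert r.mean == total / len(shares)

    def test_pooled_ratio_variant(self):
        values = pd.DataFrame(
            {"g1": [10.0, 30.0], "g2": [90.0, 70.0]}, index=["s1", "s2"]
        )
        meta = _meta({"s1": "F", "s2": "F"})
        res = tq.normalize_to_distinguished(values, meta, "rnaseq_tdgf",
                                            pooled_ratio=True)
        by_group = {r.group_id: r.mean for r in res}
        assert by_group["g1"] == pytest.approx(40.0 / 200.0)
        assert by_group["g2"] == pytest.approx(160.0 / 200.0)

    def test_scale_equivariance(self, catalog):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(
            rng.random((3, 4)) + 0.1,
            index=["s1", "s2", "s3"],
            columns=list(catalog.groups),
        )
        meta = _meta({"s1": "F", "s2": "F", "s3": "F"})
        res1 = tq.normalize_to_distinguished(values, meta, METHOD_RNASEQ)
        scaled = values.copy()
        scaled.loc["s2"] *= 37.5  # per-sample rescaling cancels in shares
        res2 = tq.normalize_to_distinguished(scaled, meta, METHOD_RNASEQ)
        for r1, r2 in zip(res1, res2):
            assert r1.values == pytest.approx(r2.values, rel=1e-12)

    def test_permutation_invariance(self, catalog):
        rng = np.random.default_rng(5)
        values = pd.DataFrame(
            rng.random((4, 4)) + 0.1,
            index=["s1", "s2", "s3", "s4"],
            columns=list(catalog.groups),
        )
        meta = _meta({"s1": "F", "s2": "F", "s3": "R", "s4": "R"})
        res1 = tq.normalize_to_distinguished(values, meta, METHOD_RNASEQ)
        shuffled = values.iloc[::-1, ::-1]
        res2 = tq.normalize_to_distinguished(shuffled, meta, METHOD_RNASEQ)
        assert {(r.group_id, r.diet, r.values) for r in res1} == {
            (r.group_id, r.diet, r.values) for r in res2
        }


class TestConfidenceInterval:
    def test_zero_variance_degenerate(self):
        assert tq.confidence_interval([5.0, 5.0, 5.0]) == (5.0, 5.0)

    def test_textbook_t_interval(self):
        lo, hi = tq.confidence_interval([1.0, 2.0, 3.0])
        half = stats.t.ppf(0.975, df=2) / np.sqrt(3)
        assert lo == pytest.approx(2 - half, abs=1e-12)
        assert hi == pytest.approx(2 + half, abs=1e-12)
        assert hi - 2 == pytest.approx(2.484, abs=5e-4)

    def test_single_value_warns_and_degenerates(self):
        with pytest.warns(UserWarning, match="k=1"):
            assert tq.confidence_interval([7.0]) == (7.0, 7.0)

    def test_bootstrap_seeded_reproducible(self):
        vals = [1.0, 4.0, 2.0, 8.0]
        a = tq.confidence_interval(vals, method="bootstrap", seed=3)
        b = tq.confidence_interval(vals, method="bootstrap", seed=3)
        assert a == b
        lo, hi = a
        assert lo <= np.mean(vals) <= hi
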