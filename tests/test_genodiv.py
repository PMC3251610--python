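"""Genotype-matrix QC and the diversity statistics."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from snpforge import genodiv, simgen
from snpforge.errors import DomainError
from snpforge.genodiv import (
    GenotypeMatrix,
    evanno_delta_k,
    filter_call_rate,
    filter_maf,
    gene_diversity,
    minor_allele_freq,
    nei_distance,
    pco,
    replicate_concordance,
    sample_heterozygosity,
    transferability_counts,
)


def matrix_from(calls_dict, index, species=None, group=None, replicate_of=None):
    n = len(index)
    calls = pd.DataFrame(calls_dict, index=index)
    samples = pd.DataFrame(
        {
            "species": species or ["H. annuus"] * n,
            "group": group or ["other"] * n,
            "replicate_of": replicate_of or [None] * n,
        },
        index=index,
    )
    return GenotypeMatrix(calls, samples)


class TestCallRateFilter:
    def _matrix(self):
        full = ["AA"] * 10
        seven = ["AA"] * 7 + [np.nan] * 3
        return matrix_from(
            {"full": full, "seven": seven}, [f"s{i}" for i in range(10)]
        )

    def test_complete_locus_retained_and_70pct_dropped(self):
        out = filter_call_rate(self._matrix(), threshold=0.8)
        assert out.loci == ["full"]

    def test_threshold_one_keeps_only_complete_loci(self):
        out = filter_call_rate(self._matrix(), threshold=1.0)
        assert out.loci == ["full"]
        out2 = filter_call_rate(self._matrix(), threshold=0.7)
        assert out2.loci == ["full", "seven"]

    def test_empty_subset_rejected(self):
        with pytest.raises(DomainError):
            filter_call_rate(self._matrix(), sample_subset=[])


class TestReplicateConcordance:
    def test_identical_replicates_are_fully_concordant(self):
        calls = {f"L{i}": ["AA", "AA"] for i in range(20)}
        m = matrix_from(calls, ["s1", "s1r"], replicate_of=[None, "s1"])
        ((_, res),) = replicate_concordance(m).items()
        assert (res.discordant_calls, res.missing_mismatch) == (0, 0)
        assert res.both_called == 20

    def test_single_missing_call_counts_as_missing_mismatch_only(self):
        calls = {"L1": ["AA", np.nan], "L2": ["AB", "AB"]}
        m = matrix_from(calls, ["s1", "s1r"], replicate_of=[None, "s1"])
        ((_, res),) = replicate_concordance(m).items()
        assert (res.discordant_calls, res.missing_mismatch) == (0, 1)

    def test_conflicting_calls_are_discordant(self):
        calls = {f"L{i}": ["AA", "AA"] for i in range(98)}
        calls["X1"] = ["AA", "BB"]
        calls["X2"] = ["AA", "BB"]
        m = matrix_from(calls, ["s1", "s1r"], replicate_of=[None, "s1"])
        ((_, res),) = replicate_concordance(m).items()
        assert res.discordant_calls == 2

    def test_no_replicates_gives_empty_result(self):
        m = matrix_from({"L1": ["AA", "BB"]}, ["a", "b"])
        assert replicate_concordance(m) == {}


class TestTransferability:
    def test_complete_matrix_counts_all_loci_everywhere(self):
        m = matrix_from(
            {"L1": ["AA"] * 4, "L2": ["BB"] * 4},
            ["a", "b", "c", "d"],
            species=["sp1", "sp1", "sp2", "sp3"],
        )
        counts = transferability_counts(m)
        assert all(v == 2 for v in counts.values())
        assert len(counts) == 7  # all non-empty subsets of 3 species

    def test_species_dropout_excludes_from_its_sets(self):
        m = matrix_from(
            {"L1": ["AA", "AA", np.nan, "AA"], "L2": ["AA"] * 4},
            ["a", "b", "c", "d"],
            species=["sp1", "sp1", "sp2", "sp3"],
        )
        counts = transferability_counts(m)
        assert counts[frozenset({"sp2"})] == 1
        assert counts[frozenset({"sp1", "sp2"})] == 1
        assert counts[frozenset({"sp1"})] == 2
        assert counts[frozenset({"sp1", "sp3"})] == 2

    def test_unknown_species_rejected(self):
        m = matrix_from(
            {"L1": ["AA", "AA"]}, ["a", "b"], species=["sp1", "sp2"]
        )
        with pytest.raises(DomainError):
            transferability_counts(m, species_sets=[frozenset({"nope"})])

    def test_matches_brute_force_on_simulated_dropout(self):
        rng = np.random.default_rng(12)
        n, loci = 12, [f"L{i}" for i in range(40)]
        species = ["sp1"] * 6 + ["sp2"] * 4 + ["sp3"] * 2
        calls = pd.DataFrame(
            rng.choice(["AA", "AB", "BB", None], p=[0.4, 0.2, 0.2, 0.2], size=(n, 40)),
            index=[f"s{i}" for i in range(n)],
            columns=loci,
        )
        m = matrix_from(calls, list(calls.index), species=species)
        counts = transferability_counts(m, threshold=0.8)
        for sset, count in counts.items():
            expected = 0
            for locus in loci:
                ok = True
                for sp in sset:
                    ids = [s for s, spp in zip(calls.index, species) if spp == sp]
                    vals = calls.loc[ids, locus]
                    if vals.notna().mean() < 0.8 - 1e-12:
                        ok = False
                assert isinstance(ok, bool)
                expected += ok
            assert count == expected


class TestAlleleFrequencies:
    def test_balanced_homozygotes_have_maximal_maf(self):
        assert minor_allele_freq(pd.Series(["AA"] * 5 + ["BB"] * 5)) == 0.5

    def test_rare_allele_below_ten_percent_dropped(self):
        calls = pd.Series(["AA"] * 9 + ["AB"])
        assert minor_allele_freq(calls) == pytest.approx(0.05)
        m = matrix_from(
            {"rare": ["AA"] * 9 + ["AB"], "mono": ["AA"] * 10,
             "ok": ["AA"] * 5 + ["BB"] * 5},
            [f"s{i}" for i in range(10)],
        )
        assert filter_maf(m, 0.10).loci == ["ok"]

    def test_all_missing_locus_dropped_with_warning(self):
        m = matrix_from(
            {"empty": [np.nan] * 4, "ok": ["AA", "AB", "BB", "AB"]},
            list("abcd"),
        )
        with pytest.warns(UserWarning):
            out = filter_maf(m, 0.0)
        assert out.loci == ["ok"]

    def test_gene_diversity_closed_forms(self):
        assert gene_diversity(pd.Series(["AA"] * 5 + ["BB"] * 5)) == pytest.approx(0.5)
        assert gene_diversity(pd.Series(["AA"] * 7)) == 0.0
        assert gene_diversity(pd.Series(["AA"] * 8 + ["AB"] * 2)) == pytest.approx(
            0.18, abs=1e-12
        )

    @given(st.lists(st.sampled_from(["AA", "AB", "BB"]), min_size=1, max_size=30))
    def test_gene_diversity_equals_2pq(self, calls):
        series = pd.Series(calls)
        dosage = series.map({"AA": 1.0, "AB": 0.5, "BB": 0.0})
        p = dosage.mean()
        he = gene_diversity(series)
        assert he == pytest.approx(2 * p * (1 - p), abs=1e-12)
        assert 0.0 <= he <= 0.5 + 1e-12

    def test_maf_and_call_rate_filters_commute_without_missing_data(self):
        rng = np.random.default_rng(3)
        calls = pd.DataFrame(
            rng.choice(["AA", "AB", "BB"], size=(12, 25)),
            index=[f"s{i}" for i in range(12)],
            columns=[f"L{i}" for i in range(25)],
        )
        m = matrix_from(calls, list(calls.index))
        a = filter_maf(filter_call_rate(m, 0.8), 0.1)
        b = filter_call_rate(filter_maf(m, 0.1), 0.8)
        assert a.loci == b.loci


class TestSampleHeterozygosity:
    def test_simple_fractions(self):
        m = matrix_from(
            {f"L{i}": ["AB", "AB" if i < 3 else "AA"] for i in range(10)},
            ["all_het", "some_het"],
        )
        het, _ = sample_heterozygosity(m)
        assert het["all_het"] == 1.0
        assert het["some_het"] == pytest.approx(0.3)

    def test_group_means_recover_simulated_inbreeding_contrast(self):
        spec = simgen.MatrixSpec(
            n_loci=400,
            groups=(
                simgen.GroupSpec("HA_oil", "H. annuus", 12, 0.8),
                simgen.GroupSpec("OPV_landrace", "H. annuus", 12, 0.0),
            ),
            missing_rate=0.0,
            n_replicate_pairs=0,
        )
        cfg = simgen.SimulationConfig(seed=6, matrix=spec)
        m, freqs = simgen.simulate_genotype_matrix(cfg)
        _, groups = sample_heterozygosity(m)
        groups = groups.set_index("group")
        expected_het = 2 * (freqs["p_allele_a"] * (1 - freqs["p_allele_a"])).mean()
        for grp, f in [("HA_oil", 0.8), ("OPV_landrace", 0.0)]:
            mean, se = groups.loc[grp, "mean"], groups.loc[grp, "se"]
            assert abs(mean - expected_het * (1 - f)) <= 2 * se + 0.01

    def test_singleton_group_has_no_se(self):
        m = matrix_from(
            {"L1": ["AB", "AA", "AB"]},
            ["a", "b", "c"],
            group=["wild", "HA_oil", "HA_oil"],
        )
        _, groups = sample_heterozygosity(m)
        assert math.isnan(groups.set_index("group").loc["wild", "se"])


class TestNeiDistance:
    def test_identical_samples_are_at_distance_zero(self):
        m = matrix_from(
            {"L1": ["AA", "AA"], "L2": ["AB", "AB"], "L3": ["BB", "BB"]},
            ["x", "y"],
        )
        d = nei_distance(m)
        assert d.loc["x", "y"] == 0.0

    def test_matches_hand_computed_three_sample_fixture(self):
        m = matrix_from(
            {"L1": ["AA", "AB", "BB"], "L2": ["AA", "AA", "AB"],
             "L3": ["AB", "BB", "BB"], "L4": ["BB", "AA", "AA"]},
            ["x", "y", "z"],
        )
        d = nei_distance(m)
        freqs = {"x": [1, 1, 0.5, 0], "y": [0.5, 1, 0, 1], "z": [0, 0.5, 0, 1]}

        def hand(a, b):
            pa, pb = np.array(freqs[a]), np.array(freqs[b])
            jx = np.mean(pa**2 + (1 - pa) ** 2)
            jy = np.mean(pb**2 + (1 - pb) ** 2)
            jxy = np.mean(pa * pb + (1 - pa) * (1 - pb))
            return -math.log(jxy / math.sqrt(jx * jy))

        for a, b in [("x", "y"), ("x", "z"), ("y", "z")]:
            assert d.loc[a, b] == pytest.approx(hand(a, b), abs=1e-12)
            assert d.loc[b, a] == d.loc[a, b]
        assert (np.diag(d.values) == 0).all()

    def test_disjoint_alleles_get_finite_sentinel_with_warning(self):
        m = matrix_from(
            {"L1": ["AA", "BB", "AA"], "L2": ["AA", "BB", "AB"]},
            ["x", "y", "z"],
        )
        with pytest.warns(UserWarning, match="sentinel"):
            d = nei_distance(m)
        finite_max = d.loc["x", "z"], d.loc["y", "z"]
        assert d.loc["x", "y"] == pytest.approx(max(finite_max) + 1.0)

    def test_loci_missing_in_either_sample_are_excluded(self):
        m = matrix_from(
            {"L1": ["AA", "AA"], "L2": ["AB", np.nan]}, ["x", "y"]
        )
        assert nei_distance(m).loc["x", "y"] == 0.0


class TestPco:
    def test_collinear_points_load_on_one_axis(self):
        pts = np.array([0.0, 1.0, 3.0, 7.0])
        d = pd.DataFrame(
            np.abs(pts[:, None] - pts[None, :]), index=list("abcd"),
            columns=list("abcd"),
        )
        res = pco(d)
        assert res.percent_variance[0] == pytest.approx(100.0)
        axis = res.coordinates.iloc[:, 0].to_numpy()
        assert np.allclose(np.abs(axis[1:] - axis[0]), pts[1:], atol=1e-8)

    def test_identical_samples_share_coordinates(self):
        d = pd.DataFrame(
            [[0, 0, 2.0], [0, 0, 2.0], [2.0, 2.0, 0]],
            index=list("abc"), columns=list("abc"),
        )
        res = pco(d)
        assert np.allclose(
            res.coordinates.loc["a"], res.coordinates.loc["b"], atol=1e-10
        )

    def test_euclidean_distances_roundtrip(self):
        rng = np.random.default_rng(19)
        pts = rng.normal(size=(12, 2))
        d = pd.DataFrame(np.linalg.norm(pts[:, None] - pts[None], axis=2))
        res = pco(d)
        coords = res.coordinates.to_numpy()
        rec = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        assert np.abs(rec - d.to_numpy()).max() < 1e-8

    def test_asymmetry_rejected(self):
        d = pd.DataFrame([[0, 1.0], [2.0, 0]])
        with pytest.raises(DomainError):
            pco(d)


class TestEvannoDeltaK:
    def test_linear_means_have_zero_second_difference(self):
        loglik = {k: [-10.0 * k, -10.0 * k - 1] for k in range(1, 5)}
        deltas = evanno_delta_k(loglik)
        for value in deltas.values():
            assert value == pytest.approx(0.0, abs=1e-9)

    def test_direct_formula(self):
        loglik = {
            1: [-99.0, -100.0, -101.0],
            2: [-52.0, -50.0, -48.0],  # mean -50, sd 2
            3: [-44.0, -45.0, -46.0],
        }
        deltas = evanno_delta_k(loglik)
        assert deltas[2] == pytest.approx(22.5)

    def test_too_few_k_values_rejected(self):
        with pytest.raises(DomainError):
            evanno_delta_k({1: [-1.0, -2.0], 2: [-1.0, -2.0]})

    def test_zero_run_sd_omits_that_k(self):
        loglik = {1: [-100.0, -99.0], 2: [-50.0, -50.0], 3: [-45.0, -44.0]}
        assert evanno_delta_k(loglik) == {}


class TestParameterRecovery:
    def test_mean_he_matches_generating_expectation(self):
        """Outbred panel, no missingness: sample expected heterozygosity
        should match 2pq scaled by the finite-sample factor (1 - 1/2N)
        within 2 Monte-Carlo SE."""
        spec = simgen.MatrixSpec(
            n_loci=500,
            groups=(simgen.GroupSpec("OPV_landrace", "H. annuus", 40, 0.0),),
            missing_rate=0.0,
            n_replicate_pairs=0,
        )
        cfg = simgen.SimulationConfig(seed=9, matrix=spec)
        m, freqs = simgen.simulate_genotype_matrix(cfg)
        he = np.array([gene_diversity(m.calls[l]) for l in m.loci])
        n = len(m.sample_ids)
        expected = (
            2 * freqs["p_allele_a"] * (1 - freqs["p_allele_a"])
        ).to_numpy() * (1 - 1 / (2 * n))
        resid = he - expected
        se = resid.std(ddof=1) / math.sqrt(len(resid))
        assert abs(resid.mean()) <= 2 * se


class TestRoundTrip:
    def test_matrix_tsv_roundtrip(self, tmp_path, sim_matrix):
        m, _ = sim_matrix
        path = tmp_path / "calls.tsv"
        genodiv.write_matrix_tsv(m, path)
        again = genodiv.read_matrix_tsv(path)
        assert again.calls.equals(m.calls)
        pd.testing.assert_frame_equal(
            again.samples.fillna("NA"), m.samples.fillna("NA"),
            check_dtype=False, check_names=False,
        )
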