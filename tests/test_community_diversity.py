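import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from dungbef import community_diversity as cd
from dungbef.data_model import TRAIT_COLUMNS


def _trait_frame(rows):
    cols = ["species_id", "individual_id", *TRAIT_COLUMNS, "biomass"]
    return pd.DataFrame(rows, columns=cols)


def _random_profiles(rng, n_species):
    cols = list(TRAIT_COLUMNS) + ["biomass"]
    data = rng.uniform(0.5, 20.0, size=(n_species, len(cols)))
    idx = [f"sp{i}" for i in range(n_species)]
    df = pd.DataFrame(data, columns=cols, index=idx)
    df["body_length"] = df[["head_length", "pronotum_length", "elytra_length"]].sum(axis=1)
    return df


class TestSpeciesProfiles:
    def test_single_individual_profile_is_that_individual(self):
        row = ["spA", "i1"] + list(range(1, 10)) + [0.5]
        traits = _trait_frame([row])
        profile = cd.species_trait_profile(traits, "spA")
        assert profile["head_length"] == 1
        assert profile["biomass"] == 0.5
        assert profile["body_length"] == 1 + 3 + 6   # head + pronotum + elytra

    def test_two_individual_means(self):
        rows = [["spA", "i1", 4, 2, 3, 3, 2, 8, 2, 1, 3, 0.2],
                ["spA", "i2", 6, 2, 3, 3, 2, 8, 2, 1, 3, 0.4]]
        profile = cd.species_trait_profile(_trait_frame(rows), "spA")
        assert profile["head_length"] == pytest.approx(5.0)
        assert profile["biomass"] == pytest.approx(0.3)

    def test_profiles_match_brute_force_column_means(self, rng):
        rows = []
        for i in range(10):
            rows.append(["spA", f"i{i}"] + list(rng.uniform(1, 10, 9))
                        + [rng.uniform(0.05, 1.0)])
        traits = _trait_frame(rows)
        profile = cd.species_trait_profile(traits, "spA")
        for j, col in enumerate(TRAIT_COLUMNS):
            expected = np.mean([r[2 + j] for r in rows])
            assert profile[col] == pytest.approx(expected, rel=1e-12)
        # vectorized table agrees with the per-species path
        table = cd.species_profiles(traits)
        assert np.allclose(table.loc["spA", profile.index], profile.to_numpy())

    def test_unknown_species_raises(self):
        with pytest.raises(KeyError):
            cd.species_trait_profile(_trait_frame([]), "ghost")


class TestFunctionalGroups:
    @pytest.mark.parametrize("guild, size, expected", [
        ("paracoprid", 19.0, "large_paracoprid"),
        ("endocoprid", 10.0, "medium_endocoprid"),   # boundary -> medium
        ("endocoprid", 18.0, "medium_endocoprid"),   # boundary -> medium
        ("telecoprid", 9.9, "small_telecoprid"),
        ("kleptocoprid", 18.01, "large_kleptocoprid"),
    ])
    def test_size_thresholds(self, guild, size, expected):
        assert cd.assign_functional_group(guild, size) == expected

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            cd.assign_functional_group("paracoprid", 0.0)

    def test_twelve_functional_groups(self):
        assert len(cd.FUNCTIONAL_GROUPS) == 12


class TestTraitDistances:
    def test_identical_profiles_have_zero_distance(self, rng):
        profiles = _random_profiles(rng, 3)
        profiles.iloc[1] = profiles.iloc[0]
        D = cd.trait_distance_matrix(profiles)
        assert D.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_metric_axioms(self, rng):
        D = cd.trait_distance_matrix(_random_profiles(rng, 6)).to_numpy()
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert (D >= 0).all()

    def test_matches_brute_force_standardized_euclidean(self, rng):
        profiles = _random_profiles(rng, 4)
        D = cd.trait_distance_matrix(profiles)
        cols = list(TRAIT_COLUMNS) + ["biomass"]
        X = profiles[cols].to_numpy().copy()
        X[:, -1] = np.log(X[:, -1])
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        for i, j in itertools.combinations(range(4), 2):
            expected = np.sqrt(((Z[i] - Z[j]) ** 2).sum())
            assert D.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_affine_rescaling_of_a_trait_is_absorbed_by_standardization(self, rng):
        profiles = _random_profiles(rng, 5)
        D1 = cd.trait_distance_matrix(profiles)
        rescaled = profiles.copy()
        rescaled["head_width"] = 3.7 * rescaled["head_width"] + 11.0
        D2 = cd.trait_distance_matrix(rescaled)
        assert np.allclose(D1.to_numpy(), D2.to_numpy(), atol=1e-10)

    def test_zero_variance_trait_dropped_with_warning(self, rng):
        profiles = _random_profiles(rng, 4)
        profiles["elytra_length"] = 5.0
        with pytest.warns(UserWarning, match="elytra_length"):
            cd.trait_distance_matrix(profiles)


class TestMeanPairwiseDistance:
    def test_single_species_is_zero(self, rng):
        D = cd.trait_distance_matrix(_random_profiles(rng, 3))
        assert cd.mean_pairwise_distance(D, ["sp0"]) == 0.0

    def test_two_species_equals_their_distance(self, rng):
        D = cd.trait_distance_matrix(_random_profiles(rng, 3))
        assert cd.mean_pairwise_distance(D, ["sp0", "sp2"]) == pytest.approx(
            D.loc["sp0", "sp2"])

    def test_four_species_brute_force(self, rng):
        D = cd.trait_distance_matrix(_random_profiles(rng, 6))
        present = ["sp0", "sp2", "sp3", "sp5"]
        pairs = [D.loc[a, b] for a, b in itertools.combinations(present, 2)]
        assert len(pairs) == 6
        assert cd.mean_pairwise_distance(D, present) == pytest.approx(
            np.mean(pairs), abs=1e-12)

    def test_unknown_species_raises(self, rng):
        D = cd.trait_distance_matrix(_random_profiles(rng, 3))
        with pytest.raises(KeyError):
            cd.mean_pairwise_distance(D, ["sp0", "ghost"])

    def test_relabeling_invariance(self, rng):
        """FDis does not depend on species names."""
        profiles = _random_profiles(rng, 5)
        D1 = cd.trait_distance_matrix(profiles)
        v1 = cd.mean_pairwise_distance(D1, list(profiles.index))
        renamed = profiles.rename(index={f"sp{i}": f"taxon{i}" for i in range(5)})
        D2 = cd.trait_distance_matrix(renamed)
        v2 = cd.mean_pairwise_distance(D2, list(renamed.index))
        assert v1 == pytest.approx(v2, abs=1e-12)


class TestBehaviorTree:
    def test_tree_has_twelve_functional_group_tips(self):
        tree = cd.build_behavior_tree()
        labels = {t.label for t in tree.taxon_namespace}
        assert labels == set(cd.FUNCTIONAL_GROUPS)
        assert len(labels) == 12

    def test_newick_export_parses_back(self):
        nwk = cd.behavior_tree_newick()
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(tree.leaf_nodes()) == 12

    def test_guild_split_dominates_size_split(self):
        coph = cd.cophenetic_matrix(cd.build_behavior_tree())
        # same superclade (para/tele) closer than across the root split
        assert coph.loc["small_paracoprid", "small_telecoprid"] \
            < coph.loc["small_paracoprid", "small_endocoprid"]
        # size split nested within guild: same guild closest of all
        assert coph.loc["large_paracoprid", "small_paracoprid"] \
            < coph.loc["large_paracoprid", "large_telecoprid"]

    def test_unit_branch_lengths_make_tree_ultrametric(self):
        tree = cd.build_behavior_tree()
        depths = {leaf.distance_from_root() for leaf in tree.leaf_nodes()}
        assert depths == {3.0}

    def test_fdis_behavior_single_group_is_zero(self):
        tree = cd.build_behavior_tree()
        groups = pd.Series({"a": "small_paracoprid", "b": "small_paracoprid"})
        assert cd.fdis_behavior(tree, groups) == 0.0

    def test_fdis_behavior_pair_equals_cophenetic_distance(self):
        tree = cd.build_behavior_tree()
        coph = cd.cophenetic_matrix(tree)
        groups = pd.Series({"a": "small_paracoprid", "b": "small_telecoprid"})
        assert cd.fdis_behavior(tree, groups) == pytest.approx(
            coph.loc["small_paracoprid", "small_telecoprid"])

    def test_fdis_behavior_five_species_brute_force(self):
        tree = cd.build_behavior_tree()
        coph = cd.cophenetic_matrix(tree)
        groups = pd.Series({
            "a": "small_paracoprid", "b": "large_paracoprid",
            "c": "small_telecoprid", "d": "medium_endocoprid",
            "e": "small_paracoprid"})
        expected = np.mean([coph.loc[g1, g2] for g1, g2 in
                            itertools.combinations(groups.to_numpy(), 2)])
        assert cd.fdis_behavior(tree, groups) == pytest.approx(expected, abs=1e-12)
        assert cd.fdis_behavior(tree, groups) <= coph.to_numpy().max()

    def test_unmapped_functional_group_raises(self):
        tree = cd.build_behavior_tree()
        with pytest.raises(KeyError):
            cd.fdis_behavior(tree, pd.Series({"a": "giant_paracoprid",
                                              "b": "small_paracoprid"}))


class TestCommunityMetrics:
    def test_equal_abundances_give_even_community(self):
        assert cd._shannon_evenness(np.array([5, 5, 5])) == pytest.approx(1.0)

    def test_shannon_evenness_brute_force(self):
        a = np.array([1, 1, 8])
        p = a / a.sum()
        h = -(p * np.log(p)).sum()
        assert cd._shannon_evenness(a) == pytest.approx(h / np.log(3), abs=1e-12)

    def test_evenness_undefined_below_two_species(self):
        assert np.isnan(cd._shannon_evenness(np.array([7])))

    def test_metrics_table_shape_and_counts(self, small_bundle):
        metrics = cd.community_metrics(small_bundle)
        assert len(metrics) == len(small_bundle.sites)
        occ = small_bundle.occurrences
        for _, row in metrics.iterrows():
            comm = occ[(occ["site_id"] == row["site_id"]) & (occ["abundance"] > 0)]
            assert row["richness"] == comm["species_id"].nunique()
            assert row["abundance"] == comm["abundance"].sum()
        assert (metrics["fdis_morphology"] >= 0).all()
        assert (metrics["fdis_behavior"] >= 0).all()
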