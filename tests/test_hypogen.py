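import numpy as np
import pytest
from scipy.spatial.distance import pdist

from conftest import embed, make_cloud
from ligopharm import (
    FeatureType,
    GenerationConfig,
    Hypothesis,
    HypothesisFeature,
    enumerate_common_cliques,
    generate_hypotheses,
    map_ligand,
    rank_hypothesis,
)
from ligopharm._geometry import aligned_displacements
from ligopharm.synthetic import BenchmarkSpec, plant_pharmacophore
from oracles import brute_force_correspondences

A, D, H, R = (FeatureType.ACCEPTOR, FeatureType.DONOR,
              FeatureType.HYDROPHOBE, FeatureType.AROMATIC)


def _random_cloud(rng, n, types=(A, D, H, R), box=8.0):
    pts = []
    for k in range(n):
        pts.append((types[rng.integers(len(types))], rng.uniform(0, box, 3)))
    return make_cloud(pts).feature_sets[0]


class TestEnumerateCommonCliques:
    def test_identity_gives_single_full_correspondence(self):
        feats = make_cloud([(D, (0, 0, 0)), (A, (3, 0, 0)), (R, (0, 4, 0))]).feature_sets[0]
        corrs = enumerate_common_cliques(feats, list(feats), 1.0)
        assert corrs[0].size == 3
        assert corrs[0].pairs == ((0, 0), (1, 1), (2, 2))

    def test_disjoint_types_empty(self):
        f1 = make_cloud([(D, (0, 0, 0)), (D, (2, 0, 0))]).feature_sets[0]
        f2 = make_cloud([(A, (0, 0, 0)), (R, (2, 0, 0))]).feature_sets[0]
        assert enumerate_common_cliques(f1, f2, 1.0) == []

    def test_nonpositive_tolerance_rejected(self):
        f = make_cloud([(D, (0, 0, 0))]).feature_sets[0]
        with pytest.raises(ValueError):
            enumerate_common_cliques(f, f, 0.0)

    def test_planted_three_point_subarrangement_matches_oracle(self):
        # two 4-point sets sharing an exact 3-point arrangement
        common = [(D, (0, 0, 0)), (A, (3, 0, 0)), (R, (0, 4, 0))]
        f1 = make_cloud(common + [(H, (9, 9, 9))]).feature_sets[0]
        f2 = make_cloud(common + [(H, (-7, 5, 3))]).feature_sets[0]
        got = {frozenset(c.pairs) for c in enumerate_common_cliques(f1, f2, 0.5)}
        assert got == brute_force_correspondences(f1, f2, 0.5)

    @pytest.mark.parametrize("seed", range(25))
    def test_random_instances_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        f1 = _random_cloud(rng, rng.integers(2, 7))
        f2 = _random_cloud(rng, rng.integers(2, 7))
        got = {frozenset(c.pairs) for c in enumerate_common_cliques(f1, f2, 1.0)}
        assert got == brute_force_correspondences(f1, f2, 1.0)

    def test_deterministic_order(self):
        rng = np.random.default_rng(4)
        f1 = _random_cloud(rng, 6)
        f2 = _random_cloud(rng, 6)
        c1 = enumerate_common_cliques(f1, f2, 1.2)
        c2 = enumerate_common_cliques(f1, f2, 1.2)
        assert c1 == c2
        sizes = [c.size for c in c1]
        assert sizes == sorted(sizes, reverse=True)


class TestGenerateHypotheses:
    def test_planted_arrangement_recovered_exactly(self):
        spec = BenchmarkSpec(n_training=4, jitter_sd=0.0,
                             extra_features_per_mol=2, seed=21)
        template, training = plant_pharmacophore(spec)
        hyps = generate_hypotheses(training, cfg=GenerationConfig())
        top = hyps[0]
        assert top.composition == "RHDDDAA"
        assert top.direct_hit_mask == "1111"
        corr = enumerate_common_cliques(
            template.feature_points(), top.feature_points(), 1.6)[0]
        assert corr.size == 7
        P = np.array([top.features[j].position for _, j in corr.pairs])
        Q = np.array([template.features[i].position for i, _ in corr.pairs])
        assert aligned_displacements(P, Q).max() < 0.1

    def test_min_interfeature_distance_invariant(self):
        spec = BenchmarkSpec(n_training=4, seed=2)
        _, training = plant_pharmacophore(spec)
        cfg = GenerationConfig()
        for h in generate_hypotheses(training, cfg=cfg):
            assert pdist(h.positions()).min() >= cfg.min_interfeature_distance

    def test_duplication_invariance(self, planted_exact):
        _, _, training = planted_exact
        base = training[0]
        two = [base, base.copy()]
        eight = [base] + [base.copy() for _ in range(7)]
        h2 = generate_hypotheses(two, cfg=GenerationConfig())[0]
        h8 = generate_hypotheses(eight, cfg=GenerationConfig())[0]
        assert h2.composition == h8.composition
        assert np.allclose(sorted(pdist(h2.positions())),
                           sorted(pdist(h8.positions())), atol=1e-6)
        assert h8.direct_hit_mask == "1" * 8

    def test_all_training_molecules_map_within_budget(self, planted_exact):
        _, _, training = planted_exact
        cfg = GenerationConfig()
        for h in generate_hypotheses(training, cfg=cfg):
            for m in training:
                r = map_ligand(h, m, max_omit=cfg.max_omit_feat)
                assert r is not None and r.omitted <= cfg.max_omit_feat

    def test_featureless_molecule_named_in_error(self, planted_exact):
        _, _, training = planted_exact
        bad = make_cloud([], mol_id="empty_mol")
        with pytest.raises(ValueError, match="empty_mol"):
            generate_hypotheses(training + [bad], cfg=GenerationConfig())

    def test_requires_two_molecules(self, planted_exact):
        _, _, training = planted_exact
        with pytest.raises(ValueError):
            generate_hypotheses(training[:1], cfg=GenerationConfig())

    def test_real_molecules_share_donor_and_ring(self):
        # catechol / 2-aminophenol / salicylamide all carry an O-H donor on
        # an aromatic ring: the common hypothesis must include D and R
        training = [
            embed("Oc1ccccc1O", "catechol", max_conformers=3),
            embed("Oc1ccccc1N", "aminophenol", max_conformers=3),
            embed("NC(=O)c1ccccc1O", "salicylamide", max_conformers=3),
        ]
        hyps = generate_hypotheses(training, cfg=GenerationConfig(max_conformers=3))
        assert hyps
        types = {f.type for f in hyps[0].features}
        assert FeatureType.DONOR in types
        assert FeatureType.AROMATIC in types


class TestRankHypothesis:
    def test_empty_hypothesis_ranks_zero(self, planted_exact):
        _, _, training = planted_exact
        assert rank_hypothesis(Hypothesis("empty", []), training) == 0.0

    def test_dropping_matched_feature_never_increases_rank(self, planted_exact):
        _, template, training = planted_exact
        cfg = GenerationConfig()
        full_rank = rank_hypothesis(template, training, cfg)
        for i in range(len(template.features)):
            sub = Hypothesis(
                "sub", [f for k, f in enumerate(template.features) if k != i])
            assert rank_hypothesis(sub, training, cfg) <= full_rank

    def test_planted_outranks_every_strict_subhypothesis(self):
        from itertools import combinations

        spec = BenchmarkSpec(composition="RHDDA", n_training=3, jitter_sd=0.0,
                             extra_features_per_mol=0, seed=9)
        template, training = plant_pharmacophore(spec)
        cfg = GenerationConfig()
        full = rank_hypothesis(template, training, cfg)
        n = len(template.features)
        for size in range(1, n):
            for idx in combinations(range(n), size):
                sub = Hypothesis("sub", [template.features[i] for i in idx])
                assert rank_hypothesis(sub, training, cfg) < full
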