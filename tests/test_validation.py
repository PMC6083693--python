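from fractions import Fraction

import pytest

from conftest import make_cloud
from ligopharm import (
    DecoyCounts,
    GenerationConfig,
    compute_counts,
    compute_metrics,
    validate,
)
from ligopharm.hypogen import Correspondence
from ligopharm.screening import MappingResult
from ligopharm.synthetic import (
    BenchmarkSpec,
    corrupt_benchmark,
    make_decoy_benchmark,
    plant_pharmacophore,
)
from oracles import gh_formula


def _hit(mol_id):
    return MappingResult(mol_id, 0, Correspondence(()), 1.0, 0)


class TestDecoyCounts:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(D=10, A=3, Ht=5, Ha=4),   # Ha > A
            dict(D=10, A=3, Ht=11, Ha=3),  # Ht > D
            dict(D=10, A=9, Ht=10, Ha=5),  # inactive hits exceed inactives
            dict(D=-1, A=0, Ht=0, Ha=0),
        ],
    )
    def test_invalid_counts_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DecoyCounts(**kwargs)


class TestComputeCounts:
    def test_all_hits_active(self):
        labels = {f"a{i}": "active" for i in range(10)}
        labels.update({f"i{i}": "inactive" for i in range(5)})
        c = compute_counts([_hit(f"a{i}") for i in range(10)], labels)
        assert (c.D, c.A, c.Ht, c.Ha) == (15, 10, 10, 10)

    def test_no_hits(self):
        c = compute_counts([], {"a": "active", "b": "inactive"})
        assert (c.Ht, c.Ha) == (0, 0)

    def test_decoy_screen_contingency(self):
        labels = {f"act_{i}": "active" for i in range(30)}
        labels.update({f"dec_{i}": "inactive" for i in range(970)})
        hits = [_hit(f"act_{i}") for i in range(24)] + [_hit(f"dec_{i}") for i in range(6)]
        c = compute_counts(hits, labels)
        assert (c.D, c.A, c.Ht, c.Ha) == (1000, 30, 30, 24)

    def test_unlabeled_hit_is_fatal(self):
        with pytest.raises(KeyError, match="mystery"):
            compute_counts([_hit("mystery")], {"a": "active"})


class TestComputeMetrics:
    def test_decoy_screen_statistics_row(self):
        r = compute_metrics(DecoyCounts(D=1000, A=30, Ht=30, Ha=24))
        assert r.yield_of_actives == pytest.approx(80.0)
        assert r.ratio_of_actives == pytest.approx(80.0)
        assert r.enrichment_factor == pytest.approx(26.6667, abs=1e-3)
        assert (r.false_negatives, r.false_positives) == (6, 6)
        assert r.gh == pytest.approx(0.795051546, abs=1e-8)
        d = r.display()
        assert d == {
            "yield_of_actives": 80.0, "ratio_of_actives": 80.0,
            "enrichment_factor": 26.7, "false_negatives": 6,
            "false_positives": 6, "gh": 0.79,
        }
        assert r.annotation == "very good model"

    def test_perfect_retrieval_is_gh_one(self):
        r = compute_metrics(DecoyCounts(D=100, A=12, Ht=12, Ha=12))
        assert r.yield_of_actives == 100.0
        assert r.ratio_of_actives == 100.0
        assert r.gh == 1.0

    def test_zero_active_hits(self):
        r = compute_metrics(DecoyCounts(D=100, A=10, Ht=8, Ha=0))
        assert r.yield_of_actives == 0.0
        assert r.enrichment_factor == 0.0
        assert r.gh == 0.0

    def test_no_hits_yield_undefined(self):
        r = compute_metrics(DecoyCounts(D=100, A=10, Ht=0, Ha=0))
        assert r.yield_of_actives is None
        assert r.enrichment_factor is None
        assert any("Ht = 0" in w for w in r.warnings)

    def test_no_actives_ratio_undefined(self):
        r = compute_metrics(DecoyCounts(D=100, A=0, Ht=5, Ha=0))
        assert r.ratio_of_actives is None
        assert r.gh is None

    @pytest.mark.parametrize("counts", [(50, 10, 20, 8), (200, 40, 13, 11), (9, 2, 3, 1)])
    def test_enrichment_factor_exact_integer_identity(self, counts):
        D, A, Ht, Ha = counts
        r = compute_metrics(DecoyCounts(D, A, Ht, Ha))
        assert r.enrichment_factor == float(Fraction(Ha * D, Ht * A))

    def test_scale_consistency_under_doubling(self):
        r1 = compute_metrics(DecoyCounts(500, 15, 15, 12))
        r2 = compute_metrics(DecoyCounts(1000, 30, 30, 24))
        assert r1.yield_of_actives == r2.yield_of_actives
        assert r1.ratio_of_actives == r2.ratio_of_actives
        assert r1.enrichment_factor == r2.enrichment_factor

    def test_gh_bounds_small_bruteforce(self):
        for D in range(2, 21):
            for A_ in range(1, D):
                for Ht in range(1, D + 1):
                    lo = max(0, Ht - (D - A_))
                    for Ha in range(lo, min(A_, Ht) + 1):
                        gh = compute_metrics(DecoyCounts(D, A_, Ht, Ha)).gh
                        assert -1e-12 <= gh <= 1 + 1e-12
                        assert gh == pytest.approx(gh_formula(D, A_, Ht, Ha), abs=1e-12)
                        if Ha == Ht == A_:
                            assert gh == 1.0
                        else:
                            assert gh < 1.0


class TestValidateEndToEnd:
    def test_clean_planted_benchmark_is_perfect(self):
        spec = BenchmarkSpec(n_actives=10, n_inactives=40, jitter_sd=0.0, seed=6)
        template, _ = plant_pharmacophore(spec)
        db, labels = make_decoy_benchmark(spec, template)
        r = validate(template, db, labels, cfg=GenerationConfig(), max_omit=0)
        assert r.yield_of_actives == 100.0
        assert r.ratio_of_actives == 100.0
        assert r.gh == 1.0

    def test_all_actives_corrupted_gives_gh_zero(self):
        spec = BenchmarkSpec(n_actives=5, n_inactives=20, seed=6)
        template, _ = plant_pharmacophore(spec)
        db, labels = make_decoy_benchmark(spec, template)
        db = corrupt_benchmark(db, labels, 5, 1, seed=1, template=template)
        r = validate(template, db, labels, cfg=GenerationConfig(), max_omit=0)
        assert r.counts.Ha == 0
        assert r.gh == 0.0

    def test_zero_actives_marks_ratio_undefined(self):
        spec = BenchmarkSpec(n_actives=0, n_inactives=20, seed=6)
        template, _ = plant_pharmacophore(spec)
        db, labels = make_decoy_benchmark(spec, template)
        r = validate(template, db, labels, max_omit=0)
        assert r.ratio_of_actives is None
        assert r.warnings
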