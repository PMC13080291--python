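"""K-prototypes fitting, silhouette scoring, CV model selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from personakit import (DistanceMatrix, DistanceSpec, SurveyDataset, assign,
                        build_supplemental_cluster, cv_silhouette,
                        fit_kprototypes, pairwise_distances, select_k,
                        silhouette)
from personakit.clustering import _update_prototypes
from personakit.errors import InfeasibleError, UndefinedSilhouetteError
from personakit.gower import cross_gower, encode_record, encode_records
from personakit.synth import GeneratorConfig, generate


def _spec(dataset):
    return DistanceSpec.from_dataset(dataset)


class TestFit:
    def test_k1_prototype_is_dataset_mode(self, make_tiny_dataset):
        ds = make_tiny_dataset(n=9, seed=4)
        model = fit_kprototypes(ds, _spec(ds), K=1, seed=0, n_restarts=1)
        proto = model.prototypes.loc[1]
        for v in ds.schema.variables:
            counts = ds.data[v.name].value_counts()
            top = counts.max()
            expected = next(c for c in v.categories if counts.get(c, 0) == top)
            assert proto[v.name] == expected

    def test_two_pure_groups_recovered_with_zero_objective(self, tiny_schema):
        df = pd.DataFrame(
            [["x", "u", "p"]] * 4 + [["y", "v", "q"]] * 4,
            columns=["a", "b", "c"], index=[f"r{i}" for i in range(8)])
        ds = SurveyDataset(tiny_schema, df)
        model = fit_kprototypes(ds, _spec(ds), K=2, seed=0, n_restarts=5)
        assert model.objective == 0.0
        groups = {tuple(sorted(model.members(k))) for k in (1, 2)}
        assert groups == {tuple(f"r{i}" for i in range(4)),
                          tuple(f"r{i}" for i in range(4, 8))}

    def test_matches_exhaustive_bipartition_optimum(self, make_tiny_dataset):
        """With many restarts the fit attains the global optimum found by
        enumerating all nonempty bipartitions of 8 records."""
        ds = make_tiny_dataset(n=8, seed=12)
        spec = _spec(ds)
        X = encode_records(ds.data, spec)
        best = np.inf
        for bits in range(1, 2 ** 8 - 1):
            labels = np.array([(bits >> i) & 1 for i in range(8)])
            P = _update_prototypes(X, labels, 2, spec)
            D = cross_gower(X, P, spec)
            best = min(best, D[np.arange(8), labels].sum())
        model = fit_kprototypes(ds, spec, K=2, seed=1, n_restarts=50)
        assert model.objective == pytest.approx(best, abs=1e-12)

    def test_objective_matches_recomputation_and_is_monotone(self, main_sample):
        main, _ = main_sample
        spec = _spec(main)
        model = fit_kprototypes(main, spec, K=4, seed=3, n_restarts=2)
        # invariant: objective equals sum of distances to assigned prototypes
        X = encode_records(main.data, spec)
        P = encode_records(model.prototypes, spec)
        labels = model.assignments.to_numpy() - 1
        D = cross_gower(X, P, spec)
        assert model.objective == pytest.approx(
            float(D[np.arange(len(labels)), labels].sum()), rel=1e-12)
        # invariant: per-iteration objective never increases
        traj = np.array(model.objective_trajectory)
        assert np.all(np.diff(traj) <= 1e-9)

    def test_cluster_labels_ordered_by_descending_size(self, main_sample):
        main, _ = main_sample
        model = fit_kprototypes(main, _spec(main), K=5, seed=0, n_restarts=2)
        sizes = [model.sizes()[k] for k in range(1, 6)]
        assert sizes == sorted(sizes, reverse=True)
        assert min(sizes) > 0

    def test_every_record_assigned_exactly_once(self, main_sample):
        main, _ = main_sample
        model = fit_kprototypes(main, _spec(main), K=3, seed=0, n_restarts=1)
        assert set(model.assignments.index) == set(main.ids)
        assert model.assignments.isin(range(1, 4)).all()

    def test_infeasible_k_raises(self, tiny_schema):
        df = pd.DataFrame([["x", "u", "p"]] * 3, columns=["a", "b", "c"],
                          index=["r0", "r1", "r2"])
        ds = SurveyDataset(tiny_schema, df)
        with pytest.raises(InfeasibleError):
            fit_kprototypes(ds, _spec(ds), K=2, seed=0, n_restarts=1)

    def test_deterministic_given_seed(self, make_tiny_dataset):
        ds = make_tiny_dataset(n=20, seed=8)
        a = fit_kprototypes(ds, _spec(ds), K=3, seed=42, n_restarts=4)
        b = fit_kprototypes(ds, _spec(ds), K=3, seed=42, n_restarts=4)
        assert a.objective == b.objective
        assert (a.assignments == b.assignments).all()


class TestAssign:
    def test_record_equal_to_prototype_gets_that_cluster(self, main_sample):
        main, _ = main_sample
        spec = _spec(main)
        model = fit_kprototypes(main, spec, K=3, seed=1, n_restarts=2)
        record = model.prototypes.loc[2].to_dict()
        assert assign(model, record, spec) == 2

    def test_tie_goes_to_lowest_cluster_index(self, tiny_schema):
        from personakit.clustering import ClusterModel
        prototypes = pd.DataFrame(
            [["x", "u", "p"], ["x", "u", "q"]],
            columns=["a", "b", "c"], index=[1, 2])
        model = ClusterModel(K=2, prototypes=prototypes,
                             assignments=pd.Series(dtype=int), objective=0.0,
                             seed=0, n_restarts=1, converged=True)
        spec = DistanceSpec(schema=tiny_schema)
        # differs from both prototypes only on c: equidistant -> cluster 1
        assert assign(model, {"a": "x", "b": "u", "c": "r"}, spec) == 1

    def test_assignment_is_argmin_over_explicit_distances(self, main_sample):
        main, _ = main_sample
        spec = _spec(main)
        model = fit_kprototypes(main, spec, K=4, seed=5, n_restarts=2)
        rng = np.random.default_rng(0)
        for _ in range(20):
            record = {v.name: v.categories[rng.integers(len(v.categories))]
                      for v in spec.schema.variables}
            x = encode_record(record, spec)[None, :]
            P = encode_records(model.prototypes, spec)
            expected = int(np.argmin(cross_gower(x, P, spec)[0])) + 1
            assert assign(model, record, spec) == expected


class TestSilhouette:
    def test_perfect_separation_gives_all_ones(self):
        ids = tuple("abcdef")
        D = np.ones((6, 6))
        D[:3, :3] = 0.0
        D[3:, 3:] = 0.0
        np.fill_diagonal(D, 0.0)
        res = silhouette({i: (1 if i in "abc" else 2) for i in ids},
                         DistanceMatrix(ids, D))
        assert all(w == 1.0 for w in res.per_point.values())
        assert res.mean == 1.0

    def test_singleton_cluster_scores_zero(self):
        ids = ("a", "b", "c")
        D = np.array([[0, .1, .9], [.1, 0, .8], [.9, .8, 0]])
        res = silhouette({"a": 1, "b": 1, "c": 2}, DistanceMatrix(ids, D))
        assert res.per_point["c"] == 0.0

    def test_single_cluster_is_undefined(self):
        ids = ("a", "b")
        with pytest.raises(UndefinedSilhouetteError):
            silhouette({"a": 1, "b": 1},
                       DistanceMatrix(ids, np.array([[0, .5], [.5, 0]])))

    def test_six_point_instance_matches_hand_computation(self):
        """Worked instance: widths recomputed from the textbook formula."""
        ids = tuple("pqrstu")
        rng = np.random.default_rng(99)
        pts = np.concatenate([rng.normal(0, .05, (3, 1)),
                              rng.normal(1, .05, (3, 1))])
        D = np.abs(pts - pts.T)
        D = np.clip(D, 0, 1)
        labels = {i: (1 if k < 3 else 2) for k, i in enumerate(ids)}
        res = silhouette(labels, DistanceMatrix(ids, D))
        for k, i in enumerate(ids):
            own = [j for j, l in enumerate(ids) if labels[l] == labels[i] and j != k]
            other = [j for j, l in enumerate(ids) if labels[l] != labels[i]]
            a = np.mean([D[k, j] for j in own])
            b = np.mean([D[k, j] for j in other])
            assert res.per_point[i] == pytest.approx((b - a) / max(a, b), abs=1e-12)

    def test_agrees_with_sklearn_on_survey_sample(self, main_sample):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        main, _ = main_sample
        sub = main.filter(main.data.index.isin(main.ids[:60]))
        spec = _spec(sub)
        model = fit_kprototypes(sub, spec, K=3, seed=2, n_restarts=2)
        D = pairwise_distances(sub, spec)
        res = silhouette(dict(model.assignments), D)
        ref = sklearn_metrics.silhouette_samples(
            D.values, model.assignments.to_numpy(), metric="precomputed")
        ours = np.array([res.per_point[i] for i in D.ids])
        assert np.allclose(ours, ref, atol=1e-12)

    def test_widths_within_unit_interval(self, main_sample):
        main, _ = main_sample
        sub = main.filter(main.data.index.isin(main.ids[:80]))
        spec = _spec(sub)
        model = fit_kprototypes(sub, spec, K=4, seed=7, n_restarts=2)
        res = silhouette(dict(model.assignments), pairwise_distances(sub, spec))
        widths = np.array(list(res.per_point.values()))
        assert np.all(widths >= -1) and np.all(widths <= 1)
        assert res.mean == pytest.approx(widths.mean())


class TestCrossValidatedSilhouette:
    def test_perfectly_separated_duplicates_score_one(self, tiny_schema):
        df = pd.DataFrame([["x", "u", "p"]] * 6 + [["y", "v", "q"]] * 6,
                          columns=["a", "b", "c"],
                          index=[f"r{i}" for i in range(12)])
        ds = SurveyDataset(tiny_schema, df)
        res = cv_silhouette(ds, _spec(ds), K=2, folds=2, seed=0, n_restarts=5)
        assert res.mean == 1.0

    def test_same_seed_gives_identical_result(self, main_sample):
        main, _ = main_sample
        sub = main.filter(main.data.index.isin(main.ids[:120]))
        spec = _spec(sub)
        a = cv_silhouette(sub, spec, K=3, folds=5, seed=9, n_restarts=2)
        b = cv_silhouette(sub, spec, K=3, folds=5, seed=9, n_restarts=2)
        assert a.per_point == b.per_point and a.mean == b.mean

    def test_planted_k_beats_neighbours(self):
        config = GeneratorConfig(seed=17, cluster_sizes=(60, 60, 60),
                                 adherence=0.95, minority_counts={})
        dataset, _ = generate(config)
        spec = _spec(dataset)
        scores = {k: cv_silhouette(dataset, spec, K=k, folds=5, seed=17,
                                   n_restarts=3).mean for k in (2, 3, 4)}
        assert scores[3] > scores[2] and scores[3] > scores[4]

    def test_select_k_single_candidate(self, make_tiny_dataset):
        ds = make_tiny_dataset(n=30, seed=2)
        k, scores = select_k(ds, _spec(ds), [2], folds=3, seed=0, n_restarts=2)
        assert k == 2 and set(scores) == {2}

    def test_select_k_recovers_three_planted_clusters(self):
        config = GeneratorConfig(seed=23, cluster_sizes=(50, 50, 50),
                                 adherence=0.95, minority_counts={})
        dataset, _ = generate(config)
        k, _ = select_k(dataset, _spec(dataset), range(2, 5), folds=5,
                        seed=23, n_restarts=3)
        assert k == 3


class TestSupplementalCluster:
    def test_planted_gender_minority_found(self, survey_dataset):
        dataset, truth = survey_dataset
        supp = build_supplemental_cluster(
            dataset, {"sex": ("Nonbinary", "Transgender")})
        assert set(supp.members) == set(truth.minority_ids)
        assert len(supp.members) == 8

    def test_summary_counts_sum_to_member_count(self, survey_dataset):
        dataset, _ = survey_dataset
        supp = build_supplemental_cluster(
            dataset, {"sex": ("Nonbinary", "Transgender")})
        for name, info in supp.summary.items():
            assert sum(info["counts"].values()) + info["missing"] == len(supp.members)

    def test_modal_value_matches_planted_majority(self, survey_dataset):
        dataset, _ = survey_dataset
        supp = build_supplemental_cluster(
            dataset, {"sex": ("Nonbinary", "Transgender")})
        counts = supp.summary["sex"]["counts"]
        assert supp.modal("sex") == max(counts, key=counts.get)

    def test_empty_predicate_warns(self, make_tiny_dataset):
        ds = make_tiny_dataset(n=5, seed=0)
        with pytest.warns(UserWarning, match="matched no respondents"):
            supp = build_supplemental_cluster(ds, {"a": ()})
        assert supp.members == ()
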