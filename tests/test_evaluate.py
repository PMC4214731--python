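import numpy as np
import pytest

import drugnet as dn
from drugnet.entities import AssociationSet, Catalogs
from drugnet.evaluate import ConstantBackend, FEATURE_SETS, make_backend
from drugnet.exceptions import ParameterError


class TestComputeAuc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),   # perfect separation
            ([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0], 0.5),   # all ties
            ([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0], 0.75),  # 3 wins of 4 pairs
            ([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0], 0.0),   # inverted ranking
        ],
    )
    def test_known_rankings(self, scores, labels, expected):
        assert dn.compute_auc(scores, labels) == expected

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            dn.compute_auc([0.1, 0.2], [1, 1])

    def test_matches_roc_integration_oracle(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(4, 60))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(n), 2)  # rounded to force ties
            assert dn.compute_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )


class TestBackends:
    def test_registry_covers_reference_backends(self):
        for name in ("tree", "forest", "mlp", "constant"):
            backend = make_backend(name, seed=0)
            assert hasattr(backend, "fit") and hasattr(backend, "score")
        with pytest.raises(ParameterError):
            make_backend("svm")

    def test_schema_mismatch_rejected(self, small_benchmark, cfg):
        mat = dn.build_training_matrix(
            small_benchmark["assoc"], small_benchmark["catalogs"],
            small_benchmark["net"], cfg, seed=0,
        )
        y = (mat["label"] == "positive").astype(int)
        model = make_backend("tree", seed=0).fit(mat[list(dn.FEATURE_NAMES)], y)
        with pytest.raises(ParameterError):
            model.score(mat[list(dn.FEATURE_NAMES[:5])])


class _LabelOracle:
    """Backend that memorizes the pair-feature -> label map of the whole
    benchmark and emits the true label as its score."""

    name = "oracle"
    feature_names_ = None

    def __init__(self, truth):
        self.truth = truth

    def fit(self, features, labels):
        self.feature_names_ = tuple(features.columns)
        return self

    def score(self, features):
        return np.array([self.truth[tuple(row)] for row in features.to_numpy()])


class TestRepeatedCV:
    def test_oracle_backend_reaches_perfect_auc(self, small_benchmark, cfg):
        bm = small_benchmark
        # memorize every possible row the CV can build: positives and any
        # sampled negative both use self-excluded feature vectors
        truth = {}
        all_pairs = [
            (d, p) for d in bm["catalogs"].drugs for p in bm["catalogs"].diseases
        ]
        for d, p in all_pairs:
            vec = dn.build_feature_vector(
                d, p, bm["catalogs"], bm["assoc"], bm["net"], cfg, exclude_self=True
            )
            truth[tuple(vec)] = 1 if (d, p) in bm["assoc"] else 0
        res = dn.repeated_cv(
            bm["assoc"], bm["catalogs"], bm["net"], cfg,
            backend=lambda seed: _LabelOracle(truth), folds=5, repeats=2, seed=4,
        )
        assert res.grand_mean_auc == 1.0

    def test_constant_backend_is_uninformative(self, small_benchmark, cfg):
        bm = small_benchmark
        res = dn.repeated_cv(
            bm["assoc"], bm["catalogs"], bm["net"], cfg,
            backend="constant", folds=5, repeats=2, seed=4,
        )
        assert res.grand_mean_auc == 0.5

    def test_same_seed_reproduces_result(self, small_benchmark, cfg, tmp_path):
        bm = small_benchmark
        runs = [
            dn.repeated_cv(
                bm["assoc"], bm["catalogs"], bm["net"], cfg,
                backend="tree", folds=5, repeats=2, seed=9,
            )
            for _ in range(2)
        ]
        assert runs[0].repeat_aucs == runs[1].repeat_aucs
        assert runs[0].negative_seeds == runs[1].negative_seeds
        assert runs[0].info_gain == runs[1].info_gain
        out1, out2 = tmp_path / "a.json", tmp_path / "b.json"
        runs[0].to_json(out1)
        runs[1].to_json(out2)
        assert out1.read_bytes() == out2.read_bytes()

    def test_feature_subsets_restrict_columns(self):
        assert set(FEATURE_SETS["adjacency"]) < set(FEATURE_SETS["all"])
        assert set(FEATURE_SETS["module"]) < set(FEATURE_SETS["all"])
        assert len(FEATURE_SETS["adjacency"]) == 3
        assert len(FEATURE_SETS["module"]) == 27

    def test_too_few_positives_rejected(self, chain_net, cfg):
        catalogs = Catalogs(
            drugs={"d1": frozenset("AB")}, diseases={"p1": frozenset("CD")}
        )
        assoc = AssociationSet([("d1", "p1")])
        with pytest.raises(ParameterError):
            dn.repeated_cv(assoc, catalogs, chain_net, cfg, folds=10)


class TestPredictCandidates:
    @pytest.fixture
    def trained(self, small_benchmark, cfg):
        bm = small_benchmark
        model = dn.fit_full(
            bm["assoc"], bm["catalogs"], bm["net"], cfg, backend="tree", seed=0
        )
        return bm, model

    def test_candidate_universe_excludes_known_positives(self, trained, cfg):
        bm, model = trained
        table = dn.predict_candidates(
            model, None, bm["catalogs"], bm["assoc"], bm["net"], cfg
        )
        n_drugs = len(bm["catalogs"].drugs)
        n_dis = len(bm["catalogs"].diseases)
        assert len(table) == n_drugs * n_dis - len(bm["assoc"])
        known = set(bm["assoc"].pairs)
        assert not any((r.drug, r.disease) in known for r in table.itertuples())
        assert list(table["score"]) == sorted(table["score"], reverse=True)

    def test_candidates_equal_to_known_positives_yield_empty_table(self, trained, cfg):
        bm, model = trained
        table = dn.predict_candidates(
            model, list(bm["assoc"]), bm["catalogs"], bm["assoc"], bm["net"], cfg
        )
        assert len(table) == 0

    def test_unattainable_threshold_predicts_nothing(self, trained, cfg):
        bm, model = trained
        table = dn.predict_candidates(
            model, None, bm["catalogs"], bm["assoc"], bm["net"], cfg, threshold=1.01
        )
        assert (table["predicted"] == "no").all()

    def test_explicit_candidate_counting(self, trained, cfg):
        bm, model = trained
        drugs = sorted(bm["catalogs"].drugs)[:5]
        diseases = sorted(bm["catalogs"].diseases)[:4]
        pairs = [(d, p) for d in drugs for p in diseases]
        known = [pair for pair in pairs if pair in bm["assoc"]]
        table = dn.predict_candidates(
            model, pairs, bm["catalogs"], bm["assoc"], bm["net"], cfg
        )
        assert len(table) == 20 - len(known)


def test_information_gain_ranks_all_features(small_benchmark, cfg):
    bm = small_benchmark
    mat = dn.build_training_matrix(bm["assoc"], bm["catalogs"], bm["net"], cfg, seed=1)
    ig = dn.information_gain(
        mat[list(dn.FEATURE_NAMES)], (mat["label"] == "positive").astype(int), seed=0
    )
    assert set(ig.index) == set(dn.FEATURE_NAMES)
    assert list(ig) == sorted(ig, reverse=True)
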