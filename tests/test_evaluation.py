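import numpy as np
import pytest
from scipy import stats

from specaug.evaluation import (
    HOLDOUT,
    ContingencyTable,
    PredictionRecord,
    auc_mann_whitney,
    balance_report,
    chi_square_independence,
    classification_metrics,
    delong_test,
    delong_variance,
    read_predictions,
    soft_vote,
    stratified_holdout,
    stratified_kfold,
    stress_schedule,
)
from specaug.io_manifest import (
    AnnotatedSample,
    BoundingBox,
    DatasetManifest,
    ValidationError,
    seeded_rng,
)

# Printed training/test covariate counts for the 2,616-image NBI cohort.
COHORT_TABLES = {
    "diagnosis": ([[1249, 120], [1127, 120]], 0.448),
    "location": ([[1309, 130], [1067, 110]], 0.783),
    "size": ([[1928, 197], [382, 35], [66, 8]], 0.753),
    "morphology": ([[571, 59], [1805, 181]], 0.849),
}


def _manifest(n_ad, n_hp, **meta_fn):
    samples = []
    for i in range(n_ad + n_hp):
        label = "AD" if i < n_ad else "HP"
        md = {k: fn(i) for k, fn in meta_fn.items()}
        samples.append(
            AnnotatedSample(f"img_{i}.png", label, BoundingBox(0, 0, 4, 4), metadata=md)
        )
    return DatasetManifest(samples)


def _preds(labels, scores, groups=None):
    return [
        PredictionRecord(
            str(i), labels[i], float(scores[i]),
            group_id=None if groups is None else groups[i],
        )
        for i in range(len(labels))
    ]


def brute_force_chi2(counts):
    counts = np.asarray(counts, float)
    total = counts.sum()
    rows = counts.sum(axis=1, keepdims=True)
    cols = counts.sum(axis=0, keepdims=True)
    expected = rows @ cols / total
    stat = ((counts - expected) ** 2 / expected).sum()
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return stat, df, stats.chi2.sf(stat, df)


class TestChiSquare:
    @pytest.mark.parametrize("name", list(COHORT_TABLES))
    def test_cohort_balance_p_values(self, name):
        counts, expected_p = COHORT_TABLES[name]
        _, _, p = chi_square_independence(ContingencyTable(counts))
        assert round(p, 3) == expected_p

    def test_identical_proportions_give_zero_statistic(self):
        stat, df, p = chi_square_independence(ContingencyTable([[10, 10], [10, 10]]))
        assert stat == 0.0 and p == 1.0

    def test_matches_textbook_oracle_on_margin_sweep(self):
        rng = seeded_rng(3)
        for _ in range(200):
            r, c = rng.choice([2, 3]), 2
            counts = rng.integers(1, 51, (r, c))
            stat, df, p = chi_square_independence(ContingencyTable(counts))
            ostat, odf, op = brute_force_chi2(counts)
            assert stat == pytest.approx(ostat)
            assert df == odf
            assert p == pytest.approx(op)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_independence(ContingencyTable([[0, 0], [5, 5]]))

    def test_column_percentages(self):
        t = ContingencyTable([[1928, 197], [382, 35], [66, 8]])
        pct = t.column_percentages()
        assert pct[0, 0] == 81.1  # diminutive share of the training column
        assert pct[0, 1] == 82.1


class TestBalanceReport:
    def test_equal_proportions_give_p_one(self):
        train = _manifest(20, 20)
        test = _manifest(5, 5)
        rep = balance_report(train, test, ["label"])
        assert rep.loc[0, "p"] == pytest.approx(1.0)

    def test_covariate_from_metadata(self):
        train = _manifest(10, 10, location=lambda i: "left" if i % 2 else "right")
        test = _manifest(4, 4, location=lambda i: "left" if i % 2 else "right")
        rep = balance_report(train, test, ["label", "location"])
        assert list(rep["covariate"]) == ["label", "location"]
        assert (rep["p"] > 0.99).all()

    def test_missing_covariate_rejected(self):
        with pytest.raises(ValidationError, match="missing"):
            balance_report(_manifest(3, 3), _manifest(2, 2), ["size"])


class TestSplits:
    def test_holdout_matches_cohort_arithmetic(self, rng):
        manifest = _manifest(1369, 1247)
        plan = stratified_holdout(manifest, 120, rng)
        pool = manifest.subset(plan.indices(0))
        assert len(plan.holdout_indices) == 240
        assert len(pool) == 2376
        assert pool.label_counts == {"AD": 1249, "HP": 1127}

    def test_zero_holdout(self, rng):
        plan = stratified_holdout(_manifest(5, 5), 0, rng)
        assert len(plan.holdout_indices) == 0

    def test_holdout_deterministic(self):
        m = _manifest(30, 30)
        a = stratified_holdout(m, 5, seeded_rng(2))
        b = stratified_holdout(m, 5, seeded_rng(2))
        assert np.array_equal(a.folds, b.folds)

    def test_insufficient_class_rejected(self, rng):
        with pytest.raises(ValidationError):
            stratified_holdout(_manifest(3, 10), 5, rng)

    def test_kfold_exact_division(self, rng):
        plan = stratified_kfold(_manifest(10, 10), 5, rng)
        m = _manifest(10, 10)
        for f in range(5):
            sub = m.subset(plan.indices(f))
            assert sub.label_counts == {"AD": 2, "HP": 2}

    def test_kfold_remainder_rule(self, rng):
        plan = stratified_kfold(_manifest(11, 10), 5, rng)
        m = _manifest(11, 10)
        ad_sizes = sorted(
            m.subset(plan.indices(f)).label_counts["AD"] for f in range(5)
        )
        assert ad_sizes == [2, 2, 2, 2, 3]

    def test_kfold_is_a_partition(self, rng):
        plan = stratified_kfold(_manifest(13, 9), 4, rng)
        all_idx = np.concatenate([plan.indices(f) for f in range(4)])
        assert sorted(all_idx) == list(range(22))


class TestStressSchedule:
    def test_full_fraction_selects_everything(self, rng):
        m = _manifest(10, 10)
        plans = stress_schedule(m, fractions=(1.0,), rng=rng)
        assert len(plans[0].selected_indices) == 20

    def test_per_class_sizes_follow_fractions(self, rng):
        m = _manifest(100, 100)
        plans = stress_schedule(m, rng=rng)
        for i, plan in enumerate(plans):
            sub = m.subset(plan.selected_indices)
            n = 10 * (i + 1)
            assert sub.label_counts == {"AD": n, "HP": n}

    def test_nesting_across_fractions(self):
        m = _manifest(37, 23)
        for seed in (0, 1, 2):
            plans = stress_schedule(m, rng=seeded_rng(seed))
            for a, b in zip(plans, plans[1:]):
                assert set(a.selected_indices) <= set(b.selected_indices)


class TestMetrics:
    def test_perfect_separation(self):
        preds = _preds(["AD"] * 3 + ["HP"] * 3, [0.9, 0.8, 0.7, 0.2, 0.1, 0.0])
        m = classification_metrics(preds)
        assert m["AUC"] == 1.0 and m["ACC"] == 1.0
        assert m["SEN"] == m["SPE"] == m["PPV"] == m["NPV"] == 1.0

    def test_all_ties_give_half_auc(self):
        preds = _preds(["AD", "AD", "HP", "HP"], [0.5] * 4)
        assert auc_mann_whitney(preds) == 0.5

    def test_auc_equals_pair_counting_oracle(self):
        rng = seeded_rng(21)
        scores = np.round(rng.random(6), 1)  # rounding forces some ties
        labels = ["AD", "HP", "AD", "HP", "AD", "HP"]
        preds = _preds(labels, scores)
        pos = scores[[0, 2, 4]]
        neg = scores[[1, 3, 5]]
        brute = np.mean(
            [1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg]
        )
        assert auc_mann_whitney(preds) == pytest.approx(brute)

    def test_auc_equals_trapezoidal_roc(self):
        from sklearn.metrics import roc_auc_score

        rng = seeded_rng(22)
        labels = ["AD" if b else "HP" for b in rng.random(50) > 0.5]
        scores = np.round(rng.random(50), 2)
        preds = _preds(labels, scores)
        sk = roc_auc_score([1 if l == "AD" else 0 for l in labels], scores)
        assert auc_mann_whitney(preds) == pytest.approx(sk)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            classification_metrics(_preds(["AD", "AD"], [0.5, 0.6]))


class TestDeLong:
    def _toy(self, seed=11, n=40, noise=0.15):
        rng = seeded_rng(seed)
        labels = ["AD"] * (n // 2) + ["HP"] * (n // 2)
        mu = np.where(np.arange(n) < n // 2, 0.6, 0.4)
        scores = np.clip(mu + rng.normal(0, noise, n), 0, 1)
        return _preds(labels, scores)

    def test_identical_classifiers(self):
        preds = self._toy()
        auc_a, auc_b, z, p = delong_test(preds, preds)
        assert auc_a == auc_b and z == 0.0 and p == 1.0

    def test_antisymmetry(self):
        a, b = self._toy(11), self._toy(13)
        _, _, z_ab, p_ab = delong_test(a, b)
        _, _, z_ba, p_ba = delong_test(b, a)
        assert z_ab == pytest.approx(-z_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_variance_tracks_bootstrap(self):
        """DeLong AUC variance within 15% of a 10^4-resample bootstrap."""
        preds = self._toy()
        dv = delong_variance(preds)
        rng = seeded_rng(99)
        pos = [r for r in preds if r.true_label == "AD"]
        neg = [r for r in preds if r.true_label == "HP"]
        boots = []
        for _ in range(10_000):
            sub = [pos[i] for i in rng.integers(0, 20, 20)] + [
                neg[i] for i in rng.integers(0, 20, 20)
            ]
            boots.append(auc_mann_whitney(sub))
        bv = np.var(boots, ddof=1)
        assert abs(dv - bv) / bv < 0.15

    def test_unpaired_inputs_rejected(self):
        a = self._toy()
        b = self._toy()[:-1]
        with pytest.raises(ValidationError):
            delong_test(a, b)


class TestSoftVote:
    def test_single_member_groups_identity(self):
        preds = _preds(["AD", "HP"], [0.7, 0.3], groups=["g1", "g2"])
        out = soft_vote(preds)
        assert [r.score for r in out] == [0.7, 0.3]

    def test_group_mean(self):
        preds = _preds(["AD"] * 3, [0.2, 0.4, 0.9], groups=["g"] * 3)
        out = soft_vote(preds)
        assert len(out) == 1
        assert out[0].score == pytest.approx(0.5)

    def test_inconsistent_group_labels_rejected(self):
        preds = _preds(["AD", "HP"], [0.7, 0.3], groups=["g", "g"])
        with pytest.raises(ValidationError):
            soft_vote(preds)

    def test_voting_improves_auc_under_symmetric_frame_noise(self):
        """Averaging noisy frame scores within a clip raises AUC on average."""
        rng = seeded_rng(5)
        frame_aucs, clip_aucs = [], []
        for _ in range(100):
            labels, scores, groups = [], [], []
            for clip in range(20):
                lab = "AD" if clip % 2 else "HP"
                mu = 0.6 if lab == "AD" else 0.4
                for f in range(5):
                    labels.append(lab)
                    scores.append(float(np.clip(mu + rng.normal(0, 0.2), 0, 1)))
                    groups.append(f"clip{clip}")
            preds = _preds(labels, scores, groups=groups)
            frame_aucs.append(auc_mann_whitney(preds))
            clip_aucs.append(auc_mann_whitney(soft_vote(preds)))
        assert np.mean(clip_aucs) >= np.mean(frame_aucs)


def test_prediction_csv_round_trip(tmp_path):
    path = tmp_path / "p.csv"
    path.write_text(
        "sample_id,group_id,true_label,score\n"
        "f1,c1,AD,0.9\nf2,c1,AD,0.7\nf3,,HP,0.2\n"
    )
    preds = read_predictions(path)
    assert preds[0].group_id == "c1" and preds[2].group_id is None
    assert preds[1].score == 0.7
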