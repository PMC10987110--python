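"""Splits, confusion metrics, AUROC, bootstrap, concordance, per-domain."""

import numpy as np
import pandas as pd
import pytest

from varens import (
    DomainAnnotation,
    EnsembleModel,
    auroc,
    bootstrap_metrics,
    concordance_counts,
    confusion_metrics,
    per_domain_metrics,
    split_train_validation,
)
from varens.metrics import (
    ConfusionCounts,
    metrics_from_counts,
    round_half_up,
    training_count,
)
from tests.conftest import PREDICTORS, make_normalized_table


def mann_whitney_auroc(scores, labels) -> float:
    """Brute-force pairwise P(score_path > score_ben) + 0.5 P(tie), in %."""
    pos = [s for s, l in zip(scores, labels) if l == "pathogenic"]
    neg = [s for s, l in zip(scores, labels) if l == "benign"]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return 100.0 * wins / (len(pos) * len(neg))


def labeled_table(scores_pos, scores_neg, predictor="REVEL"):
    values = list(scores_pos) + list(scores_neg)
    labels = ["pathogenic"] * len(scores_pos) + ["benign"] * len(scores_neg)
    X = np.array(values, dtype=float).reshape(-1, 1)
    return make_normalized_table(X, labels=labels, predictors=[predictor])


class TestSplit:
    def test_published_cohort_sizes(self):
        # 609 pathogenic -> 457/152, 60 benign -> 40/20
        X = np.full((669, 1), 0.5)
        labels = ["pathogenic"] * 609 + ["benign"] * 60
        t = make_normalized_table(X, labels=labels, predictors=["REVEL"])
        train, valid = split_train_validation(t, seed=0)
        assert (train.labels == "pathogenic").sum() == 457
        assert (valid.labels == "pathogenic").sum() == 152
        assert (train.labels == "benign").sum() == 40
        assert (valid.labels == "benign").sum() == 20

    def test_rounding_rules_for_all_sizes(self):
        for n in range(1, 10_001):
            assert training_count(n, 0.75) == int(np.floor(0.75 * n + 0.5))
            assert training_count(n, 2 / 3) == int(np.floor(n * 2 / 3 + 0.5))

    def test_deterministic_and_partitioning(self):
        rng = np.random.default_rng(4)
        X = rng.random((50, 1))
        labels = ["pathogenic"] * 35 + ["benign"] * 15
        t = make_normalized_table(X, labels=labels, predictors=["REVEL"])
        a1, b1 = split_train_validation(t, seed=7)
        a2, b2 = split_train_validation(t, seed=7)
        assert a1.df.equals(a2.df) and b1.df.equals(b2.df)
        # union is the dataset, intersection empty
        key = lambda df: set(zip(df["position"], df["alt"], df["REVEL"]))
        assert key(a1.df) | key(b1.df) == key(t.df)
        assert not key(a1.df) & key(b1.df)

    def test_tiny_class_errors(self):
        t = labeled_table([0.9, 0.8], [0.1])
        with pytest.raises(ValueError, match="benign"):
            split_train_validation(t, seed=0)


class TestConfusion:
    def test_training_sensitivity_worked_example(self):
        r = metrics_from_counts(ConfusionCounts(tp=440, fn=16, tn=40, fp=1))
        assert round_half_up(r.sensitivity) == 96.5

    def test_validation_specificity_worked_example(self):
        r = metrics_from_counts(ConfusionCounts(tp=149, fn=4, tn=20, fp=0))
        assert round_half_up(r.specificity) == 100.0
        assert round_half_up(r.sensitivity) == 97.4

    def test_perfect_classifier_f0(self):
        r = confusion_metrics(
            ["pathogenic", "benign"], ["pathogenic", "benign"]
        )
        assert r.f0 == 1.0

    def test_empty_class_errors(self):
        with pytest.raises(ValueError, match="pathogenic"):
            confusion_metrics(["benign"], ["benign"])
        with pytest.raises(ValueError, match="benign"):
            confusion_metrics(["pathogenic"], ["pathogenic"])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_metrics(["benign"], ["benign", "pathogenic"])


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.1, 0.2], ["pathogenic", "pathogenic", "benign", "benign"]) == 100.0

    def test_constant_scores_are_chance(self):
        assert auroc([0.5] * 6, ["pathogenic"] * 3 + ["benign"] * 3) == 50.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auroc([0.5, 0.6], ["pathogenic", "pathogenic"])

    def test_matches_mann_whitney_on_random_small_sets(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(4, 51))
            n_pos = int(rng.integers(1, n))
            labels = ["pathogenic"] * n_pos + ["benign"] * (n - n_pos)
            # coarse grid forces plenty of ties
            scores = rng.integers(0, 6, size=n) / 5.0
            assert auroc(scores, labels) == pytest.approx(
                mann_whitney_auroc(scores, labels), abs=1e-9
            )


ONE_PREDICTOR_MODEL = EnsembleModel(weights={"REVEL": 1.0}, intercept=-0.5)


class TestBootstrap:
    def test_perfect_classifier_degenerate_ci(self):
        t = labeled_table([0.9, 0.95, 0.97, 0.8], [0.1, 0.2, 0.3])
        r = bootstrap_metrics(t, ONE_PREDICTOR_MODEL, n_boot=200, seed=1)
        assert r.ci95["sensitivity"] == (100.0, 100.0)
        assert r.ci95["specificity"] == (100.0, 100.0)

    def test_same_seed_reproduces_cis_bit_exactly(self):
        rng = np.random.default_rng(2)
        t = labeled_table(
            np.clip(rng.normal(0.7, 0.2, 40), 0, 1),
            np.clip(rng.normal(0.3, 0.2, 15), 0, 1),
        )
        a = bootstrap_metrics(t, ONE_PREDICTOR_MODEL, n_boot=300, seed=9)
        b = bootstrap_metrics(t, ONE_PREDICTOR_MODEL, n_boot=300, seed=9)
        assert a.ci95 == b.ci95
        c = bootstrap_metrics(t, ONE_PREDICTOR_MODEL, n_boot=300, seed=10)
        assert a.ci95 != c.ci95

    def test_interval_orientation(self):
        rng = np.random.default_rng(3)
        t = labeled_table(
            np.clip(rng.normal(0.65, 0.25, 60), 0, 1),
            np.clip(rng.normal(0.35, 0.25, 25), 0, 1),
        )
        r = bootstrap_metrics(t, ONE_PREDICTOR_MODEL, n_boot=500, seed=0)
        for lo, hi in r.ci95.values():
            assert lo <= hi

    def test_ci_brackets_point_estimate_in_most_replicates(self):
        # calibration: over replicate datasets, the 95% CI should contain
        # the full-sample point estimate nearly always
        hits = 0
        runs = 30
        for rep in range(runs):
            rng = np.random.default_rng(100 + rep)
            t = labeled_table(
                np.clip(rng.normal(0.7, 0.25, 50), 0, 1),
                np.clip(rng.normal(0.35, 0.25, 20), 0, 1),
            )
            r = bootstrap_metrics(t, ONE_PREDICTOR_MODEL, n_boot=300, seed=rep)
            lo, hi = r.ci95["sensitivity"]
            hits += lo - 1e-9 <= r.sensitivity <= hi + 1e-9
        assert hits / runs >= 0.9


class TestConcordance:
    def test_all_correct(self):
        m = pd.DataFrame(True, index=range(8), columns=PREDICTORS)
        c = concordance_counts(m)
        assert c["levels"][6] == 8
        assert sum(c["levels"].values()) == 8

    def test_histogram_matches_row_sums(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.random((5, 3)) > 0.4, columns=["a", "b", "c"])
        c = concordance_counts(m)
        expected = np.bincount(m.to_numpy().sum(axis=1), minlength=4)
        assert [c["levels"][k] for k in range(4)] == list(expected)
        assert c["per_predictor"]["a"] == int(m["a"].sum())

    def test_all_false_row_counts_at_level_zero(self):
        m = pd.DataFrame([[False, False], [True, True]], columns=["a", "b"])
        assert concordance_counts(m)["levels"][0] == 1

    def test_missing_cells_count_as_incorrect(self, caplog):
        m = pd.DataFrame([[True, np.nan]], columns=["a", "b"])
        with caplog.at_level("WARNING"):
            c = concordance_counts(m)
        assert c["levels"][1] == 1
        assert "missing" in caplog.text

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            concordance_counts(pd.DataFrame())


class TestPerDomain:
    DOMAINS = DomainAnnotation.from_dict(
        {
            "protein_length": 100,
            "domains": [
                {"name": "north", "start": 1, "end": 50},
                {"name": "south", "start": 51, "end": 90},
            ],
        }
    )

    def make_table(self):
        scores = [0.9, 0.8, 0.2, 0.95, 0.1, 0.3, 0.85, 0.4]
        labels = [
            "pathogenic", "pathogenic", "benign", "pathogenic",
            "benign", "benign", "pathogenic", "pathogenic",
        ]
        positions = [5, 10, 20, 60, 70, 80, 95, 96]
        X = np.array(scores).reshape(-1, 1)
        return make_normalized_table(
            X, labels=labels, positions=positions, predictors=["REVEL"]
        )

    def test_hand_tallied_fixture(self):
        out = per_domain_metrics(self.make_table(), ONE_PREDICTOR_MODEL, self.DOMAINS)
        north = out["north"]  # path 0.9,0.8 called path; benign 0.2 called benign
        assert north["sensitivity"] == 100.0
        assert north["specificity"] == 100.0
        south = out["south"]  # path 0.95 correct; benign 0.1,0.3 correct
        assert south["sensitivity"] == 100.0
        assert south["specificity"] == 100.0
        un = out["unassigned"]  # positions 95,96: path 0.85 correct, 0.4 wrong
        assert un["sensitivity"] == 50.0
        assert un["specificity"] is None  # no benign variants there

    def test_partition_conserves_counts(self):
        t = self.make_table()
        out = per_domain_metrics(t, ONE_PREDICTOR_MODEL, self.DOMAINS)
        total_correct = sum(
            d["correct_pathogenic"] + d["correct_benign"] for d in out.values()
        )
        whole = confusion_metrics(
            (t.scores().to_numpy()[:, 0] >= 0.5), t.labels.to_numpy()
        )
        assert total_correct == whole.counts.tp + whole.counts.tn
        assert sum(d["n_pathogenic"] + d["n_benign"] for d in out.values()) == len(t)
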