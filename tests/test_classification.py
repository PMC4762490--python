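import numpy as np
import pytest

from cervidct import (
    InputError,
    ParameterError,
    confusion_report,
    grid_search,
    loocv,
    predict,
    rank_variables,
    simulate_cohort,
    train,
)
from cervidct.classification import LABEL_CONVENTION
from cervidct.io_formats import BIOMARKERS, FeatureTable
from conftest import separable_table


class TestTrainPredict:
    def test_separable_blobs_fit_perfectly(self):
        table = separable_table()
        model = train(table, c=1.0, gamma=0.1)
        labels, h = predict(model, table)
        assert (labels == table.species).all()
        assert ((h > 0) == (table.species == "red_deer")).all()

    def test_duplicated_rows_leave_decision_function_unchanged(self):
        import pandas as pd
        table = separable_table(n_per_class=6, seed=3)
        doubled = FeatureTable(pd.concat(
            [table.df, table.df.assign(sample_id=table.df.sample_id + "_b")],
            ignore_index=True))
        m1 = train(table, c=4.0, gamma=0.05)
        m2 = train(doubled, c=4.0, gamma=0.05)
        rng = np.random.default_rng(0)
        probe = rng.normal(5, 10, size=(20, 6))
        assert np.allclose(predict(m1, probe)[1], predict(m2, probe)[1], atol=1e-8)

    def test_small_c_degrades_training_accuracy_on_noisy_data(self, modern_moments):
        table = simulate_cohort(modern_moments, n_per_species=25, seed=5)
        accs = []
        for c in (2.0**-8, 1.0, 2.0**8):
            model = train(table, c=c, gamma=0.5)
            labels, _ = predict(model, table)
            accs.append((labels == table.species).mean())
        assert accs[0] <= accs[1] <= accs[2]

    def test_single_class_training_rejected(self):
        table = separable_table(n_per_class=5)
        only = table.subset(table.species == "red_deer")
        with pytest.raises(ParameterError):
            train(only, 1.0, 0.1)

    def test_midpoint_of_symmetric_pair_sits_on_boundary(self):
        import pandas as pd
        rows = []
        for sp, v in (("red_deer", 1.0), ("reindeer", -1.0)):
            for i in range(2):
                x = np.full(6, v)
                rows.append({"sample_id": f"{sp}{i}", "species": sp,
                             "corpus": "synthetic", "anatomical_location": "",
                             "bv_tv": 50 + 10 * v, "tb_n": 3 + v,
                             "tb_th": 0.2 + 0.05 * v, "tb_sp": 0.2 - 0.05 * v,
                             "tb_pf": v, "smi": v})
        table = FeatureTable(pd.DataFrame.from_records(rows))
        model = train(table, c=10.0, gamma=0.3)
        mid = table.matrix().mean(axis=0)
        _, h = predict(model, mid)
        assert abs(h[0]) < 1e-6

    def test_missing_biomarker_named(self):
        table = separable_table(n_per_class=4)
        model = train(table, 1.0, 0.1)
        with pytest.raises(InputError, match="smi"):
            predict(model, table.df.drop(columns=["smi"]))

    def test_modern_rule_collapses_on_archaeological_cohort(
            self, modern_moments, archaeological_moments):
        """The modern decision rule misreads archaeological reindeer: their
        coarser mesh (lower Tb.N, wider Tb.Sp) looks like modern red deer,
        so predictions skew heavily toward red_deer."""
        modern = simulate_cohort(modern_moments, seed=21)
        arch = simulate_cohort(archaeological_moments, seed=22)
        gs = grid_search(modern)
        model = train(modern, gs.c, gs.gamma)
        labels, _ = predict(model, arch)
        frac_red = (labels == "red_deer").mean()
        assert frac_red > 0.6
        reindeer_rows = arch.species == "reindeer"
        assert (labels[reindeer_rows] == "red_deer").mean() > 0.5


class TestLOOCV:
    def test_separable_data_perfect(self):
        cm = loocv(separable_table(), c=1.0, gamma=0.1)
        assert cm.overall_percent == 100.0
        assert np.trace(cm.counts) == cm.total

    def test_minimum_n_three_runs(self):
        import pandas as pd
        table = separable_table(n_per_class=5)
        tiny = FeatureTable(pd.concat([
            table.df[table.df.species == "red_deer"].head(2),
            table.df[table.df.species == "reindeer"].head(1)],
            ignore_index=True))
        cm = loocv(tiny, 1.0, 0.1)
        assert cm.total == 3
        # the lone reindeer's fold collapses to one class
        assert cm.fold_errors

    def test_equals_train_without_sample_then_predict(self, modern_moments):
        """The held-out row must never influence its own fold (scaler refit
        on the remaining rows only)."""
        table = simulate_cohort(modern_moments, n_per_species=8, seed=13)
        cm = loocv(table, c=2.0, gamma=0.25)
        preds = []
        x = table.matrix()
        for i in range(len(table)):
            sub = table.subset(np.arange(len(table)) != i)
            model = train(sub, c=2.0, gamma=0.25)
            preds.append(predict(model, x[i])[0][0])
        assert confusion_report(table.species, preds).counts.tolist() == \
            cm.counts.tolist()

    def test_permuted_labels_score_near_chance(self, modern_moments):
        rng = np.random.default_rng(99)
        table = simulate_cohort(modern_moments, seed=0)
        accs = []
        for _ in range(30):
            df = table.df.copy()
            df["species"] = rng.permutation(df["species"].to_numpy())
            cm = loocv(FeatureTable(df), c=1.0, gamma=0.125)
            accs.append(cm.accuracy)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.1)


class TestGridSearch:
    def test_selected_accuracy_is_grid_maximum(self, modern_moments):
        table = simulate_cohort(modern_moments, n_per_species=10, seed=7)
        gs = grid_search(table, c_powers=range(-2, 3), gamma_powers=range(-6, -1))
        assert gs.best_accuracy == gs.accuracy.max()
        ci = gs.c_powers.index(int(np.log2(gs.c)))
        gi = gs.gamma_powers.index(int(np.log2(gs.gamma)))
        assert gs.accuracy[ci, gi] == gs.best_accuracy

    def test_tie_break_prefers_smallest_c_then_gamma(self):
        table = separable_table()
        gs = grid_search(table, c_powers=range(0, 4), gamma_powers=range(-6, -2))
        assert gs.best_accuracy == 1.0
        assert (gs.c, gs.gamma) == min(gs.ties)

    def test_single_point_grid(self, toy_table):
        gs = grid_search(toy_table, c_powers=[1], gamma_powers=[-2])
        assert (gs.c, gs.gamma) == (2.0, 0.25)

    def test_fast_path_matches_reference_loocv(self, modern_moments):
        table = simulate_cohort(modern_moments, n_per_species=9, seed=17)
        gs = grid_search(table, c_powers=[-3, 0, 5], gamma_powers=[-8, -3, 0])
        for ci, cp in enumerate(gs.c_powers):
            for gi, gp in enumerate(gs.gamma_powers):
                cm = loocv(table, 2.0**cp, 2.0**gp)
                assert gs.accuracy[ci, gi] == pytest.approx(cm.accuracy), (cp, gp)


class TestRankVariables:
    @staticmethod
    def _informative_table(seed, duplicate=False):
        import pandas as pd
        rng = np.random.default_rng(seed)
        rows = []
        for sp, mu in (("red_deer", 3.0), ("reindeer", 6.0)):
            for i in range(20):
                noise = rng.normal(size=6)
                x = dict(zip(BIOMARKERS, noise))
                x["tb_n"] = abs(mu + rng.normal(scale=0.5))  # informative
                if duplicate:
                    x["tb_sp"] = x["tb_n"] + rng.normal(scale=0.01)
                x["bv_tv"] = abs(x["bv_tv"]) + 50
                x["tb_th"] = abs(x["tb_th"])
                x["tb_sp"] = abs(x["tb_sp"])
                rows.append({"sample_id": f"{sp}{i}", "species": sp,
                             "corpus": "synthetic", "anatomical_location": "", **x})
        return FeatureTable(pd.DataFrame.from_records(rows))

    def test_informative_feature_ranked_first(self):
        hits = sum(
            rank_variables(self._informative_table(seed))[0] == "tb_n"
            for seed in range(100)
        )
        assert hits >= 95

    def test_duplicated_informative_pair_occupies_top_ranks(self):
        top_pairs = 0
        for seed in range(20):
            ranking = rank_variables(self._informative_table(seed, duplicate=True))
            if set(ranking[:2]) == {"tb_n", "tb_sp"}:
                top_pairs += 1
        assert top_pairs >= 18

    def test_deterministic(self, modern_cohort):
        assert rank_variables(modern_cohort) == rank_variables(modern_cohort)


class TestConfusionReport:
    def test_modern_corpus_printed_counts(self):
        # 11/6 red deer rows, 1/21 reindeer rows
        true = ["red_deer"] * 17 + ["reindeer"] * 22
        pred = (["red_deer"] * 11 + ["reindeer"] * 6
                + ["red_deer"] * 1 + ["reindeer"] * 21)
        cm = confusion_report(true, pred)
        assert cm.counts.tolist() == [[11, 6], [1, 21]]
        assert cm.per_class_percent == {"red_deer": 64.7, "reindeer": 95.4}
        assert cm.overall_percent == 82.0

    def test_archaeological_corpus_printed_counts(self):
        true = ["red_deer"] * 23 + ["reindeer"] * 27
        pred = ["red_deer"] * 23 + ["red_deer"] * 2 + ["reindeer"] * 25
        cm = confusion_report(true, pred)
        assert cm.overall_percent == 96.0

    def test_transfer_failure_printed_counts(self):
        true = ["red_deer"] * 23 + ["reindeer"] * 27
        pred = (["red_deer"] * 18 + ["reindeer"] * 5
                + ["red_deer"] * 24 + ["reindeer"] * 3)
        cm = confusion_report(true, pred)
        assert cm.per_class_percent == {"red_deer": 78.2, "reindeer": 11.1}
        assert cm.overall_percent == 42.0

    def test_all_correct_is_100_everywhere(self):
        labels = ["red_deer", "reindeer"] * 4
        cm = confusion_report(labels, labels)
        assert cm.overall_percent == 100.0
        assert set(cm.per_class_percent.values()) == {100.0}

    def test_unknown_label_rejected(self):
        with pytest.raises(InputError):
            confusion_report(["red_deer", "moose"], ["red_deer", "red_deer"])

    def test_row_sums_match_per_species_counts(self):
        rng = np.random.default_rng(0)
        true = rng.choice(LABEL_CONVENTION, size=40)
        pred = rng.choice(LABEL_CONVENTION, size=40)
        cm = confusion_report(true, pred)
        assert cm.counts[0].sum() == (true == "red_deer").sum()
        assert cm.counts[1].sum() == (true == "reindeer").sum()
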