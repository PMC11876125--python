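"""Block medians and the Gaussian-mixture peak fit."""

import numpy as np
import pytest
from sklearn.mixture import GaussianMixture

from paleoks.formats import CollinearBlock, SpeciesMeta
from paleoks.peaks import (
    BlockMedianSet,
    PeakFitError,
    assign_events,
    block_medians,
    fit_peak_model,
)


def _blocks_and_table(ks_table_factory, block_values, species="sp"):
    blocks, rows = [], []
    for i, values in enumerate(block_values):
        pairs = []
        for j, v in enumerate(values):
            a, b = f"g{i}_{j}a", f"g{i}_{j}b"
            pairs.append((a, b))
            rows.append((species, f"b{i}", a, b, v))
        blocks.append(CollinearBlock(f"b{i}", species, pairs))
    return blocks, ks_table_factory(rows)


class TestBlockMedians:
    def test_odd_and_even_median_rules(self, ks_table_factory):
        blocks, ks = _blocks_and_table(
            ks_table_factory, [[1, 2, 3], [1, 2, 3, 4]]
        )
        result = block_medians(blocks, ks, min_pairs=3, window=(0.0, 10.0))
        assert result.n_blocks_used == 2
        # median of 3 values / mean of the two central values for 4
        assert sorted(result.medians) == [2.0, 2.5]

    def test_window_and_min_pairs_filtering(self, ks_table_factory):
        blocks, ks = _blocks_and_table(
            ks_table_factory,
            [[0.01, 1.0, 1.2, 1.4, 5.0], [1.0, 1.1, 1.2, 1.3, 1.4]],
        )
        # first block keeps only 3 in-window values -> dropped at min_pairs=5
        result = block_medians(blocks, ks, min_pairs=5, window=(0.05, 4.0))
        assert result.n_blocks_used == 1
        assert result.medians[0] == 1.2

    def test_missing_pairs_warn_and_zero_blocks_error(self, ks_table_factory):
        blocks, ks = _blocks_and_table(ks_table_factory, [[1.0, 1.1]])
        blocks[0].pairs.append(("zz1", "zz2"))  # pair absent from the table
        with pytest.warns(UserWarning, match="no Ks value"):
            result = block_medians(blocks, ks, min_pairs=2, window=(0.0, 4.0))
        assert result.n_blocks_used == 1
        with pytest.warns(UserWarning), pytest.raises(PeakFitError):
            block_medians(blocks, ks, min_pairs=3, window=(0.0, 4.0))

    def test_matches_sort_based_oracle_on_random_blocks(self, ks_table_factory):
        rng = np.random.default_rng(42)
        values = [list(rng.uniform(0.1, 3.9, size=rng.integers(5, 12)))
                  for _ in range(30)]
        blocks, ks = _blocks_and_table(ks_table_factory, values)
        result = block_medians(blocks, ks, min_pairs=5, window=(0.05, 4.0))

        def sort_median(vs):  # independent: sort, take middle / mean of two
            s = sorted(vs)
            n = len(s)
            return s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])

        expected = [sort_median(v) for v in values]
        np.testing.assert_allclose(sorted(result.medians), sorted(expected))


def _median_set(values):
    return BlockMedianSet(
        species="sp",
        medians=np.asarray(values, dtype=float),
        filter_window=(0.05, 4.0),
        min_pairs=5,
    )


class TestMixtureFit:
    def test_single_component_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1.6, 0.2, size=200)
        model = fit_peak_model(_median_set(x), n_components=1, seed=0)
        c = model.components[0]
        assert c.mu == pytest.approx(np.mean(x), abs=1e-9)
        assert c.sigma == pytest.approx(np.std(x), abs=1e-9)
        assert c.weight == pytest.approx(1.0)

    def test_single_peak_recovery(self):
        rng = np.random.default_rng(7)
        x = rng.normal(1.6, 0.2, size=1000)
        model = fit_peak_model(_median_set(x), n_components=1, seed=7)
        assert abs(model.components[0].mu - 1.6) <= 0.02

    def test_two_component_recovery(self):
        rng = np.random.default_rng(13)
        x = np.concatenate(
            [rng.normal(0.4, 0.1, 1000), rng.normal(1.6, 0.1, 1000)]
        )
        model = fit_peak_model(_median_set(x), n_components=2, seed=13)
        mus = [c.mu for c in model.components]
        weights = [c.weight for c in model.components]
        assert abs(mus[0] - 0.4) <= 0.03 and abs(mus[1] - 1.6) <= 0.03
        assert abs(weights[0] - 0.5) <= 0.05

    def test_weights_sum_to_one_and_ll_non_decreasing(self):
        rng = np.random.default_rng(5)
        x = np.concatenate(
            [rng.normal(0.5, 0.15, 400), rng.normal(1.7, 0.2, 600)]
        )
        model = fit_peak_model(_median_set(x), n_components=2, seed=5)
        assert sum(c.weight for c in model.components) == pytest.approx(
            1.0, abs=1e-6
        )
        diffs = np.diff(model.ll_trace)
        assert (diffs >= -1e-8).all()

    def test_components_sorted_by_mu(self):
        rng = np.random.default_rng(3)
        x = np.concatenate(
            [rng.normal(1.8, 0.1, 500), rng.normal(0.4, 0.1, 500)]
        )
        model = fit_peak_model(_median_set(x), n_components=2, seed=3)
        mus = [c.mu for c in model.components]
        assert mus == sorted(mus)

    def test_matches_sklearn_mixture(self):
        """Cross-check the hand EM against sklearn on the same data."""
        rng = np.random.default_rng(21)
        x = np.concatenate(
            [rng.normal(0.4, 0.1, 800), rng.normal(1.6, 0.12, 800)]
        )
        model = fit_peak_model(_median_set(x), n_components=2, seed=21)
        gm = GaussianMixture(
            n_components=2,
            means_init=[[0.4], [1.6]],
            tol=1e-8,
            max_iter=500,
            random_state=0,
        ).fit(x.reshape(-1, 1))
        sk_mus = sorted(gm.means_.ravel())
        for ours, theirs in zip([c.mu for c in model.components], sk_mus):
            assert ours == pytest.approx(theirs, abs=0.01)

    def test_too_few_medians_rejected(self):
        with pytest.raises(PeakFitError, match="too few"):
            fit_peak_model(_median_set(np.ones(15) * 1.2), n_components=2)

    def test_degenerate_data_errors_after_refit(self):
        x = np.full(40, 1.5)  # zero spread: sigma collapses below the floor
        with pytest.raises(PeakFitError, match="degenerate"):
            fit_peak_model(_median_set(x), n_components=2, seed=1)

    def test_replicate_recovery_error_bound(self):
        """Mean absolute error of both recovered means stays within 0.03
        over 20 seeded replicates of the two-peak scenario."""
        errs_low, errs_high = [], []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            x = np.concatenate(
                [rng.normal(0.4, 0.1, 1000), rng.normal(1.6, 0.1, 1000)]
            )
            model = fit_peak_model(_median_set(x), n_components=2, seed=seed)
            errs_low.append(abs(model.components[0].mu - 0.4))
            errs_high.append(abs(model.components[1].mu - 1.6))
        assert np.mean(errs_low) <= 0.03
        assert np.mean(errs_high) <= 0.03


class TestEventAssignment:
    def test_single_round_species(self):
        rng = np.random.default_rng(2)
        model = fit_peak_model(
            _median_set(rng.normal(1.6, 0.1, 100)), n_components=1
        )
        model = assign_events(model, SpeciesMeta("vitis", 1, True))
        assert model.event_labels == {"ceWGT": 0}
        assert model.peak("ceWGT") == model.components[0].mu

    def test_two_round_species_orders_old_first(self):
        rng = np.random.default_rng(2)
        x = np.concatenate(
            [rng.normal(0.3, 0.05, 300), rng.normal(1.6, 0.1, 300)]
        )
        model = fit_peak_model(_median_set(x), n_components=2)
        model = assign_events(model, SpeciesMeta("mango", 2))
        assert model.peak("ceWGT") > model.peak("WGD_1")

    def test_component_round_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        model = fit_peak_model(
            _median_set(rng.normal(1.6, 0.1, 100)), n_components=1
        )
        with pytest.raises(PeakFitError, match="rounds"):
            assign_events(model, SpeciesMeta("mango", 2))

    def test_labels_match_simulation_truth(self, small_dataset):
        from paleoks.pipeline import PipelineConfig, fit_all_species

        models = fit_all_species(
            small_dataset.blocks,
            small_dataset.ks,
            small_dataset.meta,
            PipelineConfig(seed=11),
        )
        truth = small_dataset.truth["species"]
        for model in models:
            events = truth[model.species]["events"]
            assert abs(model.peak("ceWGT") - events["ceWGT"]["true_mu"]) < 0.05
            if "WGD" in events:
                assert abs(
                    model.peak("WGD_1") - events["WGD"]["true_mu"]
                ) < 0.05
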