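"""End-to-end pipeline: planted coherence, plaid composition, determinism."""

import itertools

import numpy as np
import pytest

from tricgen import (
    GeneratorConfig,
    PlaidCoherency,
    compose_plaid,
    generate,
    reconstruct_block,
    write_dataset,
    write_solution,
)
from conftest import small_config


def _degraded_flat(dataset):
    return set(
        int(c)
        for c in np.concatenate(
            [dataset.missing_cells, dataset.noise_cells, dataset.error_cells]
        )
    )


def _membership(t, i, j, k):
    if i in t.rows and j in t.cols and k in t.ctxs:
        return (t.rows.index(i), t.cols.index(j), t.ctxs.index(k))
    return None


class TestPlantedCoherence:
    @pytest.mark.parametrize("dtype", ["real", "integer"])
    def test_clean_numeric_blocks_match_their_compact_model(self, dtype):
        cfg = GeneratorConfig.model_validate(small_config(
            dataset={"dtype": dtype, "dims": [15, 12, 8],
                     "alphabet": {"min": 0, "max": 100},
                     "background": {"family": "uniform"}},
        ))
        res = generate(cfg, seed=11)
        assert not res.warnings
        for t in res.dataset.triclusters:
            block = reconstruct_block(t)
            got = res.dataset.values[np.ix_(t.rows, t.cols, t.ctxs)]
            assert np.array_equal(got, block)

    def test_clean_symbolic_blocks_match_their_seeds(self):
        cfg = GeneratorConfig.model_validate(small_config(
            dataset={"dtype": "symbolic", "dims": [15, 12, 8],
                     "alphabet": {"symbols": ["a", "b", "c", "d"]}},
        ))
        res = generate(cfg, seed=13)
        for t in res.dataset.triclusters:
            got = res.dataset.values[np.ix_(t.rows, t.cols, t.ctxs)]
            assert np.array_equal(got, reconstruct_block(t))

    def test_all_values_in_alphabet_after_generation(self):
        cfg = GeneratorConfig.model_validate(small_config())
        res = generate(cfg, seed=17)
        vals = res.dataset.values
        assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 50
        assert np.array_equal(vals[~np.isnan(vals)], np.rint(vals[~np.isnan(vals)]))


class TestPlaidComposition:
    @pytest.mark.parametrize(
        "plaid", [PlaidCoherency.ADDITIVE, PlaidCoherency.MULTIPLICATIVE,
                  PlaidCoherency.INTERPOLED]
    )
    def test_overlap_cells_equal_composed_contributions(self, plaid):
        cfg = GeneratorConfig.model_validate(small_config(
            dataset={"dtype": "real", "dims": [20, 15, 10],
                     "alphabet": {"min": -100, "max": 100},
                     "background": {"family": "uniform"}},
            triclusters={"n": 4,
                         "rows": {"dist": "uniform", "a": 3, "b": 4},
                         "cols": {"dist": "uniform", "a": 3, "b": 3},
                         "ctxs": {"dist": "uniform", "a": 2, "b": 3},
                         "patterns": "constant"},
            overlap={"plaid": plaid.value, "pct_triclusters": 100,
                     "max_group_size": 2, "pct_elements": 60},
        ))
        res = generate(cfg, seed=23)
        trics = res.dataset.triclusters
        blocks = {t.id: reconstruct_block(t) for t in trics}
        checked = 0
        for a, b in itertools.combinations(trics, 2):
            shared = (
                set(a.cells()) & set(b.cells())
            )
            for i, j, k in shared:
                contributions = []
                for t in trics:
                    loc = _membership(t, i, j, k)
                    if loc is not None:
                        contributions.append(float(blocks[t.id][loc]))
                expected = np.clip(compose_plaid(contributions, plaid), -100, 100)
                assert res.dataset.values[i, j, k] == pytest.approx(expected)
                checked += 1
        assert checked > 0  # the plan must have produced real overlaps

    def test_plaid_none_keeps_last_generated_value(self):
        cfg = GeneratorConfig.model_validate(small_config(
            triclusters={"n": 2,
                         "rows": {"dist": "uniform", "a": 3, "b": 3},
                         "cols": {"dist": "uniform", "a": 3, "b": 3},
                         "ctxs": {"dist": "uniform", "a": 2, "b": 2},
                         "patterns": "constant"},
            overlap={"plaid": "none", "pct_triclusters": 100,
                     "max_group_size": 2, "pct_elements": 50},
        ))
        res = generate(cfg, seed=29)
        t_last = res.dataset.triclusters[-1]
        shared = set(res.dataset.triclusters[0].cells()) & set(t_last.cells())
        assert shared
        block = reconstruct_block(t_last)
        for i, j, k in shared:
            assert res.dataset.values[i, j, k] == block[_membership(t_last, i, j, k)]


class TestDeterminism:
    def test_same_seed_same_files(self, tmp_path):
        cfg = GeneratorConfig.model_validate(small_config(
            quality={"missing_background": 10, "noise_background": 5,
                     "error_background": 2, "missing_triclusters": 20,
                     "noise_triclusters": 10, "error_triclusters": 5,
                     "noise_deviation": 2},
        ))

        def run(stem):
            res = generate(cfg, seed=31)
            write_dataset(res.dataset, stem)
            write_solution(res.report, stem)
            return [
                (tmp_path / f"{stem.name}{sfx}").read_bytes()
                for sfx in ("_data.tsv", "_trics.json", "_trics.txt")
            ]

        assert run(tmp_path / "a") == [
            b for b in run(tmp_path / "b")
        ]

    def test_different_seeds_differ(self):
        cfg = GeneratorConfig.model_validate(small_config())
        a = generate(cfg, seed=1).dataset.values
        b = generate(cfg, seed=2).dataset.values
        assert not np.array_equal(a, b, equal_nan=True)

    def test_quality_stage_is_last_clean_grid_reproducible(self):
        # same seed with quality zeroed reproduces the pre-degradation grid
        noisy = GeneratorConfig.model_validate(small_config(
            quality={"missing_background": 30, "noise_background": 20,
                     "error_background": 10, "noise_deviation": 3},
        ))
        clean = GeneratorConfig.model_validate(small_config())
        res_noisy = generate(noisy, seed=37)
        res_clean = generate(clean, seed=37)
        degraded = _degraded_flat(res_noisy.dataset)
        flat_noisy = res_noisy.dataset.values.reshape(-1)
        flat_clean = res_clean.dataset.values.reshape(-1)
        untouched = [x for x in range(flat_noisy.size) if x not in degraded]
        assert np.array_equal(flat_noisy[untouched], flat_clean[untouched])
        # missing cells went missing, noisy cells changed within the deviation
        assert np.all(np.isnan(flat_noisy[res_noisy.dataset.missing_cells]))
        noised = flat_noisy[res_noisy.dataset.noise_cells]
        original = flat_clean[res_noisy.dataset.noise_cells]
        assert np.all(noised != original)
        assert np.all(np.abs(noised - original) <= 3)


class TestQualityBookkeeping:
    def test_report_percentages_match_recorded_counts(self):
        cfg = GeneratorConfig.model_validate(small_config(
            quality={"missing_triclusters": 50, "noise_triclusters": 25,
                     "noise_deviation": 2},
        ))
        res = generate(cfg, seed=41)
        for t, tr in zip(res.dataset.triclusters, res.report.triclusters):
            n_m, n_n, n_e = t.quality_counts
            assert tr.pct_missing == pytest.approx(100 * n_m / t.volume)
            assert tr.pct_noise == pytest.approx(100 * n_n / t.volume)
            assert tr.pct_errors == pytest.approx(100 * n_e / t.volume)

    def test_noise_respects_deviation_errors_exceed_it(self):
        cfg = GeneratorConfig.model_validate(small_config(
            quality={"noise_background": 20, "error_background": 10,
                     "noise_triclusters": 25, "error_triclusters": 25,
                     "noise_deviation": 3},
        ))
        res_noisy = generate(cfg, seed=43)
        res_clean = generate(GeneratorConfig.model_validate(small_config()), seed=43)
        flat_noisy = res_noisy.dataset.values.reshape(-1)
        flat_clean = res_clean.dataset.values.reshape(-1)
        for c in res_noisy.dataset.noise_cells:
            assert 0 < abs(flat_noisy[c] - flat_clean[c]) <= 3
        bg = set(int(x) for x in res_noisy.dataset.error_cells)
        tric_cells = set()
        for t in res_noisy.dataset.triclusters:
            for i, j, k in t.cells():
                tric_cells.add((i * 10 + j) * 6 + k)
        for c in bg & tric_cells:  # tricluster-scope errors: beyond the deviation
            assert abs(flat_noisy[c] - flat_clean[c]) > 3
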