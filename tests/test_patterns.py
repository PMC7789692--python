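"""Pattern-triple admissibility and coherence-exact value synthesis."""

import itertools

import numpy as np
import pytest

from tricgen import (
    Alphabet,
    BackgroundSpec,
    ConfigError,
    Pattern,
    PatternTriple,
    TemporalProfile,
    admissible_triples,
    build_numeric,
    build_order_preserving,
    build_symbolic,
    validate_triple,
)

OP, C, A, M, N = (
    Pattern.ORDER_PRESERVING,
    Pattern.CONSTANT,
    Pattern.ADDITIVE,
    Pattern.MULTIPLICATIVE,
    Pattern.NONE,
)


def _rule_oracle(ps, dataset_type):
    """Independent brute-force evaluation of the textual admissibility rules."""
    n_op = sum(p is OP for p in ps)
    if n_op >= 1:
        return n_op == 1 and all(p in (OP, N) for p in ps)
    if A in ps and M in ps:
        return False
    if dataset_type == "symbolic" and (A in ps or M in ps):
        return False
    if N in ps and (A in ps or M in ps):
        return False
    return not all(p is N for p in ps)


class TestValidateTriple:
    @pytest.mark.parametrize(
        "triple, dtype, ok",
        [
            ((OP, N, N), "symbolic", True),
            ((A, A, C), "symbolic", False),
            ((A, M, C), "real", False),
            ((C, C, C), "integer", True),
            ((N, N, N), "real", False),
            ((OP, C, N), "real", False),
            ((A, N, C), "real", False),
        ],
    )
    def test_known_triples(self, triple, dtype, ok):
        result = validate_triple(PatternTriple(*triple), dtype)
        assert (result is None) is ok

    @pytest.mark.parametrize("dtype, expected", [("real", 24), ("integer", 24), ("symbolic", 10)])
    def test_accept_set_equals_rule_oracle_on_all_125_triples(self, dtype, expected):
        accepted = []
        for ps in itertools.product(Pattern, repeat=3):
            ok = validate_triple(PatternTriple(*ps), dtype) is None
            assert ok == _rule_oracle(ps, dtype), ps
            if ok:
                accepted.append(ps)
        assert len(accepted) == expected
        assert [t.patterns for t in admissible_triples(dtype)] == accepted

    def test_violation_names_the_broken_rule(self):
        v = validate_triple(PatternTriple(A, M, C), "real")
        assert v.rule == "additive-multiplicative-exclusive"


class TestBuildNumeric:
    def test_all_constant_triple_yields_constant_block(self, real_alphabet, rng):
        c, a, b, g = build_numeric(PatternTriple(C, C, C), (3, 4, 2), real_alphabet, rng)
        assert np.all(a == 0) and np.all(b == 0) and np.all(g == 0)
        assert -100 <= c <= 100

    def test_additive_block_follows_the_additive_model(self, real_alphabet, rng):
        # explicitly evaluate c + alpha_i + beta_j + gamma_k against known factors
        t = PatternTriple(C, A, A)
        c, alpha, beta, gamma = 1.0, np.zeros(3), np.array([1.0, 2, 3]), np.array([2.0, -1, 6])
        assert c + alpha[0] + beta[1] + gamma[1] == 2.0  # oracle sanity
        cs, a_, b_, g_ = build_numeric(t, (3, 3, 3), real_alphabet, rng)
        assert np.all(a_ == 0)  # constant rows
        block = cs + a_[:, None, None] + b_[None, :, None] + g_[None, None, :]
        assert block.min() >= -100 - 1e-9 and block.max() <= 100 + 1e-9

    @pytest.mark.parametrize("seed", range(20))
    def test_multiplicative_block_stays_inside_alphabet(self, seed):
        alpha = Alphabet(kind="real", min_value=0, max_value=100)
        rng = np.random.default_rng(seed)
        c, a, b, g = build_numeric(
            PatternTriple(M, M, M), (4, 3, 2), alpha, rng
        )
        block = c * a[:, None, None] * b[None, :, None] * g[None, None, :]
        assert block.max() <= 100 + 1e-9 and block.min() >= -1e-9

    def test_integer_alphabet_gives_integer_seed_and_factors(self, integer_alphabet, rng):
        c, a, b, g = build_numeric(PatternTriple(A, A, A), (3, 3, 3), integer_alphabet, rng)
        for arr in (np.array([c]), a, b, g):
            assert np.all(arr == np.rint(arr))

    def test_narrow_alphabet_falls_back_to_constant_factors(self, rng):
        binary = Alphabet(kind="integer", min_value=0, max_value=1)
        c, a, b, g = build_numeric(PatternTriple(A, A, A), (5, 5, 5), binary, rng)
        block = c + a[:, None, None] + b[None, :, None] + g[None, None, :]
        assert set(np.unique(block)) <= {0.0, 1.0}

    def test_symbolic_alphabet_rejected(self, symbolic_alphabet, rng):
        with pytest.raises(ConfigError):
            build_numeric(PatternTriple(C, C, C), (2, 2, 2), symbolic_alphabet, rng)


class TestBuildSymbolic:
    def test_all_constant_fills_single_symbol(self, symbolic_alphabet, rng):
        tpl, seeds = build_symbolic(PatternTriple(C, C, C), (3, 4, 2), symbolic_alphabet, rng)
        assert seeds is None
        assert len(np.unique(tpl)) == 1

    def test_none_rows_constant_cols_ctxs_one_symbol_per_row(self, symbolic_alphabet, rng):
        tpl, seeds = build_symbolic(PatternTriple(N, C, C), (3, 4, 2), symbolic_alphabet, rng)
        assert seeds is None
        for r in range(3):
            assert len(np.unique(tpl[r])) == 1  # each row holds one symbol

    def test_none_context_yields_independent_constant_seeds(self, symbolic_alphabet, rng):
        tpl, seeds = build_symbolic(PatternTriple(C, C, N), (2, 3, 2), symbolic_alphabet, rng)
        assert tpl is None and len(seeds) == 2
        for s in seeds:
            assert len(np.unique(s)) == 1  # internally constant per context

    def test_constant_rows_one_symbol_per_column(self, symbolic_alphabet, rng):
        tpl, _ = build_symbolic(PatternTriple(C, N, C), (4, 3, 2), symbolic_alphabet, rng)
        for j in range(3):
            assert len(np.unique(tpl[:, j])) == 1


class TestBuildOrderPreserving:
    def test_single_row_is_sorted_in_permutation_order(self, real_alphabet):
        rng = np.random.default_rng(0)
        block, pi = build_order_preserving(
            (1, 3, 1), "cols", TemporalProfile.NA, real_alphabet, rng
        )
        assert sorted(pi) == [0, 1, 2]
        assert np.all(np.diff(block[0, pi, 0]) >= 0)

    def test_increasing_profile_is_identity_decreasing_is_reversal(self, real_alphabet, rng):
        _, pi_inc = build_order_preserving(
            (2, 2, 4), "ctxs", TemporalProfile.INCREASING, real_alphabet, rng
        )
        _, pi_dec = build_order_preserving(
            (2, 2, 4), "ctxs", TemporalProfile.DECREASING, real_alphabet, rng
        )
        assert np.array_equal(pi_inc, [0, 1, 2, 3])
        assert np.array_equal(pi_dec, [3, 2, 1, 0])

    @pytest.mark.parametrize("axis_name, axis", [("rows", 0), ("cols", 1), ("ctxs", 2)])
    def test_every_fiber_is_sorted_under_the_shared_permutation(
        self, axis_name, axis, real_alphabet
    ):
        rng = np.random.default_rng(3)
        dims = (3, 3, 2)
        block, pi = build_order_preserving(
            dims, axis_name, TemporalProfile.RANDOM, real_alphabet, rng
        )
        # brute-force check of all fibers along the ordered axis
        moved = np.moveaxis(block, axis, 0)
        for fiber in moved.reshape(dims[axis], -1).T:
            ordered = fiber[pi]
            assert np.all(np.diff(ordered) >= 0)

    def test_symbolic_op_uses_alphabet_ranks(self, symbolic_alphabet):
        rng = np.random.default_rng(5)
        block, pi = build_order_preserving(
            (2, 4, 2), "cols", TemporalProfile.RANDOM, symbolic_alphabet, rng,
            BackgroundSpec(family="discrete", probabilities=(0.1, 0.15, 0.3, 0.3, 0.15)),
        )
        assert set(np.unique(block)).issubset(set(range(5)))
        for i in range(2):
            for k in range(2):
                assert np.all(np.diff(block[i, pi, k]) >= 0)

    def test_singleton_op_dimension_is_degenerate_but_valid(self, real_alphabet, rng):
        block, pi = build_order_preserving(
            (2, 2, 1), "ctxs", TemporalProfile.RANDOM, real_alphabet, rng
        )
        assert block.shape == (2, 2, 1) and np.array_equal(pi, [0])
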