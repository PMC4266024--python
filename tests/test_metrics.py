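"""Rate codes, distances, DI, and the Fano factor, against brute-force oracles."""

import itertools

import numpy as np
import pytest

from spikedisc import (NetworkConfig, RateCode, compute_di,
                       discriminability_index, fano_factor,
                       inter_pattern_distance, intra_pattern_distance,
                       max_inter_distance, prototype_code, rate_code)
from spikedisc.metrics import code_thresholds, fano_factor_curve


def code(pid, *symbols):
    return RateCode(pid, tuple(symbols))


class TestRateCode:
    def test_band_arithmetic(self):
        # ratios (1.0, 0.9, 0.4, 0.1) -> symbols (2, 2, 1, 0)
        assert rate_code([40, 36, 16, 4], C=3).symbols == (2, 2, 1, 0)

    def test_equal_counts_all_top(self):
        assert rate_code([7, 7, 7], C=3).symbols == (2, 2, 2)

    def test_all_zero_counts_all_zero_code(self):
        assert rate_code([0, 0, 0], C=3).symbols == (0, 0, 0)

    def test_max_neuron_always_top_symbol(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.integers(0, 100, size=8)
            if counts.max() == 0:
                continue
            c = rate_code(counts, C=3)
            assert c.symbols[int(np.argmax(counts))] == 2

    def test_binary_code_thresholds(self):
        assert rate_code([10, 6, 4], C=2).symbols == (1, 1, 0)

    def test_threshold_table(self):
        assert code_thresholds(2).tolist() == [0.5]
        assert code_thresholds(3).tolist() == [0.4, 0.9]
        edges4 = code_thresholds(4)
        assert len(edges4) == 3 and edges4[-1] == pytest.approx(0.9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            rate_code([-1, 2], C=3)


class TestPrototype:
    def test_identical_codes(self, rng):
        codes = [code(1, 0, 1, 2)] * 5
        assert prototype_code(codes, rng).symbols == (0, 1, 2)

    def test_mode_wins(self, rng):
        codes = [code(1, 0, 0), code(1, 0, 0), code(1, 1, 1)]
        assert prototype_code(codes, rng).symbols == (0, 0)

    def test_no_repeats_uniform_choice(self):
        codes = [code(1, 0, 0), code(1, 1, 1), code(1, 2, 2)]
        rng = np.random.default_rng(0)
        seen = {prototype_code(codes, rng).symbols for _ in range(200)}
        assert seen == {(0, 0), (1, 1), (2, 2)}


class TestDistances:
    def test_identical_prototypes_zero(self):
        d, _ = inter_pattern_distance([code(1, 0, 1), code(2, 0, 1)])
        assert d == 0.0

    def test_fully_distinct_pair_equals_m(self):
        d, _ = inter_pattern_distance([code(1, 0, 0, 0), code(2, 1, 1, 1)])
        assert d == 3.0

    def test_three_pattern_example(self):
        # codes (0,0), (0,1), (1,1): per-neuron (2/3, 2/3), sum 4/3
        d, per = inter_pattern_distance([code(1, 0, 0), code(2, 0, 1), code(3, 1, 1)])
        assert per == pytest.approx([2 / 3, 2 / 3])
        assert d == pytest.approx(4 / 3)

    def test_inter_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            P, M, C = rng.integers(2, 6), rng.integers(1, 5), 3
            protos = [code(p, *rng.integers(0, C, M)) for p in range(P)]
            acc = 0.0
            for a, b in itertools.combinations(protos, 2):
                acc += sum(x != y for x, y in zip(a.symbols, b.symbols))
            oracle = acc / (P * (P - 1) / 2)
            d, _ = inter_pattern_distance(protos)
            assert d == pytest.approx(oracle)

    def test_intra_identical_is_zero(self):
        codes = {1: [code(1, 0, 1)] * 4, 2: [code(2, 2, 2)] * 4}
        assert intra_pattern_distance(codes) == 0.0

    def test_intra_two_pattern_example(self):
        # one pattern identical codes, other differs at 1 of M neurons
        codes = {1: [code(1, 0, 0), code(1, 0, 0)],
                 2: [code(2, 0, 0), code(2, 0, 1)]}
        assert intra_pattern_distance(codes) == pytest.approx(0.5)

    def test_requires_two_prototypes(self):
        with pytest.raises(ValueError):
            inter_pattern_distance([code(1, 0)])

    def test_requires_two_repeats(self):
        with pytest.raises(ValueError):
            intra_pattern_distance({1: [code(1, 0)]})


def enumeration_max(P, C):
    """Brute-force maximum mean pairwise symbol distance at one neuron."""
    best = 0.0
    for assign in itertools.product(range(C), repeat=P):
        acc = sum(a != b for a, b in itertools.combinations(assign, 2))
        best = max(best, acc / (P * (P - 1) / 2))
    return best


class TestMaxInterDistance:
    def test_printed_worked_value(self):
        # the canonical M=8, C=2, P=15 bound: 15*8/(2*14) = 4.2857
        assert max_inter_distance(15, 2, 8) == pytest.approx(4.2857, abs=1e-4)

    def test_grows_linearly_in_m(self):
        base = max_inter_distance(15, 3, 1)
        for M in (2, 4, 8, 32):
            assert max_inter_distance(15, 3, M) == pytest.approx(M * base)

    def test_exact_matches_enumeration(self):
        for P in range(2, 6):
            for C in (2, 3):
                got = max_inter_distance(P, C, 1, method="exact")
                assert got == pytest.approx(enumeration_max(P, C)), (P, C)

    def test_exact_matches_enumeration_multi_neuron(self):
        # per-neuron independence: M=2 doubles the M=1 maximum
        for P, C in [(3, 3), (4, 2), (5, 3)]:
            assert max_inter_distance(P, C, 2, method="exact") == pytest.approx(
                2 * enumeration_max(P, C))

    def test_formula_agrees_with_exact_for_odd_p_divisible_by_c(self):
        for P, C in [(3, 3), (9, 3), (15, 3)]:
            assert max_inter_distance(P, C, 1) == pytest.approx(
                max_inter_distance(P, C, 1, method="exact"))

    def test_di_bound_holds_for_random_codes(self, rng):
        # D_inter never exceeds the exact bound
        for _ in range(30):
            P, M, C = int(rng.integers(2, 6)), int(rng.integers(1, 4)), 3
            protos = [code(p, *rng.integers(0, C, M)) for p in range(P)]
            d, _ = inter_pattern_distance(protos)
            assert d <= max_inter_distance(P, C, M, method="exact") + 1e-12


class TestDI:
    def test_perfect_discrimination(self):
        protos = [code(0, 0, 0), code(1, 1, 1), code(2, 2, 2)]
        rep = discriminability_index(0.0, 2.0, protos, P=3, C=3)
        assert rep.DI == pytest.approx(1.0)
        assert rep.uniqueness == 1.0

    def test_identical_prototypes_guarded_to_zero(self):
        protos = [code(0, 1, 1), code(1, 1, 1)]
        rep = discriminability_index(0.3, 0.0, protos, P=2, C=3)
        assert rep.DI == 0.0
        assert rep.uniqueness == 0.5

    def test_negative_di_when_intra_exceeds_inter(self):
        protos = [code(0, 0, 0), code(1, 1, 1)]
        rep = discriminability_index(3.0, 2.0, protos, P=2, C=3)
        assert rep.DI < 0

    def test_full_pipeline_invariant_to_pattern_order(self, rng):
        # unambiguous modes, so prototype selection is deterministic
        C = 3
        codes = {}
        for p in range(6):
            modal = code(p, *rng.integers(0, C, 4))
            other = code(p, *((np.array(modal.symbols) + 1) % C))
            codes[p] = [modal, modal, modal, other]
        r1 = compute_di(codes, np.random.default_rng(0), C=C)
        shuffled = {p: codes[p] for p in reversed(list(codes))}
        r2 = compute_di(shuffled, np.random.default_rng(0), C=C)
        assert r1.DI == pytest.approx(r2.DI)

    def test_per_code_symbol_shuffle_degrades_structured_codes(self, rng):
        # structured codes: one hot neuron per pattern, tiny within-pattern
        # noise; independently permuting symbol positions within each code
        # destroys neuron identity and must lower the DI.
        M, P, J, C = 8, 8, 6, 3
        codes = {}
        for p in range(P):
            cs = []
            for j in range(J):
                sym = np.zeros(M, int)
                sym[p] = 2
                sym[(p + 3) % M] = 1
                cs.append(RateCode(p, tuple(sym)))
            codes[p] = cs
        base = compute_di(codes, np.random.default_rng(1), C=C).DI
        shuf = {p: [RateCode(p, tuple(np.array(c.symbols)[rng.permutation(M)]))
                    for c in cs] for p, cs in codes.items()}
        got = compute_di(shuf, np.random.default_rng(1), C=C).DI
        assert base == pytest.approx(1.0)
        assert got < base


class TestFano:
    def test_poisson_counts_near_one(self, rng):
        counts = rng.poisson(30.0, size=20000)
        assert fano_factor(counts) == pytest.approx(1.0, abs=0.05)

    def test_constant_counts_zero(self):
        assert fano_factor([5, 5, 5, 5]) == 0.0

    def test_zero_mean_undefined(self):
        assert np.isnan(fano_factor([0, 0, 0]))

    def test_curve_from_poisson_sampler_flat_at_one(self, rng, patterns):
        M, trials = 8, 200

        def sampler(pattern, d_s, n):
            return rng.poisson(25.0 * d_s, size=(n, M))

        df = fano_factor_curve(sampler, patterns[:3], [0.5, 1.0, 2.0], trials, M)
        assert np.allclose(df.fano_factor, 1.0, atol=0.15)
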