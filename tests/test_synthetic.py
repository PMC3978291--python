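"""Generators: reproducibility, constraints, and statistical targets."""

import math

import numpy as np
import pytest

from symcomplex.encoding import GridSpec
from symcomplex.sequences import ALPHABET, MOVES, EmptyInputError
from symcomplex.synthetic import (
    CONDITIONS,
    DEFAULT_N,
    GeneratorSpec,
    gen_grid_random_walk,
    gen_iid_frequencies,
    gen_markov,
    gen_motif_library,
    gen_motif_pattern,
    gen_regime_walk,
    gen_rhythmic,
    gen_trajectory,
    generate_condition,
    generate_suite,
    markov_entropy_rate,
    persistent_walk_matrix,
    random_closed_motif,
)


def in_grid_throughout(seq, start=(5, 5), width=10, height=10):
    i, j = start
    for c in seq.symbols:
        dx, dy = MOVES[c]
        i, j = i + dx, j + dy
        if not (0 <= i < width and 0 <= j < height):
            return False
    return True


class TestRhythmic:
    def test_small(self):
        assert gen_rhythmic(4).symbols == "udud"

    def test_default_length_and_alphabet_use(self):
        seq = gen_rhythmic(DEFAULT_N)
        assert len(seq) == 10_000
        assert set(seq.symbols) == {"u", "d"}
        assert len(seq.trial_boundaries) == 49


class TestGridRandomWalk:
    def test_deterministic_in_seed(self):
        a = gen_grid_random_walk(n=2000, seed=9)
        b = gen_grid_random_walk(n=2000, seed=9)
        c = gen_grid_random_walk(n=2000, seed=10)
        assert a.symbols == b.symbols
        assert a.symbols != c.symbols

    def test_stays_in_bounds(self):
        assert in_grid_throughout(gen_grid_random_walk(n=5000, seed=1))

    def test_1x2_grid_forces_alternation(self):
        seq = gen_grid_random_walk(GridSpec(1, 2, 1.0), n=50, seed=0)
        assert seq.symbols in ("ud" * 25, ("du" * 25))

    def test_empirical_step_entropy_matches_analytic(self):
        from symcomplex.entropy import entropy_rate_random_walk

        grid = GridSpec(10, 10, 1.0)
        walk = gen_grid_random_walk(grid, n=100_000, seed=2)
        i, j = 5, 5
        acc = 0.0
        for c in walk.symbols:
            acc += math.log(grid.n_moves(i, j), 4)
            dx, dy = MOVES[c]
            i, j = i + dx, j + dy
        assert abs(acc / len(walk) - entropy_rate_random_walk(grid)) < 0.005


class TestIIDFrequencies:
    def test_point_mass(self):
        assert gen_iid_frequencies([1, 0, 0, 0], n=20, seed=0).symbols == "l" * 20

    def test_frequencies_within_three_standard_errors(self):
        freqs = np.array([0.4, 0.3, 0.2, 0.1])
        n = 100_000
        seq = gen_iid_frequencies(freqs, n=n, seed=1)
        for c, p in zip(ALPHABET, freqs):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(seq.symbols.count(c) / n - p) < 3 * se

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ValueError):
            gen_iid_frequencies([0.5, 0.5, 0.5, -0.5], n=10)


class TestMarkov:
    def test_absorbing_identity_gives_constant(self):
        seq = gen_markov(np.eye(4), n=100, seed=0, start=2)
        assert seq.symbols == "u" * 100

    def test_uniform_rows_have_unit_rate(self):
        T = np.full((4, 4), 0.25)
        assert markov_entropy_rate(T) == pytest.approx(1.0)

    def test_persistent_matrix_rate_recovered_by_lz(self):
        from symcomplex.regularity import lz_entropy_rate

        T = persistent_walk_matrix()
        h = markov_entropy_rate(T)
        est = lz_entropy_rate(gen_markov(T, n=100_000, seed=3))
        assert abs(est - h) / h < 0.05

    def test_bad_matrix_rejected(self):
        with pytest.raises(ValueError):
            gen_markov(np.ones((4, 4)), n=10)


class TestMotifGenerators:
    def test_closed_motifs_are_closed(self, rng):
        for _ in range(20):
            motif = random_closed_motif(rng)
            dx = motif.count("r") - motif.count("l")
            dy = motif.count("u") - motif.count("d")
            assert (dx, dy) == (0, 0)

    def test_open_motif_rejected_for_pattern(self):
        with pytest.raises(ValueError):
            gen_motif_pattern(motif="rru", n=100, seed=0)

    def test_pure_motif_is_periodic(self):
        seq = gen_motif_pattern(
            motif="rrddlluu", n=64, switch_prob=0.0, noise_prob=0.0, seed=0
        )
        assert seq.symbols == ("rrddlluu" * 8)

    def test_pattern_stays_in_grid(self):
        seq = gen_motif_pattern(n=5000, seed=7)
        # reconstruct from an unknown start: net excursion must fit a 10x10 box
        x = y = 0
        xs, ys = [0], [0]
        for c in seq.symbols:
            dx, dy = MOVES[c]
            x, y = x + dx, y + dy
            xs.append(x)
            ys.append(y)
        assert max(xs) - min(xs) <= 9 and max(ys) - min(ys) <= 9

    def test_seed_reproducibility(self):
        assert (
            gen_motif_pattern(n=1000, seed=4).symbols
            == gen_motif_pattern(n=1000, seed=4).symbols
        )

    def test_single_motif_library_reduces_to_pattern(self):
        lib = gen_motif_library(motifs=["rrddlluu"], n=64, seed=0)
        pure = gen_motif_pattern(
            motif="rrddlluu", n=64, switch_prob=0.0, noise_prob=0.0, seed=0
        )
        assert lib.symbols == pure.symbols

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            gen_motif_library(motifs=[], n=10)

    def test_library_reproducible(self):
        a = gen_motif_library(n=2000, seed=11)
        b = gen_motif_library(n=2000, seed=11)
        assert a.symbols == b.symbols


class TestRegimeWalk:
    def test_reproducible_and_bounded(self):
        a = gen_regime_walk(n=3000, seed=5)
        assert a.symbols == gen_regime_walk(n=3000, seed=5).symbols
        assert in_grid_throughout(a)


class TestTrajectories:
    def test_zero_duration_rejected(self):
        with pytest.raises(EmptyInputError):
            gen_trajectory("circle", duration_s=0.0)

    def test_circle_discretization_is_periodic(self):
        from symcomplex.encoding import GridSpec, discretize

        traj = gen_trajectory("circle", duration_s=6.0, radius=3.0, period_s=2.0)
        seq = discretize(traj, GridSpec(10, 10, 1.0)).symbols
        # After the first revolution the symbol stream repeats with a fixed
        # cycle (the crossings of one revolution).
        tail = seq[len(seq) // 3 :]
        periods = [
            p
            for p in range(5, len(tail) // 2 + 2)
            if all(tail[i] == tail[i + p] for i in range(len(tail) - p))
        ]
        assert periods, "no repeating cycle found"

    def test_oversized_circle_rejected(self):
        with pytest.raises(ValueError):
            gen_trajectory("circle", duration_s=1.0, radius=6.0)

    def test_brownian_stays_in_workspace(self):
        traj = gen_trajectory("brownian", duration_s=5.0, seed=3, step_cm=0.2)
        assert traj.xy.min() >= 0.0 and traj.xy.max() <= 10.0


class TestConditionSuite:
    def test_all_conditions_generate(self):
        suite = generate_suite(seed=1, n=2000)
        assert set(suite) == set(CONDITIONS)
        for lab, seq in suite.items():
            assert len(seq) == 2000
            assert seq.label == lab

    def test_af_matches_pattern_frequencies(self):
        n = 10_000
        pattern = generate_condition("P", seed=2, n=n)
        af = generate_condition("AF", seed=2, n=n)
        for c in ALPHABET:
            p = pattern.symbols.count(c) / n
            se = math.sqrt(max(p * (1 - p), 1e-9) / n)
            assert abs(af.symbols.count(c) / n - p) < 4 * se + 1e-9

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            generate_condition("XX")

    def test_generator_spec_dispatch(self):
        spec = GeneratorSpec(kind="rhythmic", n=6)
        assert spec.generate().symbols == "ududud"
        with pytest.raises(ValueError):
            GeneratorSpec(kind="nope").generate()
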