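import itertools

import numpy as np
import pytest

from lossweb import (
    RandomMatrixSpec,
    full_randomize,
    minimal_randomize,
    random_competition_matrix,
    restore_community_asymmetry,
    restore_pairwise_asymmetry,
    stability_threshold_curve,
    weak_randomize,
)
from lossweb.asymmetry import community_asymmetry_at_order
from lossweb.randomization import MANIPULATIONS, stable_fraction

from conftest import random_normalized


def two_link_products(a):
    """Multiset of a_ij * a_ji over reciprocal pairs (2-link loop weights squared)."""
    s = a.shape[0]
    return sorted(
        a[i, j] * a[j, i]
        for i in range(s)
        for j in range(i + 1, s)
        if a[i, j] != 0 and a[j, i] != 0
    )


@pytest.mark.parametrize("kind", list(MANIPULATIONS))
def test_manipulations_preserve_values_topology_diagonal(kind, rng):
    for _ in range(5):
        n = random_normalized(rng, s=6, connectance=0.8)
        out = MANIPULATIONS[kind](n, rng)
        a, b = n.abar, out.abar
        assert np.array_equal(a != 0, b != 0)  # zero pattern
        assert np.allclose(b.diagonal(), -1.0)
        assert np.allclose(np.sort(a[a != 0]), np.sort(b[b != 0]))  # value multiset


class TestFullRandomize:
    def test_single_pair_swap_or_identity(self, rng):
        a = np.array([[-1.0, -0.7], [-0.2, -1.0]])
        out = full_randomize(random_normalized(rng, s=2), rng)
        vals = sorted(out.abar[out.abar != -1.0])
        assert len(vals) == 2

    def test_generally_breaks_two_link_loops(self, rng):
        n = random_normalized(rng, s=7)
        changed = any(
            two_link_products(full_randomize(n, rng).abar)
            != pytest.approx(two_link_products(n.abar))
            for _ in range(10)
        )
        assert changed


class TestWeakAndMinimal:
    def test_two_link_loop_multiset_preserved(self, rng):
        n = random_normalized(rng, s=7, connectance=0.8)
        for fn in (weak_randomize, minimal_randomize):
            out = fn(n, rng)
            assert two_link_products(out.abar) == pytest.approx(two_link_products(n.abar))

    def test_pairwise_asymmetry_preserved(self, rng):
        from lossweb import pairwise_asymmetry

        n = random_normalized(rng, s=6)
        for fn in (weak_randomize, minimal_randomize):
            assert pairwise_asymmetry(fn(n, rng).abar).value == pytest.approx(
                pairwise_asymmetry(n.abar).value
            )

    def test_minimal_preserves_community_asymmetry_at_source_order(self, rng):
        n = random_normalized(rng, s=7)
        out = minimal_randomize(n, rng)
        assert community_asymmetry_at_order(out.abar) == pytest.approx(
            community_asymmetry_at_order(n.abar)
        )

    def test_one_sided_link_rejected(self, rng):
        n = random_normalized(rng, s=5)
        a = n.abar.copy()
        a[0, 1] = 0.0  # break reciprocity
        from lossweb import NormalizedMatrix

        broken = NormalizedMatrix(n.species, a)
        with pytest.raises(ValueError, match="reciprocal"):
            weak_randomize(broken, rng)


class TestRestorations:
    def test_strongest_with_weakest_pairing(self, rng):
        a = np.array(
            [
                [-1.0, -0.9, 0.0],
                [-0.1, -1.0, -0.7],
                [0.0, -0.3, -1.0],
            ]
        )
        from lossweb import NormalizedMatrix

        n = NormalizedMatrix(["A", "B", "C"], a)
        out = restore_pairwise_asymmetry(n, rng)
        assert two_link_products(out.abar) == pytest.approx([0.9 * 0.1, 0.7 * 0.3])

    def test_pairing_minimises_max_two_link_weight(self, rng):
        # brute force over all ways to pair 6 values
        vals = [0.95, 0.8, 0.6, 0.35, 0.2, 0.05]

        def pairings(items):
            if not items:
                yield []
                return
            first, rest = items[0], items[1:]
            for k, other in enumerate(rest):
                for tail in pairings(rest[:k] + rest[k + 1 :]):
                    yield [(first, other)] + tail

        best = min(max(x * y for x, y in p) for p in pairings(vals))
        strong_weak = max(vals[k] * vals[5 - k] for k in range(3))
        assert strong_weak == pytest.approx(best)

    def test_restore_community_puts_strong_below(self, rng):
        n = random_normalized(rng, s=6)
        paired = restore_pairwise_asymmetry(n, rng)
        out = restore_community_asymmetry(paired)
        a = out.abar
        for i in range(6):
            for j in range(i + 1, 6):
                if a[i, j] != 0:
                    assert abs(a[j, i]) >= abs(a[i, j])
        assert community_asymmetry_at_order(a) >= community_asymmetry_at_order(paired.abar) - 1e-12

    def test_flip_keeps_two_link_loops(self, rng):
        n = random_normalized(rng, s=6)
        paired = restore_pairwise_asymmetry(n, rng)
        out = restore_community_asymmetry(paired)
        assert two_link_products(out.abar) == pytest.approx(two_link_products(paired.abar))


class TestRandomMatrices:
    def test_full_connectance_all_links_negative(self, rng):
        a = random_competition_matrix(RandomMatrixSpec(S=3, C=1.0), rng)
        off = ~np.eye(3, dtype=bool)
        assert (a[off] < 0).all()
        assert np.allclose(a.diagonal(), -1.0)

    @pytest.mark.parametrize("pairing", ["asymmetric", "symmetric"])
    def test_pairing_rules_recoverable_from_output(self, pairing, rng):
        # reconstruct the sorted draw list from the matrix itself and check
        # which products the pairing rule should have produced
        a = random_competition_matrix(RandomMatrixSpec(S=6, C=1.0, pairing=pairing), rng)
        off = ~np.eye(6, dtype=bool)
        v = np.sort(np.abs(a[off]))[::-1]
        n = len(v) // 2
        if pairing == "asymmetric":
            expected = sorted(v[k] * v[2 * n - 1 - k] for k in range(n))
        else:
            expected = sorted(v[2 * k] * v[2 * k + 1] for k in range(n))
        assert two_link_products(a) == pytest.approx(sorted(np.array(expected)))

    def test_half_normal_magnitude_mean(self, rng):
        sigma = 0.8
        draws = []
        for _ in range(100):
            a = random_competition_matrix(RandomMatrixSpec(S=10, C=1.0, sigma=sigma), rng)
            draws.append(np.abs(a[~np.eye(10, dtype=bool)]))
        draws = np.concatenate(draws)
        expected = sigma * np.sqrt(2 / np.pi)
        se = sigma * np.sqrt(1 - 2 / np.pi) / np.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 3 * se

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            RandomMatrixSpec(S=5, C=0.0)
        with pytest.raises(ValueError):
            RandomMatrixSpec(S=5, C=0.5, sigma=-1.0)
        with pytest.raises(ValueError):
            RandomMatrixSpec(S=5, C=0.5, pairing="nope")


class TestThresholdCurve:
    def test_weakly_coupled_pairs_always_stable(self, rng):
        thresholds, grid = stability_threshold_curve(
            [2], [0.3, 0.6, 0.9], reps=30, sigma=0.1, pairing="asymmetric", rng=rng
        )
        assert (grid["stable_fraction"] > 0.9).all()
        assert thresholds["C_threshold"].iloc[0] == 0.9

    def test_cutoff_validation(self, rng):
        with pytest.raises(ValueError):
            stability_threshold_curve([3], [0.5], reps=5, rng=rng)
        with pytest.raises(ValueError):
            stability_threshold_curve([], [0.5], rng=rng)
        with pytest.raises(ValueError):
            stability_threshold_curve([3], [0.5], stable_fraction_cutoff=1.5, rng=rng)

    def test_stable_fraction_bounds(self, rng):
        frac = stable_fraction(RandomMatrixSpec(S=4, C=0.5, reps=40), rng)
        assert 0.0 <= frac <= 1.0
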