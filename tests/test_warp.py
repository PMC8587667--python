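"""COW warping: DP correctness, reference selection, parameter optimizers."""

import itertools
import math

import numpy as np
import pytest

from chromalink import (
    FingerprintSet,
    Fingerprint,
    SynthConfig,
    WarpingParams,
    acow_optimize,
    correlation_structure,
    cow_pair,
    cow_set,
    doe_optimize,
    generate_dataset,
    select_reference,
)
from chromalink.errors import ParameterError, PreconditionError
from chromalink.warp import (
    _segment_nodes,
    alignment_objective,
    doe_levels,
    fit_quadratic_response,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def segment_benefit(sample, target, sl, ss, increments=None):
    """Reference benefit computation: sum of per-segment correlations for an
    explicit node placement (``increments=None`` → the unwarped placement)."""
    nodes_t = _segment_nodes(len(target), sl)
    d = np.diff(nodes_t)
    ls = len(sample)
    if increments is None:
        increments = d
    total, x = 0.0, 0
    for i, inc in enumerate(increments):
        m = d[i] + 1
        pos = x + np.linspace(0, inc, m)
        base = np.minimum(pos.astype(int), ls - 2)
        frac = pos - base
        seg = sample[base] * (1 - frac) + sample[base + 1] * frac
        tseg = target[nodes_t[i] : nodes_t[i + 1] + 1]
        sc, tc = seg - seg.mean(), tseg - tseg.mean()
        sn, tn = math.sqrt(sc @ sc), math.sqrt(tc @ tc)
        total += (sc @ tc) / (sn * tn) if sn > 1e-12 and tn > 1e-12 else 0.0
        x += inc
    return total


def brute_force_best(sample, target, sl, ss):
    """Exhaustive enumeration over all admissible node placements."""
    d = np.diff(_segment_nodes(len(target), sl))
    best = -np.inf
    ranges = [range(max(di - ss, 1), di + ss + 1) for di in d]
    for incs in itertools.product(*ranges):
        if sum(incs) == len(sample) - 1:
            best = max(best, segment_benefit(sample, target, sl, ss, incs))
    return best


def gaussian(n, centre, width=6.0, height=10.0):
    return height * np.exp(-0.5 * ((np.arange(n) - centre) / width) ** 2)


# ---------------------------------------------------------------------------
# cow_pair
# ---------------------------------------------------------------------------

class TestCowPair:
    @pytest.mark.parametrize("sl, ss", [(10, 2), (20, 5), (33, 8)])
    def test_identity_warp(self, sl, ss, rng):
        x = rng.normal(0, 1, 200).cumsum()
        warped, benefit = cow_pair(x, x, WarpingParams(sl, ss))
        np.testing.assert_allclose(warped, x, atol=1e-12)
        assert benefit == pytest.approx(len(_segment_nodes(200, sl)) - 1)

    def test_shifted_peak_benefit_exceeds_unwarped(self):
        n = 120
        target = gaussian(n, 60)
        sample = gaussian(n, 64)  # +4-point retention shift
        _, benefit = cow_pair(sample, target, WarpingParams(20, 5))
        assert benefit > segment_benefit(sample, target, 20, 5)

    def test_dp_matches_brute_force_on_tiny_instances(self, rng):
        for _ in range(10):
            sl = int(rng.integers(8, 13))
            ss = int(rng.integers(1, 4))
            n = int(rng.integers(2 * sl, 41))
            target = rng.normal(0, 1, n).cumsum()
            sample = rng.normal(0, 1, n).cumsum()
            _, benefit = cow_pair(sample, target, WarpingParams(sl, ss))
            assert benefit == pytest.approx(brute_force_best(sample, target, sl, ss), abs=1e-9)

    def test_output_length_and_bounds(self, rng):
        for _ in range(5):
            sample = rng.random(150) * 10
            target = rng.random(150) * 10
            warped, _ = cow_pair(sample, target, WarpingParams(25, 6))
            assert len(warped) == len(target)
            # linear interpolation cannot extrapolate
            assert warped.min() >= sample.min() - 1e-12
            assert warped.max() <= sample.max() + 1e-12
            assert warped[0] == sample[0] and warped[-1] == sample[-1]

    def test_too_short_sequence_rejected(self):
        with pytest.raises(PreconditionError, match="2\\*SL"):
            cow_pair(np.zeros(30), np.zeros(30), WarpingParams(20, 5))

    def test_invalid_slack_rejected(self):
        with pytest.raises(ParameterError, match="SS"):
            WarpingParams(10, 10)
        with pytest.raises(ParameterError, match="SL"):
            WarpingParams(2, 1)


# ---------------------------------------------------------------------------
# reference selection and set-level warping
# ---------------------------------------------------------------------------

class TestSelectReference:
    def test_mean_profile_sample_selected(self, rng):
        base = rng.random((5, 100)) * 5
        base[3] = np.delete(base, 3, axis=0).mean(axis=0)  # close to everyone
        time = np.arange(100.0)
        fpset = FingerprintSet(
            [Fingerprint(f"s{i}", time, base[i], "g") for i in range(5)]
        )
        # brute-force oracle: highest mean r to all others
        c = np.corrcoef(base)
        np.fill_diagonal(c, 0)
        expected = int(np.argmax(c.sum(axis=1) / 4))
        assert select_reference(fpset) == expected == 3

    def test_tie_breaks_to_lowest_index(self):
        time = np.arange(50.0)
        trace = np.sin(time / 5)
        fpset = FingerprintSet(
            [Fingerprint("a", time, trace, "g"), Fingerprint("b", time, trace, "g")]
        )
        assert select_reference(fpset) == 0

    def test_single_sample_rejected(self):
        fpset = FingerprintSet([Fingerprint("a", np.arange(9.0), np.arange(9.0))])
        with pytest.raises(PreconditionError):
            select_reference(fpset)


class TestCowSet:
    def test_zero_shift_noiseless_set_unchanged(self):
        cfg = SynthConfig(
            n_groups=2, samples_per_group=3, n_points=300, n_peaks=8,
            intra_sd=0.0, inter_sd=0.0, shift_sd=0.0, noise_sd=0.0, seed=4,
        )
        ds = generate_dataset(cfg)
        result = cow_set(ds, WarpingParams(30, 5))
        np.testing.assert_allclose(result.aligned.matrix(), ds.matrix(), atol=1e-9)

    def test_reference_r_is_exactly_one(self, shifted_set):
        result = cow_set(shifted_set, WarpingParams(40, 6))
        assert result.per_sample_r[result.reference_index] == 1.0

    def test_two_rounds_equal_manual_composition(self, shifted_set):
        params = WarpingParams(40, 6)
        direct = cow_set(shifted_set, params, rounds=2)
        manual = cow_set(cow_set(shifted_set, params).aligned, params)
        np.testing.assert_array_equal(direct.aligned.matrix(), manual.aligned.matrix())

    def test_alignment_raises_mean_intra_r(self, shifted_set):
        before = correlation_structure(shifted_set).intra_r.mean()
        result = cow_set(shifted_set, WarpingParams(40, 6))
        after = correlation_structure(result.aligned).intra_r.mean()
        assert after > before

    def test_invalid_rounds(self, shifted_set):
        with pytest.raises(ParameterError, match="rounds"):
            cow_set(shifted_set, WarpingParams(40, 6), rounds=0)


# ---------------------------------------------------------------------------
# parameter optimizers
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def acow_fixture():
    return generate_dataset(
        SynthConfig(n_groups=3, samples_per_group=3, n_points=500,
                    n_peaks=15, shift_sd=4.0, seed=2)
    )


class TestAcow:
    def test_matches_exhaustive_on_small_ranges(self, acow_fixture):
        sl_range, ss_range = (15, 22), (1, 3)
        params = acow_optimize(acow_fixture, sl_range, ss_range)
        assert sl_range[0] <= params.sl <= sl_range[1]
        assert ss_range[0] <= params.ss <= ss_range[1]
        best = max(
            alignment_objective(acow_fixture, WarpingParams(sl, ss))
            for sl in range(sl_range[0], sl_range[1] + 1)
            for ss in range(ss_range[0], ss_range[1] + 1)
        )
        assert alignment_objective(acow_fixture, params) == pytest.approx(best)

    def test_plateau_returns_first_evaluated_optimum(self):
        cfg = SynthConfig(
            n_groups=2, samples_per_group=2, n_points=300, n_peaks=8,
            intra_sd=0.0, inter_sd=0.0, shift_sd=0.0, noise_sd=0.0, seed=4,
        )
        ds = generate_dataset(cfg)
        params = acow_optimize(ds, (20, 30), (1, 3))
        assert alignment_objective(ds, params) == pytest.approx(1.0)
        assert (params.sl, params.ss) == (20, 1)  # documented tie-break

    def test_empty_range_rejected(self, acow_fixture):
        with pytest.raises(ParameterError, match="ranges"):
            acow_optimize(acow_fixture, (25, 15), (1, 3))


class TestDoE:
    def test_table_levels(self):
        assert doe_levels((15, 100), (1, 10)) == ([15, 58, 100], [1, 6, 10])
        assert doe_levels((25, 200), (1, 10)) == ([25, 113, 200], [1, 6, 10])

    def test_nine_design_points_at_design1_levels(self, shifted_set):
        result = doe_optimize(shifted_set, design=1)
        pairs = [(p.sl, p.ss) for p in result.design_points]
        assert len(pairs) == 9
        assert pairs == list(itertools.product([15, 58, 100], [1, 6, 10]))
        assert result.best_params in result.design_points
        best = int(np.argmax(result.responses))
        assert result.best_params == result.design_points[best]

    def test_quadratic_fit_recovers_known_coefficients(self):
        coded = np.array(list(itertools.product((-1, 0, 1), repeat=2)), dtype=float)
        beta_true = np.array([0.9, 0.03, -0.01, -0.05, 0.02, 0.015])
        x1, x2 = coded[:, 0], coded[:, 1]
        responses = (
            beta_true[0] + beta_true[1] * x1 + beta_true[2] * x2
            + beta_true[3] * x1**2 + beta_true[4] * x2**2 + beta_true[5] * x1 * x2
        )
        np.testing.assert_allclose(
            fit_quadratic_response(coded, responses), beta_true, atol=1e-12
        )

    def test_constant_responses_give_intercept_only(self):
        coded = np.array(list(itertools.product((-1, 0, 1), repeat=2)), dtype=float)
        beta = fit_quadratic_response(coded, np.full(9, 0.42))
        np.testing.assert_allclose(beta, [0.42, 0, 0, 0, 0, 0], atol=1e-12)

    def test_unlabelled_set_rejected(self):
        time = np.arange(300.0)
        rng = np.random.default_rng(1)
        fpset = FingerprintSet(
            [Fingerprint(f"s{i}", time, rng.random(300)) for i in range(4)]
        )
        with pytest.raises(PreconditionError, match="label"):
            doe_optimize(fpset, design=1)


def test_both_optimizers_improve_shifted_data(shifted_set):
    """ACOW and the factorial design both strictly raise mean intra-group r
    over the unaligned data (their results need not coincide)."""
    before = correlation_structure(shifted_set).intra_r.mean()
    acow_params = acow_optimize(shifted_set, (30, 50), (2, 6))
    doe_params = doe_optimize(shifted_set, design=1).best_params
    for params in (acow_params, doe_params):
        aligned = cow_set(shifted_set, params).aligned
        assert correlation_structure(aligned).intra_r.mean() > before
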