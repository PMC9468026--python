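"""Colocalization pairing, normalization, and per-condition aggregation."""

import numpy as np
import pytest

from simca import (
    AffineTransform2D,
    FovCounts,
    SimulationConfig,
    aggregate_counts,
    colocalize,
    normalize,
    simulate_fov,
)
from simca.detection import SpotSet


def _spots(xy, channel="capture", fov="f"):
    return SpotSet(fov_id=fov, channel=channel, xy=np.asarray(xy, float))


IDENTITY = AffineTransform2D.identity()


def brute_force_pairs(cab_xy, dab_xy, radius):
    """Independent oracle: enumerate all pairs, sort by (distance, i, j),
    accept greedily while both unassigned."""
    cand = []
    for i, c in enumerate(cab_xy):
        for j, d in enumerate(dab_xy):
            dist = float(np.hypot(*(np.asarray(c) - np.asarray(d))))
            if dist <= radius:
                cand.append((dist, i, j))
    cand.sort()
    used_i, used_j, pairs = set(), set(), []
    for _, i, j in cand:
        if i not in used_i and j not in used_j:
            used_i.add(i)
            used_j.add(j)
            pairs.append((i, j))
    return pairs


class TestColocalize:
    @pytest.mark.parametrize("distance,expected", [(1.4, 1), (1.6, 0)])
    def test_pairing_criterion_boundary(self, distance, expected):
        """1.4 px apart is a colocalized pair; 1.6 px is not."""
        counts, _ = colocalize(
            _spots([[10.0, 10.0]]), _spots([[10.0 + distance, 10.0]], "detection"),
            IDENTITY,
        )
        assert counts.coloc_count == expected

    def test_empty_detection_set_gives_zero(self):
        counts, pairs = colocalize(
            _spots([[1.0, 1.0]]), _spots(np.empty((0, 2)), "detection"), IDENTITY
        )
        assert counts.coloc_count == 0 and pairs == []

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            colocalize(_spots([[0, 0]]), _spots([[0, 0]], "detection"),
                       IDENTITY, radius_px=0.0)

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(30):
            cab_xy = rng.uniform(0, 30, (20, 2))
            dab_xy = rng.uniform(0, 30, (20, 2))
            counts, pairs = colocalize(
                _spots(cab_xy), _spots(dab_xy, "detection"), IDENTITY
            )
            oracle = brute_force_pairs(cab_xy, dab_xy, 1.5)
            assert counts.coloc_count == len(oracle)
            assert sorted(pairs) == sorted(oracle)

    def test_transform_applied_to_detection_coordinates(self):
        t = AffineTransform2D.from_translation(-5.0, 0.0)
        counts, _ = colocalize(
            _spots([[10.0, 10.0]]), _spots([[15.0, 10.0]], "detection"), t
        )
        assert counts.coloc_count == 1

    def test_one_to_one_never_exceeds_either_count(self, rng):
        cab_xy = rng.uniform(0, 5, (10, 2))  # crowded: many candidates
        dab_xy = rng.uniform(0, 5, (25, 2))
        counts, _ = colocalize(_spots(cab_xy), _spots(dab_xy, "detection"), IDENTITY)
        assert counts.coloc_count <= min(counts.cab_count, counts.dab_count)

    def test_enlarging_radius_never_decreases_count(self, rng):
        cab_xy = rng.uniform(0, 50, (30, 2))
        dab_xy = rng.uniform(0, 50, (30, 2))
        prev = -1
        for radius in (0.5, 1.5, 3.0, 6.0, 12.0):
            counts, _ = colocalize(
                _spots(cab_xy), _spots(dab_xy, "detection"), IDENTITY, radius
            )
            assert counts.coloc_count >= prev
            prev = counts.coloc_count

    def test_role_swap_with_inverse_transform_gives_same_count(
        self, rng, example_transform
    ):
        cab_xy = rng.uniform(20, 200, (25, 2))
        dab_xy = rng.uniform(20, 200, (25, 2))
        fwd, _ = colocalize(
            _spots(cab_xy), _spots(dab_xy, "detection"), example_transform
        )
        # swapped roles: map capture coords into the detection frame instead
        swapped, _ = colocalize(
            _spots(dab_xy, "capture"), _spots(cab_xy, "detection"),
            example_transform.inverse(),
        )
        assert fwd.coloc_count == swapped.coloc_count

    def test_ground_truth_pairs_recovered_from_coordinates(self, small_config):
        """>=99% of truly bound pairs lie within 1.5 px after mapping the
        detection coordinates through the true transform (geometric stage,
        ground-truth coordinates)."""
        recovered = total = 0
        for seed in range(8):
            _, truth = simulate_fov(small_config, 20000.0, seed)
            counts, pairs = colocalize(
                _spots(truth.cab_xy),
                _spots(truth.dab_specific_xy, "detection"),
                small_config.true_transform,
            )
            hits = sum(1 for i, j in pairs if truth.dab_specific_pair[j] == i)
            recovered += hits
            total += len(truth.dab_specific_xy)
        assert total > 300
        assert recovered / total >= 0.99

    def test_false_pair_rate_matches_poisson_coverage(self, small_config):
        """Non-specific detections pair with a random capture antibody at the
        analytic 1−exp(−rho·pi·r²) rate, within 3 binomial SEs."""
        hits = total = 0
        exp_rate = 0.0
        for seed in range(30):
            _, truth = simulate_fov(small_config, 0.0, seed)
            counts, _ = colocalize(
                _spots(truth.cab_xy),
                _spots(truth.dab_nonspecific_xy, "detection"),
                small_config.true_transform,
            )
            area = (small_config.image_height_px - 2 * small_config.edge_margin_px) * (
                small_config.half_width_px - 2 * small_config.edge_margin_px
            )
            rho = truth.n_cab / area
            exp_rate += (1 - np.exp(-rho * np.pi * 1.5**2)) * truth.n_dab
            hits += counts.coloc_count
            total += truth.n_dab
        p = exp_rate / total
        se = np.sqrt(total * p * (1 - p))
        assert abs(hits - exp_rate) < 3 * se + 1


class TestNormalize:
    def test_ratio_formulas(self):
        counts = normalize(FovCounts("f", cab_count=200, dab_count=80, coloc_count=50))
        assert counts.normalized_coloc == pytest.approx(0.25)
        assert counts.normalized_single == pytest.approx(0.40)

    def test_zero_coloc_gives_zero_ratio(self):
        counts = normalize(FovCounts("f", cab_count=200, dab_count=10, coloc_count=0))
        assert counts.normalized_coloc == 0.0

    def test_no_capture_spots_flagged_invalid_not_raised(self):
        counts = normalize(FovCounts("f", cab_count=0, dab_count=5, coloc_count=0))
        assert not counts.valid
        assert np.isnan(counts.normalized_coloc)

    def test_normalized_coloc_bounded_by_unit_interval(self, rng):
        for _ in range(50):
            cab = int(rng.integers(1, 300))
            dab = int(rng.integers(0, 300))
            coloc = int(rng.integers(0, min(cab, dab) + 1))
            c = normalize(FovCounts("f", cab, dab, coloc))
            assert 0.0 <= c.normalized_coloc <= 1.0


class TestAggregateCounts:
    def _fov(self, fov_id, cab, dab, coloc, conc=100.0):
        return normalize(
            FovCounts(fov_id, cab, dab, coloc, concentration_pm=conc)
        )

    def test_identical_fovs_have_zero_cv(self):
        fovs = [self._fov(f"f{i}", 200, 80, 50) for i in range(4)]
        out = aggregate_counts(fovs)
        assert out["coloc_count_cv"].iloc[0] == 0.0

    def test_hand_computed_cv_with_sample_std(self):
        """Counts {90, 110}: mean 100, sample std 14.142, CV 0.1414."""
        fovs = [self._fov("a", 90, 10, 5), self._fov("b", 110, 10, 5)]
        out = aggregate_counts(fovs)
        assert out["cab_count_mean"].iloc[0] == pytest.approx(100.0)
        assert out["cab_count_std"].iloc[0] == pytest.approx(14.1421356, rel=1e-6)
        assert out["cab_count_cv"].iloc[0] == pytest.approx(0.141421356, rel=1e-6)

    def test_all_invalid_fovs_rejected(self):
        fovs = [normalize(FovCounts("a", 0, 5, 0)), normalize(FovCounts("b", 0, 5, 0))]
        with pytest.raises(ValueError):
            aggregate_counts(fovs)

    def test_normalization_reduces_cv_under_heterogeneous_cab_loading(self, rng):
        """When capture-antibody surface loading varies across FOVs, the
        capture-normalized colocalized count is more consistent than the raw
        single-color detection count (the assay's variance-reduction claim)."""
        fovs = []
        for i in range(40):
            cab = int(rng.integers(100, 400))  # heterogeneous loading
            bound = rng.binomial(cab, 0.3)
            dab = bound + rng.poisson(10)
            fovs.append(self._fov(f"f{i}", cab, dab, bound))
        out = aggregate_counts(fovs)
        assert (
            out["normalized_coloc_cv"].iloc[0] < out["dab_count_cv"].iloc[0]
        )

    def test_grouping_by_concentration(self):
        fovs = [self._fov("a", 100, 10, 5, 0.0), self._fov("b", 120, 12, 6, 0.0),
                self._fov("c", 100, 50, 40, 300.0), self._fov("d", 90, 45, 30, 300.0)]
        out = aggregate_counts(fovs)
        assert len(out) == 2
        assert set(out["concentration_pm"]) == {0.0, 300.0}
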