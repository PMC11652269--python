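import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from sgsearch.gumbel import GumbelParams, gumbel_density
from sgsearch.table import (SGTableConfig, TableFormatError, TableMismatchError,
                            build_sg_table, importance_weight, load_table,
                            precision_cutoff, save_table)

Y = GumbelParams(0.0, 1 / 3)
PROP = GumbelParams(33.0, 1 / 15)


class TestImportanceWeight:
    @given(s=st.floats(-20, 80))
    @settings(max_examples=100, deadline=None)
    def test_identical_densities_give_unit_weight(self, s):
        assert importance_weight(s, Y, Y) == pytest.approx(1.0, rel=1e-12)

    def test_unit_weight_where_densities_cross(self):
        logratio = lambda s: (np.log(gumbel_density(s, Y))
                              - np.log(gumbel_density(s, PROP)))
        s_cross = brentq(logratio, 0.0, 40.0)
        assert importance_weight(s_cross, Y, PROP) == pytest.approx(1.0, rel=1e-9)

    def test_frozen_ratio_at_proposal_location(self):
        # numerator f_{G(0,1/3)}(33); denominator (1/15) e^{-1}
        assert importance_weight(33.0, Y, PROP) == pytest.approx(
            0.00022699585756387053933714520881, rel=1e-12)

    def test_positive_for_extreme_scores(self):
        assert importance_weight(200.0, Y, PROP) > 0


class TestConfigValidation:
    def test_bin_geometry_must_be_integral(self):
        with pytest.raises(ValueError):
            SGTableConfig(t_min=0.0, t_max=1.0005, bin_width=0.001 * 3)

    def test_m_and_threshold(self):
        with pytest.raises(ValueError):
            SGTableConfig(m=1)
        with pytest.raises(ValueError):
            SGTableConfig(cv_threshold=0.0)
        with pytest.raises(ValueError):
            SGTableConfig(cv_mode="bogus")

    def test_tiny_n_draws_refused(self):
        with pytest.raises(ValueError):
            build_sg_table(SGTableConfig(n_draws=500))


class TestBuild:
    def test_tail_monotone_and_bounded(self, sg_table_1e6):
        t = sg_table_1e6
        finite = np.isfinite(t.log10_tail)
        assert np.all(np.diff(t.log10_tail[finite]) <= 1e-12)
        upto = t.bin_centers <= t.precision_cutoff
        g = 10.0 ** t.log10_tail[upto]
        assert np.all((g > 0) & (g <= 1))
        assert t.t_min <= t.precision_cutoff <= t.t_max

    def test_reproducible(self):
        a = build_sg_table(SGTableConfig(n_draws=10**5, seed=5))
        b = build_sg_table(SGTableConfig(n_draws=10**5, seed=5))
        np.testing.assert_array_equal(a.log10_tail, b.log10_tail)
        assert a.precision_cutoff == b.precision_cutoff

    def test_pivotality_under_affine_reparameterization(self):
        """The SG_m law does not depend on the generating (mu, lam).

        Re-expressing both the null and the proposal through the same
        affine map x -> a x + b must reproduce the same studentized draws,
        hence the same table, bin for bin.
        """
        base = build_sg_table(SGTableConfig(n_draws=10**5, seed=8))
        a_map, b_map = 1 / 6, 7.0  # sends Gumbel(0, 1/3) to Gumbel(7, 2)
        moved = build_sg_table(SGTableConfig(
            n_draws=10**5, seed=8,
            y_params=GumbelParams(b_map, (1 / 3) / a_map),
            proposal_params=GumbelParams(a_map * 33.0 + b_map, (1 / 15) / a_map)))
        np.testing.assert_allclose(moved.log10_tail, base.log10_tail,
                                   rtol=1e-8, atol=1e-10)

    def test_total_mass_matches_plain_monte_carlo(self, sg_table_1e6):
        """Sum of all bin weights / N estimates P(T in [t_min, t_max)).

        The bulk (lowest bins) is where the shifted proposal is thinnest,
        so the comparison budget uses the builder's own standard error for
        the importance-sampling side plus the binomial error of the plain
        side.
        """
        table = sg_table_1e6
        mass = 10.0 ** table.log10_tail[0]  # G at the lowest bin = all mass
        rng = np.random.default_rng(10)
        n = 4 * 10**5
        m = table.m
        plain_hits = 0
        for _ in range(4):
            c = n // 4
            y = -np.log(-np.log(rng.random((c, m)))) / table.y_params.lam
            s = -np.log(-np.log(rng.random(c))) / table.y_params.lam
            t = (s - y.mean(axis=1)) / y.std(axis=1, ddof=1)
            plain_hits += int(((t >= table.t_min) & (t < table.t_max)).sum())
        plain = plain_hits / n
        se = np.hypot(np.sqrt(plain * (1 - plain) / n), table.tail_se[0])
        assert mass == pytest.approx(plain, abs=4 * se)

    def test_lookup_step_semantics(self, sg_table_1e6):
        t = sg_table_1e6
        assert t.tail(0.0) == 1.0
        assert t.tail(-3.0) == 1.0
        assert t.tail(t.precision_cutoff + 5.0) == t.tail_at_cutoff
        # within one bin the lookup is flat
        assert t.tail(1.0001) == t.tail(1.0009)


class TestPrecisionCutoff:
    def test_identical_weights_qualify_everywhere(self):
        # zero SD in every tail -> CV = 0 -> the top bin wins
        weights = [np.ones(4), np.ones(4), np.ones(4)]
        tail = np.array([12 / 20, 8 / 20, 4 / 20])
        centers = np.array([0.5, 1.5, 2.5])
        assert precision_cutoff(weights, tail, centers, 0.01) == 2.5

    def test_hand_built_three_bins(self):
        """Weights {1,1}, {1,3}, {2}; N = 8.

        Tail collections (bin and above): {1,1,1,3,2}, {1,3,2}, {2}.
        Sample SDs: 0.8944, 1.0, undefined.  G = 1.0, 0.75, 0.25.
        CVs: 0.8944, 1.3333, -.  Thresholds pick the largest qualifying
        bin: 1.0 admits only bin 0; 1.5 admits bin 1.
        """
        weights = [np.array([1.0, 1.0]), np.array([1.0, 3.0]), np.array([2.0])]
        tail = np.array([8.0, 6.0, 2.0]) / 8.0
        centers = np.array([0.5, 1.5, 2.5])
        assert precision_cutoff(weights, tail, centers, 1.0) == 0.5
        assert precision_cutoff(weights, tail, centers, 1.5) == 1.5
        # nothing qualifies at a stringent threshold -> t_min (lower edge)
        assert precision_cutoff(weights, tail, centers, 0.1) == 0.0

    def test_fewer_than_two_tail_weights_everywhere(self):
        weights = [np.array([]), np.array([]), np.array([1.0])]
        tail = np.array([0.1, 0.1, 0.1])
        centers = np.array([0.5, 1.5, 2.5])
        assert precision_cutoff(weights, tail, centers, 0.01) == 0.0

    def test_cutoff_grows_with_draws(self):
        """More Monte-Carlo draws extend the trusted range of the table."""
        small = build_sg_table(SGTableConfig(n_draws=2 * 10**5, seed=3))
        big = build_sg_table(SGTableConfig(n_draws=10**6, seed=3))
        assert big.precision_cutoff > small.precision_cutoff


class TestSerialization:
    def test_round_trip_bit_identical(self, sg_table_1e6):
        buf = io.StringIO()
        save_table(sg_table_1e6, buf)
        buf.seek(0)
        loaded = load_table(buf)
        np.testing.assert_array_equal(loaded.log10_tail, sg_table_1e6.log10_tail)
        np.testing.assert_array_equal(loaded.tail_se, sg_table_1e6.tail_se)
        for attr in ("m", "t_min", "bin_width", "precision_cutoff",
                     "tail_at_cutoff", "n_draws", "seed", "cv_threshold",
                     "y_params", "proposal_params", "n_dropped"):
            assert getattr(loaded, attr) == getattr(sg_table_1e6, attr)

    def test_corrupted_header_names_line(self, sg_table_1e6):
        buf = io.StringIO()
        save_table(sg_table_1e6, buf)
        lines = buf.getvalue().splitlines(True)
        lines[3] = "# broken header line without separator\n"
        with pytest.raises(TableFormatError, match="line 4"):
            load_table(io.StringIO("".join(lines)))

    def test_version_mismatch(self, sg_table_1e6):
        buf = io.StringIO()
        save_table(sg_table_1e6, buf)
        text = buf.getvalue().replace("sg-table-format: 1", "sg-table-format: 99", 1)
        with pytest.raises(TableFormatError, match="version"):
            load_table(io.StringIO(text))

    def test_m_mismatch(self, sg_table_1e6):
        buf = io.StringIO()
        save_table(sg_table_1e6, buf)
        buf.seek(0)
        with pytest.raises(TableMismatchError, match="m=50"):
            load_table(buf, m=20)
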