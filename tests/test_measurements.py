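import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adipoflux.measurements import (
    MID,
    NATURAL_ABUNDANCE,
    absolute_dnl,
    correct_mid,
    correction_matrix,
    desaturation_index,
    exchange_rate,
    mpe,
    parse_formula,
    read_mid_table,
    write_mid_table,
)


def brute_force_fragment_distribution(counts: dict[str, int], n_labeled: int, length: int):
    """Independent oracle: enumerate every isotope assignment of every atom
    and accumulate the mass-shift distribution."""
    atoms = []
    for el, cnt in counts.items():
        cnt = cnt - n_labeled if el == "C" else cnt
        atoms.extend([el] * cnt)
    dist = np.zeros(length)
    choices = [range(len(NATURAL_ABUNDANCE[el])) for el in atoms]
    for combo in itertools.product(*choices):
        shift = n_labeled + sum(combo)
        if shift >= length:
            continue
        p = 1.0
        for el, iso in zip(atoms, combo):
            p *= NATURAL_ABUNDANCE[el][iso]
        dist[shift] += p
    return dist


class TestCorrectionMatrix:
    def test_identity_when_abundances_zero(self):
        pure = {el: tuple([1.0] + [0.0] * (len(v) - 1))
                for el, v in NATURAL_ABUNDANCE.items()}
        M = correction_matrix("C3", 3, abundances=pure)
        np.testing.assert_allclose(M, np.eye(4), atol=1e-15)

    @pytest.mark.parametrize("formula,n", [("CO2", 1), ("C3H6O3", 3)])
    def test_columns_match_enumeration_oracle(self, formula, n):
        counts = parse_formula(formula)
        M = correction_matrix(formula, n, n_rows=n + 2)
        for j in range(n + 1):
            expected = brute_force_fragment_distribution(counts, j, n + 2)
            np.testing.assert_allclose(M[:, j], expected, atol=1e-12)

    def test_labeled_carbons_cannot_lighten_the_fragment(self):
        M = correction_matrix("C2H4O2", 2, n_rows=4)
        assert M[0, 2] == 0.0 and M[1, 2] == 0.0

    def test_columns_sum_below_one_by_truncation(self):
        M = correction_matrix("C16H32O2Si", 16)
        assert (M.sum(axis=0) <= 1.0 + 1e-12).all()

    def test_backbone_exceeding_formula_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            correction_matrix("C2O2", 3)


class TestCorrectMid:
    def test_unlabeled_standard_recovers_delta(self):
        M = correction_matrix("C5H9NO2Si2", 5, n_rows=8)
        mid = correct_mid(M[:, 0], "C5H9NO2Si2", 5)
        np.testing.assert_allclose(mid.fractions, np.eye(6)[0], atol=1e-9)

    def test_forward_then_invert_round_trip(self):
        truth = np.array([0.25, 0.25, 0.5])
        M = correction_matrix("C2H6OSi", 2, n_rows=5)
        raw = M @ truth
        mid = correct_mid(raw, "C2H6OSi", 2)
        np.testing.assert_allclose(mid.fractions, truth, atol=1e-9)

    def test_small_negative_noise_is_clipped_to_simplex(self):
        M = correction_matrix("C2H6OSi", 2, n_rows=5)
        raw = M @ np.array([0.7, 0.2, 0.1])
        raw[3] = -1e-4
        mid = correct_mid(raw, "C2H6OSi", 2)
        assert mid.fractions.min() >= 0
        assert abs(mid.fractions.sum() - 1) < 1e-9

    def test_all_zero_raw_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            correct_mid(np.zeros(4), "C3", 3)

    def test_large_negative_raw_rejected(self):
        with pytest.raises(ValueError, match="below"):
            correct_mid(np.array([0.5, -0.2, 0.7]), "C2", 2)


class TestMPE:
    @pytest.mark.parametrize("fractions,expected", [
        ([1, 0, 0], 0.0),
        ([0, 0, 1], 100.0),
        ([0.5, 0.25, 0.25], 37.5),
    ])
    def test_printed_formula_cases(self, fractions, expected):
        mid = MID("x", "f", 2, np.array(fractions, float))
        assert mpe(mid) == pytest.approx(expected, abs=1e-12)

    def test_zero_backbone_rejected(self):
        with pytest.raises(ValueError):
            mpe(np.array([1.0]), n_backbone=0)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=3, max_size=7))
    def test_bounded_and_linear(self, weights):
        w = np.asarray(weights)
        if w.sum() <= 0:
            return
        frac = w / w.sum()
        n = len(frac) - 1
        value = mpe(frac, n_backbone=n)
        assert 0.0 <= value <= 100.0
        # linearity: mpe of a mixture is the mixture of mpes
        other = np.eye(len(frac))[0]
        mix = 0.3 * frac + 0.7 * other
        assert mpe(mix, n_backbone=n) == pytest.approx(
            0.3 * value + 0.7 * mpe(other, n_backbone=n), abs=1e-9)


class TestExchangeRates:
    def test_no_concentration_change_means_zero_flux(self):
        assert exchange_rate(10.0, 10.0, 1000.0, 48.0).flux == 0.0

    def test_glucose_uptake_arithmetic(self):
        meas = exchange_rate(25.0, 20.0, 1000.0, 48.0, direction="uptake")
        assert meas.flux == pytest.approx(104.1667, abs=1e-3)

    def test_lactate_secretion_arithmetic(self):
        meas = exchange_rate(0.0, 10.0, 1000.0, 48.0, direction="auto")
        assert meas.direction == "secretion"
        assert meas.flux == pytest.approx(208.3333, abs=1e-3)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0, 50), st.floats(0, 50))
    def test_uptake_secretion_antisymmetry(self, fresh, spent):
        up = exchange_rate(fresh, spent, 500.0, 24.0, direction="uptake")
        sec = exchange_rate(fresh, spent, 500.0, 24.0, direction="secretion")
        assert up.flux == pytest.approx(-sec.flux, abs=1e-9)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            exchange_rate(1.0, 1.0, 100.0, 0.0)


class TestFattyAcidSummaries:
    def test_desaturation_index_values(self):
        out = desaturation_index({"C16:1": 2, "C16:0": 8, "C18:1": 3, "C18:0": 6})
        assert out["C16:1/C16:0"] == pytest.approx(0.25)
        assert out["C18:1/C18:0"] == pytest.approx(0.5)

    def test_desaturation_missing_key(self):
        with pytest.raises(KeyError):
            desaturation_index({"C16:1": 1, "C16:0": 1})

    def test_absolute_dnl(self):
        out = absolute_dnl({"C16:0": 0.35, "C15:0": 0.0}, {"C16:0": 120.0, "C15:0": 10.0})
        assert out["C16:0"] == pytest.approx(42.0)
        assert out["C15:0"] == 0.0
        assert out["total"] == pytest.approx(42.0)

    def test_absolute_dnl_rejects_fraction_outside_unit_interval(self):
        with pytest.raises(ValueError):
            absolute_dnl({"C16:0": 1.2}, {"C16:0": 1.0})


class TestCsvIO:
    def test_mid_table_round_trip(self, tmp_path):
        mids = [
            MID("CIT.m", "full", 6, np.array([0.4, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])),
            MID("PYR.c", "full", 3, np.array([0.7, 0.1, 0.1, 0.1])),
        ]
        path = tmp_path / "mids.csv"
        write_mid_table(mids, path)
        back = read_mid_table(path)
        assert [m.metabolite for m in back] == ["CIT.m", "PYR.c"]
        np.testing.assert_allclose(back[0].fractions, mids[0].fractions)
        np.testing.assert_allclose(back[1].sd, mids[1].sd)
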