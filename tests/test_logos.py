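"""Logo matrices, differential logos and contingency statistics."""

import numpy as np
import pandas as pd
import pytest

from phosphocycle.logos import (
    MAX_IC_BITS,
    acceptor_category_counts,
    background_from_sequences,
    build_logo,
    chi2_late_vs_rest,
    differential_logo,
    information_logo,
    logo_to_frame,
    position_probability_matrix,
    ptp_fold_change,
)
from phosphocycle.simulate import YEAST_AA_FREQS
from phosphocycle.timecourse import TimecourseProfile


class TestPPM:
    def test_identical_windows_unit_probabilities(self):
        ppm = position_probability_matrix(["AAAAAASPAKRAA"] * 5)
        assert ppm.loc[0, "S"] == 1.0
        assert ppm.loc[1, "P"] == 1.0
        assert ppm.loc[3, "K"] == 1.0

    def test_half_split_at_single_position(self):
        ppm = position_probability_matrix(["AAAAAASPAKRAA", "AAAAAATPAKRAA"])
        assert ppm.loc[0, "S"] == 0.5 and ppm.loc[0, "T"] == 0.5

    def test_columns_normalized(self):
        rng = np.random.default_rng(0)
        windows = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 13)) for _ in range(30)]
        ppm = position_probability_matrix(windows)
        assert np.allclose(ppm.sum(axis=1), 1.0, atol=1e-9)

    def test_padding_excluded_from_denominator(self):
        ppm = position_probability_matrix(["______SPAKRAA", "AAAAAASPAKRAA"])
        # position -6: one '_' and one 'A' -> A has probability 1 among residues
        assert ppm.loc[-6, "A"] == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            position_probability_matrix(["SHORT"])

    def test_order_invariance(self):
        windows = ["AAAAAASPAKRAA", "KKKKKKTPKKKKK", "RRRRRRSARRRRR"]
        a = build_logo(windows).letter_heights
        b = build_logo(windows[::-1]).letter_heights
        pd.testing.assert_frame_equal(a, b)


class TestInformation:
    def test_uniform_column_zero_bits(self):
        ppm = position_probability_matrix(["AAAAAASPAKRAA"])
        ppm.loc[-6] = 1.0 / 20
        logo = information_logo(ppm)
        assert logo.information.loc[-6] == pytest.approx(0.0, abs=1e-12)

    def test_single_letter_column_max_bits(self):
        logo = information_logo(position_probability_matrix(["AAAAAASPAKRAA"]))
        assert logo.information.loc[0] == pytest.approx(MAX_IC_BITS)
        assert MAX_IC_BITS == pytest.approx(np.log2(20))

    def test_half_half_column_entropy_arithmetic(self):
        logo = information_logo(
            position_probability_matrix(["AAAAAASPAKRAA", "AAAAAATPAKRAA"])
        )
        assert logo.information.loc[0] == pytest.approx(np.log2(20) - 1.0)

    def test_bounds_and_heights(self):
        rng = np.random.default_rng(1)
        windows = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 13)) for _ in range(20)]
        logo = build_logo(windows)
        assert ((logo.information >= 0) & (logo.information <= MAX_IC_BITS)).all()
        expected = logo.probabilities.mul(logo.information, axis=0)
        pd.testing.assert_frame_equal(logo.letter_heights, expected)


class TestDifferentialLogo:
    def test_direct_formula_value(self):
        # p_bg=0.05, p_fg=0.5, n=100 -> z = 0.45/sqrt(0.05*0.95/100) = 20.65
        fg = ["AAAAAASPAKRAA"] * 50 + ["CAAAAASPAKRAA"] * 50
        bg = {aa: 0.05 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        out = differential_logo(fg, bg).set_index(["position", "residue"])
        assert out.loc[(-6, "C"), "z"] == pytest.approx(20.6474, abs=1e-3)

    def test_matched_frequency_zero_z(self):
        fg = ["AAAAAASPAKRAA"]
        bg = {aa: 0.0 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        bg["A"] = 0.5
        bg["S"] = 0.5
        out = differential_logo(fg, bg).set_index(["position", "residue"])
        # p_fg(A at -6) = 1 vs p_bg 0.5: nonzero; S at 0 = 1 vs 0.5: same sign
        assert out.loc[(-6, "A"), "z"] > 0
        assert out.loc[(-6, "C"), "z"] == pytest.approx(0.0)  # p_bg = 0 and p_fg = 0

    def test_infinite_z_sentinel_flagged(self):
        fg = ["CAAAAASPAKRAA"]
        bg = {aa: 0.0 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        bg["A"] = 1.0
        out = differential_logo(fg, bg).set_index(["position", "residue"])
        row = out.loc[(-6, "C")]
        assert np.isinf(row["z"]) and row["infinite_z"]

    def test_null_foreground_few_significant_cells(self):
        rng = np.random.default_rng(11)
        letters = np.array(list(YEAST_AA_FREQS))
        probs = np.array(list(YEAST_AA_FREQS.values()))
        probs = probs / probs.sum()
        fg = ["".join(rng.choice(letters, 13, p=probs)) for _ in range(500)]
        bg = dict(zip(letters, probs))
        out = differential_logo(fg, bg)
        assert (out["p"] < 0.05).mean() <= 0.07  # ~5% expected under the null

    def test_background_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            differential_logo(["AAAAAASPAKRAA"], {aa: 0.1 for aa in "ACDEFGHIKLMNPQRSTVWY"})


def test_background_from_sequences_counts():
    bg = background_from_sequences(["AAC", "CG"])
    assert bg["A"] == pytest.approx(0.4)
    assert bg["C"] == pytest.approx(0.4)
    assert bg["G"] == pytest.approx(0.2)


def _profile(site_id, category, labels):
    values = pd.Series(np.linspace(0.1, 1.0, 10), index=range(0, 100, 10))
    return TimecourseProfile(
        site_id=site_id, acceptor="T" if "pTP" in labels else "S",
        motif_labels=frozenset(labels), raw=values, normalized=values,
        increasing=category != "stable",
        peak_time=None, timing_category=category,
    )


class TestContingency:
    def test_empty_profiles_zero_table(self):
        table = acceptor_category_counts([])
        assert (table.to_numpy() == 0).all()

    def test_handcrafted_counts(self):
        profiles = [
            _profile("a", "early", {"minimal_cdk", "pSP"}),
            _profile("b", "early", {"minimal_cdk", "pTP"}),
            _profile("c", "late", {"minimal_cdk", "pTP"}),
            _profile("d", "late", {"minimal_cdk", "pTP"}),
            _profile("e", "stable", {"minimal_cdk", "pSP"}),
            _profile("f", "intermediate", {"aurora"}),  # not a Cdk site
        ]
        table = acceptor_category_counts(profiles)
        assert table.loc["early", "pSP"] == 1 and table.loc["early", "pTP"] == 1
        assert table.loc["late", "pTP"] == 2 and table.loc["late", "pSP"] == 0
        assert table.loc["stable", "pSP"] == 1
        assert table.to_numpy().sum() == 5  # non-Cdk site excluded

    def test_fold_change_printed_counts(self):
        table = pd.DataFrame(
            {"pTP": [3, 0, 14, 0], "pSP": [22, 0, 12, 0]},
            index=["early", "intermediate", "late", "stable"],
        )
        assert ptp_fold_change(table) == pytest.approx((14 / 26) / (3 / 25))
        assert ptp_fold_change(table) == pytest.approx(4.487, abs=0.001)

    def test_fold_change_identical_proportions(self):
        table = pd.DataFrame(
            {"pTP": [2, 0, 4, 0], "pSP": [8, 0, 16, 0]},
            index=["early", "intermediate", "late", "stable"],
        )
        assert ptp_fold_change(table) == pytest.approx(1.0)

    def test_fold_change_zero_numerator_guard(self):
        table = pd.DataFrame(
            {"pTP": [0, 0, 4, 0], "pSP": [8, 0, 16, 0]},
            index=["early", "intermediate", "late", "stable"],
        )
        with pytest.raises(ValueError, match="fold undefined"):
            ptp_fold_change(table)

    def test_chi2_uniform_proportions_near_zero(self):
        table = pd.DataFrame(
            {"pTP": [5, 5, 5, 5], "pSP": [15, 15, 15, 15]},
            index=["early", "intermediate", "late", "stable"],
        )
        out = chi2_late_vs_rest(table)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert out["p_raw"] == pytest.approx(1.0)

    def test_chi2_early_vs_late_example(self):
        table = pd.DataFrame(
            {"pTP": [3, 14], "pSP": [22, 12]}, index=["early", "late"]
        )
        out = chi2_late_vs_rest(table, focal="late", categories=["early", "late"])
        assert out["chi2"] == pytest.approx(10.043, abs=0.001)
        assert out["p_adjusted"] == pytest.approx(min(1.0, 4 * out["p_raw"]))

    def test_chi2_exact_fallback_on_zero_expected(self):
        table = pd.DataFrame(
            {"pTP": [0, 0, 0, 0], "pSP": [5, 5, 5, 5]},
            index=["early", "intermediate", "late", "stable"],
        )
        out = chi2_late_vs_rest(table)
        assert out["method"] == "fisher_exact"
        assert out["p_raw"] == pytest.approx(1.0)


def test_logo_to_frame_round_shape():
    logo = build_logo(["AAAAAASPAKRAA", "AAAAAATPAKRAA"])
    frame = logo_to_frame(logo)
    assert set(frame.columns) == {"position", "residue", "probability", "height_bits"}
    assert len(frame) == 13 * 20
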