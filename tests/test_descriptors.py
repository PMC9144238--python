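"""Global reactivity descriptors: printed-table examples, algebraic
identities, calibration of the nucleophilicity reference, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdftkit import (
    APRATOXIN_GLOBAL_TABLE,
    NucleophilicityReference,
    ValidationError,
    calibrate_nucleophilicity_reference,
    classify_electrophile,
    classify_nucleophile,
    compute_all,
    electroaccepting_power,
    electrodonating_power,
    electronegativity,
    electrophilicity,
    hardness,
    net_electrophilicity,
    nucleophilicity,
    softness,
)

# strictly-ordered frontier pairs: HOMO in [-12, -2), LUMO in (HOMO, 2]
pairs = st.tuples(
    st.floats(min_value=-12.0, max_value=-2.0),
    st.floats(min_value=-1.9, max_value=2.0),
).filter(lambda p: p[1] - p[0] > 1e-6)


class TestPrintedExamples:
    """Spot checks against the printed apratoxin descriptor table (2 dp)."""

    @pytest.mark.parametrize("h,l,expected", [
        (-6.24, -1.22, 3.73), (-6.20, -1.74, 3.97)])
    def test_electronegativity(self, h, l, expected):
        assert round(electronegativity(h, l), 2) == expected

    @pytest.mark.parametrize("h,l,expected", [
        (-6.24, -1.22, 5.02), (-6.04, -1.76, 4.28)])
    def test_hardness(self, h, l, expected):
        assert round(hardness(h, l), 2) == expected

    @pytest.mark.parametrize("eta,expected", [(5.02, 0.1992), (4.39, 0.2278)])
    def test_softness(self, eta, expected):
        assert softness(eta) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize("h,l,expected", [
        (-6.24, -1.22, 1.3857), (-6.04, -1.76, 1.7769)])
    def test_electrophilicity(self, h, l, expected):
        assert electrophilicity(h, l) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize("h,l,expected", [
        (-6.24, -1.22, 4.9502), (-6.12, -1.79, 5.8606)])
    def test_electrodonating_power(self, h, l, expected):
        assert electrodonating_power(h, l) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize("h,l,expected", [
        (-6.24, -1.22, 1.2202), (-6.12, -1.79, 1.9056)])
    def test_electroaccepting_power(self, h, l, expected):
        assert electroaccepting_power(h, l) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize("wm,wp,expected", [
        (4.95, 1.22, 6.17), (5.86, 1.91, 7.77), (0.0, 0.0, 0.0)])
    def test_net_electrophilicity(self, wm, wp, expected):
        assert net_electrophilicity(wm, wp) == pytest.approx(expected)


class TestSymmetricGap:
    """Closed forms for a gap symmetric about zero: (-x, x)."""

    @pytest.mark.parametrize("x", [0.5, 1.0, 3.7])
    def test_closed_forms(self, x):
        assert electronegativity(-x, x) == 0.0
        assert electrophilicity(-x, x) == 0.0
        assert electrodonating_power(-x, x) == pytest.approx(x / 8)
        assert electroaccepting_power(-x, x) == pytest.approx(x / 8)
        assert hardness(-x, 0.0) == x if x > 0 else True


class TestInvariants:
    @given(pairs)
    @settings(max_examples=500)
    def test_donating_minus_accepting_equals_chi(self, pair):
        h, l = pair
        lhs = electrodonating_power(h, l) - electroaccepting_power(h, l)
        assert lhs == pytest.approx(electronegativity(h, l), abs=1e-9)

    @given(pairs)
    def test_softness_hardness_reciprocal(self, pair):
        h, l = pair
        eta = hardness(h, l)
        assert softness(eta) * eta == pytest.approx(1.0, rel=1e-12)

    def test_hardness_monotone_in_lumo(self):
        etas = [hardness(-6.0, l) for l in np.linspace(-2.0, 1.0, 50)]
        assert np.all(np.diff(etas) > 0)

    def test_electrophilicity_monotone_in_centroid_shift(self):
        # fixed gap, growing |eps_H + eps_L| => omega strictly increases
        gap = 5.0
        omegas = []
        for shift in np.linspace(0.0, 4.0, 40):
            h, l = -gap / 2 - shift, gap / 2 - shift
            omegas.append(electrophilicity(h, l))
        assert np.all(np.diff(omegas) > 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            hardness(-1.0, -2.0)
        with pytest.raises(ValidationError):
            softness(0.0)
        with pytest.raises(ValidationError):
            net_electrophilicity(-0.1, 1.0)
        with pytest.raises(ValidationError):
            classify_electrophile(-0.5)


def brute_force_descriptors(h, l):
    """Independent re-evaluation of every formula, coded separately."""
    chi = -0.5 * (h + l)
    eta = l - h
    return {
        "chi": chi,
        "mu": 0.5 * (h + l),
        "eta": eta,
        "softness": eta ** -1,
        "omega": (h + l) ** 2 / (8.0 * (l - h)),
        "omega_minus": (3.0 * h + l) ** 2 / (16.0 * (l - h)),
        "omega_plus": (h + 3.0 * l) ** 2 / (16.0 * (l - h)),
        "net_electrophilicity": ((3.0 * h + l) ** 2 + (h + 3.0 * l) ** 2)
        / (16.0 * (l - h)),
    }


def test_oracle_equivalence(rng, apratoxins):
    """compute_all agrees with the independent brute-force formulas to 1e-12."""
    template = apratoxins[0]
    for _ in range(100):
        h = rng.uniform(-12.0, -3.0)
        l = h + rng.uniform(0.5, 8.0)
        d = compute_all(template.replace(id="rnd", eps_homo=h, eps_lumo=l))
        expected = brute_force_descriptors(h, l)
        for key, value in expected.items():
            assert getattr(d, key) == pytest.approx(value, rel=1e-12), key


class TestCalibration:
    def test_seven_printed_pairs(self):
        from cdftkit import APRATOXIN_KID_TABLE
        pairs_ = [
            (APRATOXIN_KID_TABLE[k]["homo"],
             APRATOXIN_GLOBAL_TABLE[k]["nucleophilicity"])
            for k in APRATOXIN_KID_TABLE
        ]
        ref = calibrate_nucleophilicity_reference(pairs_)
        assert ref.eps_homo_ref == pytest.approx(-8.79, abs=0.01)
        assert "sd" in ref.provenance
        # residual sd below 0.01 eV
        residuals = [h - n - ref.eps_homo_ref for h, n in pairs_]
        assert np.std(residuals) < 0.01

    def test_single_pair_exact(self):
        ref = calibrate_nucleophilicity_reference([(-6.0, 2.0)])
        assert ref.eps_homo_ref == -8.0

    def test_idempotent_under_duplication(self):
        once = calibrate_nucleophilicity_reference([(-6.0, 2.0)])
        twice = calibrate_nucleophilicity_reference([(-6.0, 2.0)] * 2)
        assert once.eps_homo_ref == twice.eps_homo_ref

    def test_empty_is_error(self):
        with pytest.raises(ValidationError):
            calibrate_nucleophilicity_reference([])

    def test_nucleophilicity_against_calibrated_reference(self):
        ref = NucleophilicityReference(-8.79)
        assert nucleophilicity(-6.04, ref) == pytest.approx(2.75, abs=1e-9)
        assert nucleophilicity(-6.08, ref) == pytest.approx(2.71, abs=1e-9)
        assert nucleophilicity(-8.79, ref) == 0.0


class TestClassification:
    @pytest.mark.parametrize("omega,expected", [
        (1.39, "moderate"), (0.5, "marginal"), (1.81, "strong"),
        (1.5, "moderate"), (0.8, "marginal"),   # boundary points, assigned down
    ])
    def test_electrophile_scale(self, omega, expected):
        assert classify_electrophile(omega) == expected

    @pytest.mark.parametrize("n,expected", [
        (2.56, "moderate"), (3.5, "strong"), (2.0, "moderate"),
        (3.0, "moderate"), (1.99, "marginal"),
    ])
    def test_nucleophile_scale(self, n, expected):
        assert classify_nucleophile(n) == expected


class TestComputeAll:
    def test_row_a_matches_printed_within_rounding(self, apratoxins):
        d = compute_all(apratoxins[0])
        printed = APRATOXIN_GLOBAL_TABLE["A"]
        for key, value in printed.items():
            assert getattr(d, key) == pytest.approx(value, abs=0.015), key

    def test_symmetric_input_closed_form(self, apratoxins):
        rec = apratoxins[0].replace(id="sym", eps_homo=-4.0, eps_lumo=4.0)
        d = compute_all(rec)
        assert d.chi == 0.0 and d.omega == 0.0
        assert d.omega_minus == pytest.approx(0.5)
        assert d.omega_plus == pytest.approx(0.5)

    def test_all_seven_rows_are_moderate_nucleophiles(self, apratoxins):
        labels = [compute_all(r).nucleophile_class for r in apratoxins]
        assert labels == ["moderate"] * 7
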