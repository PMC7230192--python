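"""Cross engine: gamete tables, offspring distributions, distortion limits.

The brute-force oracle below re-derives every offspring distribution from
its own hard-coded gamete tables (balanced trivalent resolutions written
out by hand), independently of the implementation's rule table.
"""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoxy.karyotype import (
    Element,
    Hypothesis,
    Karyomorph,
    Sex,
    SexComplement,
    ViabilityModel,
    classify_karyomorph,
    phenotype,
)
from neoxy.meiosis import (
    CrossParameters,
    UnsupportedCrossError,
    cross,
    daughter_karyomorph_distribution,
    expected_sex_ratio,
    gametes,
    nonviable_fraction,
)

X1, X2, X3, Y = Element.X1, Element.X2, Element.X3, Element.Y
A, STD = Hypothesis.MECH_A, Hypothesis.STANDARD
KI, KII, KIII, KIV = (
    Karyomorph.KI,
    Karyomorph.KII,
    Karyomorph.KIII,
    Karyomorph.KIV,
)


def C(*elems):
    return SexComplement(elems)


# hand-written gamete tables for the oracle (s = X1-/X2-class probability)
def oracle_gametes(karyomorph, xy_female, s_kii=0.5, s_kiii=0.5):
    if xy_female:
        return {
            KI: [(C(X1, X3), 0.5), (C(Y, X3), 0.5)],
            KII: [(C(X1, X3), s_kii), (C(X2), 1 - s_kii)],
            KIII: [(C(X2), s_kiii), (C(X3, Y), 1 - s_kiii)],
            KIV: [(C(X1, X3), 1.0)],
        }[karyomorph]
    return {
        KI: [(C(X1), 0.5), (C(Y), 0.5)],
        KII: [(C(X1), s_kii), (C(X2), 1 - s_kii)],
        KIII: [(C(X2), s_kiii), (C(), 1 - s_kiii)],
        KIV: [(C(X1), 1.0)],
    }[karyomorph]


def oracle_cross(dam, hypothesis, params):
    """Explicit (dam gamete, sire gamete) enumeration, fertilization
    weights, viability and renormalization — all recomputed here."""
    xyf = hypothesis.xy_female
    dam_g = oracle_gametes(dam, xyf, params.s_kii, params.s_kiii)
    sire_g = oracle_gametes(KI, xyf)
    wx, wy = params.w_x1.get(dam, 1.0), params.w_y.get(dam, 1.0)
    sire_w = [(g, p * (wy if Y in g else wx)) for g, p in sire_g]
    tot = sum(p for _, p in sire_w)
    sire_w = [(g, p / tot) for g, p in sire_w]
    model = ViabilityModel.for_hypothesis(hypothesis, params.v_x1x1)
    raw, viab = {}, {}
    for dg, dp in dam_g:
        for sg, sp in sire_w:
            z = dg + sg
            raw[z] = raw.get(z, 0.0) + dp * sp
            viab[z] = model.weight(z)
    live = sum(raw[z] * viab[z] for z in raw)
    norm = {z: raw[z] * viab[z] / live for z in raw} if live else {}
    return raw, viab, norm


def params_strategy():
    weights = st.floats(0.01, 100.0, allow_nan=False)
    fracs = st.floats(0.0, 1.0, allow_nan=False)
    return st.builds(
        lambda wy2, wy3, wy4, s2, s3, v: CrossParameters(
            w_y={KII: wy2, KIII: wy3, KIV: wy4},
            s_kii=s2,
            s_kiii=s3,
            v_x1x1=v,
        ),
        weights, weights, weights, fracs, fracs, fracs,
    )


class TestGametes:
    def test_kiv_dam_single_class(self):
        g = gametes(KIV, Sex.FEMALE)
        assert dict(g.items()) == {C(X1, X3): 1.0}

    def test_kii_dam_balanced_trivalent(self):
        g = dict(gametes(KII, Sex.FEMALE).items())
        assert g == {C(X1, X3): 0.5, C(X2): 0.5}

    def test_kiii_dam_balanced_trivalent(self):
        g = dict(gametes(KIII, Sex.FEMALE).items())
        assert g == {C(X2): 0.5, C(X3, Y): 0.5}

    def test_standard_regime_drops_acrocentrics(self):
        g = dict(gametes(KIII, Sex.FEMALE, hypothesis=STD).items())
        assert g == {C(X2): 0.5, C(): 0.5}

    def test_sex_must_match_hypothesis_phenotype(self):
        with pytest.raises(UnsupportedCrossError):
            gametes(KIII, Sex.MALE)  # KIII is female under XY-female rules

    def test_unlisted_karyomorph_rejected(self):
        with pytest.raises(UnsupportedCrossError):
            gametes(Karyomorph.UNLISTED, Sex.FEMALE)

    def test_probabilities_sum_to_one_at_extreme_s(self):
        p = CrossParameters(s_kii=1.0)
        g = dict(gametes(KII, Sex.FEMALE, p).items())
        assert g == {C(X1, X3): 1.0}


class TestCrossAgainstOracle:
    @pytest.mark.parametrize("dam", [KII, KIII, KIV])
    @pytest.mark.parametrize("hypothesis", list(Hypothesis))
    def test_matches_brute_force_enumeration(self, dam, hypothesis):
        params = CrossParameters(
            w_y={KII: 2.0, KIII: 0.5, KIV: 3.0}, s_kii=0.4, s_kiii=0.7,
            v_x1x1=0.6,
        )
        raw, viab, norm = oracle_cross(dam, hypothesis, params)
        dist = cross(dam, KI, hypothesis, params)
        got = {
            row["zygote"]: (row["raw_p"], row["viability"], row["norm_p"])
            for _, row in dist.table.iterrows()
        }
        assert set(got) == {str(z) for z in raw}
        for z in raw:
            g_raw, g_v, g_norm = got[str(z)]
            assert g_raw == pytest.approx(raw[z], abs=1e-15)
            assert g_v == pytest.approx(viab[z], abs=1e-15)
            assert g_norm == pytest.approx(norm.get(z, 0.0), abs=1e-15)

    @settings(max_examples=30, deadline=None)
    @given(params_strategy(), st.sampled_from([KII, KIII, KIV]),
           st.sampled_from(list(Hypothesis)))
    def test_raw_sums_to_one_and_norm_over_viable(self, params, dam, hyp):
        dist = cross(dam, KI, hyp, params)
        assert dist.table["raw_p"].sum() == pytest.approx(1.0, abs=1e-12)
        live = dist.table["norm_p"].sum()
        assert live == pytest.approx(1.0, abs=1e-12) or live == 0.0

    @settings(max_examples=30, deadline=None)
    @given(params_strategy(), st.sampled_from([KII, KIII, KIV]),
           st.sampled_from(list(Hypothesis)))
    def test_zygotes_conserve_gamete_content(self, params, dam, hyp):
        dam_g = gametes(dam, Sex.FEMALE, params, hyp)
        sire_g = gametes(KI, Sex.MALE, params, hyp)
        unions = {str(dg + sg) for dg, _ in dam_g.items() for sg, _ in sire_g.items()}
        dist = cross(dam, KI, hyp, params)
        assert set(dist.table["zygote"]) == unions


class TestPredictedProportions:
    def test_kii_cross_four_classes_at_one_quarter(self):
        dist = cross(KII, KI, A)
        by_class = {
            (row["karyomorph"], row["sex"]): row["norm_p"]
            for _, row in dist.table.iterrows()
        }
        assert by_class == {
            ("KIV", "female"): pytest.approx(0.25),
            ("KI", "male"): pytest.approx(0.25),
            ("KII", "female"): pytest.approx(0.25),
            ("KIII", "female"): pytest.approx(0.25),
        }

    @pytest.mark.parametrize(
        "dam, hyp, expected",
        [
            (KII, A, 0.25),
            (KIII, A, 1 / 3),
            (KIV, A, 0.5),
        ],
    )
    def test_expected_sex_ratio(self, dam, hyp, expected):
        assert expected_sex_ratio(dam, KI, hyp) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "dam, hyp, expected",
        [
            (KIII, STD, 0.75),  # Y/0, X1/0 and X2/Y classes all lethal
            (KII, STD, 0.25),  # the X2/Y quarter
            (KIV, A, 0.0),
            (KIII, A, 0.25),  # the neo-Y/neo-Y quarter
        ],
    )
    def test_nonviable_fraction(self, dam, hyp, expected):
        assert nonviable_fraction(dam, KI, hyp) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "dam, hyp, expected",
        [
            (KIII, A, {KII: 0.5, KIII: 0.5}),
            (KIII, STD, {KII: 1.0}),  # only KII daughters possible
            (KIV, A, {KIV: 1.0}),
        ],
    )
    def test_daughter_distribution(self, dam, hyp, expected):
        got = daughter_karyomorph_distribution(dam, KI, hyp)
        assert set(got) == set(expected)
        for k, v in expected.items():
            assert got[k] == pytest.approx(v)

    def test_non_ki_sire_rejected(self):
        with pytest.raises(UnsupportedCrossError):
            cross(KII, KIV)

    def test_ki_dam_rejected(self):
        with pytest.raises(UnsupportedCrossError):
            cross(KI, KI)


class TestSpermSelectionLimits:
    def test_large_w_y_pushes_ki_sons_and_kiii_daughters_to_half(self):
        params = CrossParameters(w_y={KII: 1e9, KIII: 1.0, KIV: 1.0})
        dist = cross(KII, KI, A, params)
        assert dist.class_probability(KI, Sex.MALE) == pytest.approx(0.5, abs=1e-6)
        assert dist.class_probability(KIII, Sex.FEMALE) == pytest.approx(0.5, abs=1e-6)

    def test_zero_w_y_removes_y_sperm_classes(self):
        params = CrossParameters(w_y={KII: 0.0, KIII: 1.0, KIV: 1.0})
        dist = cross(KII, KI, A, params)
        assert dist.class_probability(KI, Sex.MALE) == 0.0
        assert dist.class_probability(KIII, Sex.FEMALE) == 0.0
        assert dist.male_fraction() == 0.0

    @settings(max_examples=25, deadline=None)
    @given(st.floats(0.01, 100.0), st.floats(0.01, 100.0))
    def test_only_sperm_weight_ratio_matters(self, w, scale):
        base = CrossParameters(w_y={KII: w, KIII: 1.0, KIV: 1.0})
        scaled = CrossParameters(
            w_x1={KII: scale, KIII: 1.0, KIV: 1.0},
            w_y={KII: w * scale, KIII: 1.0, KIV: 1.0},
        )
        a = cross(KII, KI, A, base).table
        b = cross(KII, KI, A, scaled).table
        assert a["norm_p"].tolist() == pytest.approx(b["norm_p"].tolist())

    @settings(max_examples=25, deadline=None)
    @given(params_strategy(), st.sampled_from(list(Hypothesis)))
    def test_kiv_never_among_daughters_of_kiii_dams(self, params, hyp):
        got = daughter_karyomorph_distribution(KIII, KI, hyp, params)
        assert got.get(KIV, 0.0) == 0.0

    def test_viability_renormalization_preserves_viable_ratios(self):
        full = cross(KIII, KI, A).table
        viable = full[full["viability"] > 0]
        ratios = (viable["norm_p"] / viable["raw_p"]).tolist()
        # uniform rescale by 1/(1 - lethal quarter) over viable classes
        assert ratios == pytest.approx([1 / 0.75] * len(ratios))
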