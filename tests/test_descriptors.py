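import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from parse_llps import (
    describe,
    describe_batch,
    f_ppii,
    generate_sequence,
    net_charge,
    predict_rh,
    r_model,
    scd,
    shd,
    turn_cf,
    turn_ht,
    turn_levitt,
    v_int,
    v_model,
)
from parse_llps.scales import load_scale

PPII = load_scale("ppii")
LEVITT = load_scale("levitt_turn")
CF = load_scale("chou_fasman_turn")
HT = load_scale("ht_turn_positional")
LAMBDA = load_scale("hydropathy_normalized")


# ---------------------------------------------------------------------------
# composition descriptors
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("aa", list("AGKWP"))
def test_homopolymer_means_equal_scale_values(aa):
    seq = aa * 12
    assert f_ppii(seq) == pytest.approx(PPII[aa])
    assert turn_levitt(seq) == pytest.approx(LEVITT[aa])
    assert turn_cf(seq) == pytest.approx(CF[aa])
    # every 4-residue window of a homopolymer is identical
    assert turn_ht(seq) == pytest.approx(sum(HT.positional[aa]) / 4)


def test_f_ppii_of_gp_mix_is_the_two_value_average():
    assert f_ppii("GGGGGPPPPP") == pytest.approx((PPII["G"] + PPII["P"]) / 2)


@pytest.mark.parametrize(
    "seq, expected",
    [("KKDE", 0), ("KRKR", 4), ("DDHR", -1), ("ACGT", 0), ("EEEE", -4)],
)
def test_net_charge_counts_k_r_minus_d_e(seq, expected):
    assert net_charge(seq) == expected


# ---------------------------------------------------------------------------
# R_h model and scaling exponent
# ---------------------------------------------------------------------------


def test_predict_rh_at_zero_ppii_and_charge():
    # hand evaluation: 2.16 * 100**0.503 - 0.29 * 10
    assert predict_rh(100, 0.0, 0) == pytest.approx(19.0, abs=0.05)


def test_each_added_charge_raises_rh_by_its_coefficient():
    base = predict_rh(120, 0.3, 2)
    assert predict_rh(120, 0.3, 3) - base == pytest.approx(0.26)
    # negative direction: |Q| drives the term
    assert predict_rh(120, 0.3, -3) - predict_rh(120, 0.3, -2) == pytest.approx(0.26)


def test_predict_rh_rejects_out_of_domain_ppii():
    with pytest.raises(ValueError):
        predict_rh(50, 1.0, 0)
    with pytest.raises(ValueError):
        predict_rh(50, -0.1, 0)
    with pytest.raises(ValueError):
        predict_rh(0, 0.3, 0)


@settings(deadline=None, max_examples=60)
@given(
    n=st.integers(min_value=5, max_value=5000),
    f=st.floats(min_value=0.0, max_value=0.93),
    df=st.floats(min_value=1e-4, max_value=0.05),
    q=st.integers(min_value=-30, max_value=30),
)
def test_rh_strictly_increases_in_fppii_and_charge_magnitude(n, f, df, q):
    assert predict_rh(n, f + df, q) > predict_rh(n, f, q)
    assert predict_rh(n, f, abs(q) + 1) > predict_rh(n, f, q)


def test_v_model_inverts_the_power_law():
    for n in (2, 10, 100, 5000):
        assert v_model(2.16 * n**0.5, n) == pytest.approx(0.5)
    assert v_model(2.16, 50) == 0.0
    with pytest.raises(ValueError):
        v_model(20.0, 1)


def test_v_model_recovers_the_ppii_exponent_asymptotically():
    # with charge 0 and the finite-size term switched off, the exponent
    # must come back exactly: R_h = R0 * N**e
    n = 100_000
    for f in (0.0, 0.25, 0.6):
        e = 0.503 - 0.11 * math.log(1.0 - f)
        assert v_model(2.16 * n**e, n) == pytest.approx(e, abs=1e-3)


def test_v_model_sanity_envelope_for_natural_compositions():
    rng = np.random.default_rng(42)
    for i in range(1000):
        n = int(rng.integers(30, 400))
        rec = generate_sequence("natural", n, seed=int(rng.integers(2**31)))
        d = describe(rec.seq)
        assert 0.3 < d.v_model < 0.8


# ---------------------------------------------------------------------------
# positional turn propensity
# ---------------------------------------------------------------------------


def test_turn_ht_single_window_is_the_window_mean():
    seq = "GPSG"
    expected = (
        HT.positional["G"][0]
        + HT.positional["P"][1]
        + HT.positional["S"][2]
        + HT.positional["G"][3]
    ) / 4
    assert turn_ht(seq) == pytest.approx(expected)


def test_turn_ht_two_window_enumeration():
    seq = "GPSGV"
    w1 = (
        HT.positional["G"][0]
        + HT.positional["P"][1]
        + HT.positional["S"][2]
        + HT.positional["G"][3]
    ) / 4
    w2 = (
        HT.positional["P"][0]
        + HT.positional["S"][1]
        + HT.positional["G"][2]
        + HT.positional["V"][3]
    ) / 4
    assert turn_ht(seq) == pytest.approx((w1 + w2) / 2)


def test_turn_ht_needs_four_residues():
    with pytest.raises(ValueError):
        turn_ht("GPS")


# ---------------------------------------------------------------------------
# patterning descriptors
# ---------------------------------------------------------------------------


def _shd_brute(seq):
    lam = [LAMBDA[aa] for aa in seq]
    n = len(seq)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += (lam[i] + lam[j]) / (j - i)
    return total / n


def _scd_brute(seq):
    from parse_llps.scales import load_scale

    q = [load_scale("charge")[aa] for aa in seq]
    n = len(seq)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += q[i] * q[j] * math.sqrt(j - i)
    return total / n


def test_shd_of_a_dimer_is_half_the_lambda_sum():
    assert shd("AV") == pytest.approx((LAMBDA["A"] + LAMBDA["V"]) / 2)


@pytest.mark.parametrize("seq, expected", [("KE", -0.5), ("KK", 0.5)])
def test_scd_single_pair_hand_values(seq, expected):
    assert scd(seq) == pytest.approx(expected)


def test_scd_is_zero_without_charged_residues():
    assert scd("GGSSAATTQQNN") == 0.0


def test_shd_scd_match_the_double_loop_definition():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n = int(rng.integers(5, 60))
        rec = generate_sequence("natural", n, seed=int(rng.integers(2**31)))
        assert shd(rec.seq) == pytest.approx(_shd_brute(rec.seq), rel=1e-10)
        assert scd(rec.seq) == pytest.approx(_scd_brute(rec.seq), rel=1e-10, abs=1e-12)


def test_scd_long_chain_path_agrees_with_pairwise_path():
    # charge-dense chain long enough to take the autocorrelation branch
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("KEKRDEAG"), size=3500))
    q = np.array([1 if c in "KR" else -1 if c in "DE" else 0 for c in seq])
    nz = np.nonzero(q)[0]
    assert nz.size > 2048
    gaps = np.abs(nz[:, None] - nz[None, :]).astype(float)
    prod = np.outer(q[nz], q[nz])
    iu = np.triu_indices(nz.size, k=1)
    expected = float(np.sum(prod[iu] * np.sqrt(gaps[iu])) / len(seq))
    assert scd(seq) == pytest.approx(expected, rel=1e-9)


def test_v_int_is_linear_with_the_published_coefficients():
    assert v_int(0.0, 0.0) == pytest.approx(0.701)
    assert v_int(1.0, 0.0) == pytest.approx(0.701 - 0.0423)
    assert v_int(0.0, 1.0) == pytest.approx(0.701 + 0.0074)


# ---------------------------------------------------------------------------
# permutation (in)variance and the combined descriptor set
# ---------------------------------------------------------------------------


def test_composition_descriptors_are_permutation_invariant(natural_500):
    from parse_llps import scramble

    rec = generate_sequence("natural", 150, seed=5)
    shuffled = scramble(rec, seed=99)
    assert shuffled.seq != rec.seq
    for fn in (f_ppii, net_charge, turn_levitt, turn_cf, r_model):
        assert fn(shuffled.seq) == pytest.approx(fn(rec.seq))
    d1, d2 = describe(rec.seq), describe(shuffled.seq)
    assert d1.R_h == pytest.approx(d2.R_h)
    assert d1.v_model == pytest.approx(d2.v_model)


def test_patterning_descriptors_see_residue_order():
    # blocky vs alternating charge: same composition, different SCD;
    # segregating opposite charges drives SCD more negative
    assert scd("KKKEEE") != pytest.approx(scd("KEKEKE"))
    assert scd("KKKEEE") < scd("KEKEKE") < 0 < scd("KKKKKK")
    # moving the hydrophobic patch between chain end and chain middle
    # changes SHD (the pair-distance weights depend on position)
    assert shd("IIGGGGGG") != pytest.approx(shd("GGGIIGGG"))
    # the four-position turn score is order-sensitive too
    assert turn_ht("PGSV") != pytest.approx(turn_ht("VSGP"))


def test_r_model_is_turn_over_v(natural_500):
    d = describe(natural_500.seq)
    assert d.r_model == pytest.approx(d.turn_levitt / d.v_model)
    assert d.r_model > 0


def test_describe_batch_layout(natural_records):
    df = describe_batch(natural_records[:5])
    assert list(df.columns) == [
        "id", "N", "f_PPII", "Q_net", "R_h", "v_model", "turn_levitt",
        "turn_cf", "turn_ht", "SHD", "SCD", "v_int", "r_model",
    ]
    assert len(df) == 5
    assert (df["R_h"] > 0).all()
    row = df.iloc[0]
    assert row["r_model"] == pytest.approx(row["turn_levitt"] / row["v_model"])
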