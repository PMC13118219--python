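"""Composition and codon-usage indices against hand values and brute-force
oracles written directly from the defining formulas."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mitocub.codes import CODONS, get_code
from mitocub.indices import (build_cai_weights, cai, composition_profile,
                             correlation_matrix, enc, optimal_set_indices,
                             protein_indices, rscu, HYDROPATHY)

from conftest import make_counts, random_counts


# ---------------------------------------------------------------------------
# composition


def test_composition_single_gly_codon(std_code):
    prof = composition_profile(make_counts({"GGG": 1}), std_code)
    assert prof.GC3s == 100.0 and prof.G3 == 100.0
    assert prof.A3 == prof.T3 == prof.C3 == 0.0


def test_composition_met_only_has_no_synonymous_third_positions(std_code):
    prof = composition_profile(make_counts({"ATG": 5}), std_code)
    assert math.isnan(prof.GC3s) and math.isnan(prof.A3)


def test_composition_hand_tally_positions(std_code):
    prof = composition_profile(make_counts({"AAA": 1, "GGC": 1}), std_code)
    assert prof.GC1 == prof.GC2 == prof.GC3 == prof.GC12 == 50.0


def test_composition_invariants_on_random_counts(std_code):
    rng = np.random.default_rng(11)
    for _ in range(30):
        cc = random_counts(rng, std_code, n_codons=200)
        prof = composition_profile(cc, std_code)
        assert prof.pct_A + prof.pct_T + prof.pct_G + prof.pct_C == pytest.approx(100, abs=1e-9)
        assert prof.A3 + prof.T3 + prof.G3 + prof.C3 == pytest.approx(100, abs=1e-9)
        assert prof.GC3s == pytest.approx(prof.G3 + prof.C3, abs=1e-9)
        assert prof.GC12 == (prof.GC1 + prof.GC2) / 2


# ---------------------------------------------------------------------------
# RSCU


def test_rscu_phe_family(std_code):
    r = rscu(make_counts({"TTT": 3, "TTC": 1}), std_code)
    assert r["TTT"] == pytest.approx(1.5)
    assert r["TTC"] == pytest.approx(0.5)


def test_rscu_uniform_usage_is_one(std_code):
    r = rscu(make_counts({c: 2 for c in std_code.families["L"]}), std_code)
    assert all(r[c] == pytest.approx(1.0) for c in std_code.families["L"])


def test_rscu_singleton_family_is_one(std_code):
    assert rscu(make_counts({"ATG": 7}), std_code)["ATG"] == 1.0


def test_rscu_unobserved_family_is_missing(std_code):
    r = rscu(make_counts({"TTT": 3}), std_code)
    assert math.isnan(r["GGG"])


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_rscu_family_sums_equal_family_size(std_code, seed):
    rng = np.random.default_rng(seed)
    cc = random_counts(rng, std_code, n_codons=int(rng.integers(10, 400)))
    r = rscu(cc, std_code)
    for aa, family in std_code.families.items():
        total = sum(cc[c] for c in family)
        if total > 0:
            assert sum(r[c] for c in family) == pytest.approx(len(family), abs=1e-9)


# ---------------------------------------------------------------------------
# ENC


def enc_oracle(cc, code):
    """Independent transcription of Wright's formulas (no class imputation).

    Returns (value, complete); ``complete`` is True when every degeneracy
    class had an estimable positive mean homozygosity, i.e. neither the
    imputation nor the rescaling convention could come into play.
    """
    by_size = {}
    for aa, family in code.families.items():
        k = len(family)
        if k == 1:
            continue
        n = sum(cc[c] for c in family)
        if n <= 1:
            continue
        p2 = sum((cc[c] / n) ** 2 for c in family)
        f = (n * p2 - 1) / (n - 1)
        by_size.setdefault(k, []).append(f)
    total = len([1 for f in code.families.values() if len(f) == 1])
    covered = total
    complete = True
    for k, aas in code.degeneracy_classes().items():
        if k == 1:
            continue
        fs = by_size.get(k, [])
        fbar = sum(fs) / len(fs) if fs else 0.0
        if fbar <= 0:
            complete = False
            continue
        total += len(aas) / fbar
        covered += len(aas) * k
    n_sense = len(code.sense_codons)
    if covered < n_sense:
        total *= n_sense / covered
    return min(max(total, len(code.families)), n_sense), complete


def test_enc_lower_bound_one_codon_per_family(std_code):
    counts = {family[0]: 100 for family in std_code.families.values()}
    assert enc(make_counts(counts), std_code) == pytest.approx(20.0)


def test_enc_upper_bound_uniform_usage(std_code):
    counts = {c: 500 for c in std_code.sense_codons}
    assert enc(make_counts(counts), std_code) == pytest.approx(61.0, abs=0.2)


def test_enc_matches_brute_force_oracle(std_code, t4_code):
    rng = np.random.default_rng(23)
    compared = 0
    for i in range(140):
        code = std_code if i % 2 else t4_code
        cc = random_counts(rng, code, n_codons=600)
        ref, complete = enc_oracle(cc, code)
        if complete:  # otherwise the documented imputation convention differs
            assert enc(cc, code) == pytest.approx(ref, abs=1e-9)
            compared += 1
    assert compared >= 100


def test_enc_scaling_invariance_large_n(std_code):
    # F-hat carries an O(1/n) finite-sample term, so exact scale invariance
    # only emerges in the large-n limit
    rng = np.random.default_rng(5)
    for _ in range(10):
        cc = random_counts(rng, std_code, n_codons=40_000, alpha=5.0)
        doubled = make_counts({c: 2 * k for c, k in cc.as_dict().items()})
        assert abs(enc(cc, std_code) - enc(doubled, std_code)) < 0.05


# ---------------------------------------------------------------------------
# CAI


def test_cai_all_weights_one(std_code):
    cc = make_counts({"TTT": 5, "GGA": 5})
    weights = {c: 1.0 for c in std_code.degenerate_codons}
    assert cai(cc, weights) == pytest.approx(1.0)


def test_cai_two_codon_geometric_mean(std_code):
    cc = make_counts({"TTT": 1, "TTC": 1})
    assert cai(cc, {"TTT": 0.25, "TTC": 1.0}) == pytest.approx(0.5)


def test_cai_empty_weight_table_raises(std_code):
    with pytest.raises(ValueError):
        cai(make_counts({"TTT": 1}), {})


def test_cai_matches_log_domain_oracle(std_code):
    rng = np.random.default_rng(31)
    for _ in range(100):
        ref = random_counts(rng, std_code, n_codons=500)
        weights = build_cai_weights(ref, std_code)
        cc = random_counts(rng, std_code, n_codons=150)
        # oracle: direct product over the codon stream
        prod, n = 1.0, 0
        for codon, k in cc.as_dict().items():
            if codon in weights and k:
                prod *= weights[codon] ** k
                n += k
        assert cai(cc, weights) == pytest.approx(prod ** (1 / n), rel=1e-12)


def test_cai_monotone_in_weight_substitution(std_code):
    weights = build_cai_weights(make_counts({"TTT": 9, "TTC": 1, "GGA": 5, "GGC": 5}),
                                std_code)
    low = make_counts({"TTC": 10})
    high = make_counts({"TTT": 10})
    assert cai(high, weights) >= cai(low, weights)


# ---------------------------------------------------------------------------
# CBI / FOP


def test_all_codons_optimal_gives_unity(std_code):
    cc = make_counts({"TTT": 4, "GGA": 6})
    cbi, fop = optimal_set_indices(cc, {"TTT", "GGA"}, std_code)
    assert cbi == pytest.approx(1.0) and fop == pytest.approx(1.0)


def test_random_usage_gives_zero_cbi(std_code):
    cc = make_counts({"TTT": 5, "TTC": 5})  # exactly random for a 2-fold family
    cbi, fop = optimal_set_indices(cc, {"TTT"}, std_code)
    assert cbi == pytest.approx(0.0)
    assert fop == pytest.approx(0.5)


def test_cbi_fop_hand_computation(std_code):
    # 10 codons: 6 TTT, 2 TTC (Phe), 2 GGA (Gly); optimal = {TTT, GGA}
    cc = make_counts({"TTT": 6, "TTC": 2, "GGA": 2})
    cbi, fop = optimal_set_indices(cc, {"TTT", "GGA"}, std_code)
    # N_syn = 10, N_opt = 8, N_rand = 8*(1/2) + 2*(1/4) = 4.5
    assert fop == pytest.approx(0.8)
    assert cbi == pytest.approx((8 - 4.5) / (10 - 4.5))


def test_fop_monotone_under_optimal_substitution(std_code):
    cc1 = make_counts({"TTT": 3, "TTC": 7})
    cc2 = make_counts({"TTT": 4, "TTC": 6})
    _, fop1 = optimal_set_indices(cc1, {"TTT"}, std_code)
    _, fop2 = optimal_set_indices(cc2, {"TTT"}, std_code)
    assert fop2 >= fop1


# ---------------------------------------------------------------------------
# protein indices


def test_gravy_poly_ile(std_code):
    gravy, _ = protein_indices(make_counts({"ATT": 50}), std_code)
    assert gravy == pytest.approx(4.5)


def test_aromo_poly_phe(std_code):
    _, aromo = protein_indices(make_counts({"TTT": 50}), std_code)
    assert aromo == pytest.approx(1.0)


def test_protein_indices_mixed_toy(std_code):
    cc = make_counts({"ATT": 1, "TTT": 1, "AAA": 1, "GGA": 1})  # I F K G
    gravy, aromo = protein_indices(cc, std_code)
    expected = (HYDROPATHY["I"] + HYDROPATHY["F"] + HYDROPATHY["K"] + HYDROPATHY["G"]) / 4
    assert gravy == pytest.approx(expected)
    assert aromo == pytest.approx(0.25)


# ---------------------------------------------------------------------------
# correlations


def test_correlation_self_and_antisymmetric():
    x = np.arange(11.0)
    table = pd.DataFrame({"a": x, "b": -x, "c": x ** 2})
    r, p = correlation_matrix(table)
    assert r.loc["a", "a"] == 1.0 and p.loc["a", "a"] == 0.0
    assert r.loc["a", "b"] == pytest.approx(-1.0)


def test_correlation_zero_variance_is_missing():
    table = pd.DataFrame({"a": np.arange(5.0), "b": np.ones(5)})
    r, _ = correlation_matrix(table)
    assert math.isnan(r.loc["a", "b"])


def test_correlation_matches_direct_formula_oracle():
    rng = np.random.default_rng(13)
    for _ in range(100):
        table = pd.DataFrame(rng.normal(size=(11, 3)), columns=list("abc"))
        r, p = correlation_matrix(table)
        for i in "ab":
            for j in "bc":
                if i == j:
                    continue
                x, y = table[i].to_numpy(), table[j].to_numpy()
                xm, ym = x - x.mean(), y - y.mean()
                r_ref = (xm @ ym) / math.sqrt((xm @ xm) * (ym @ ym))
                assert r.loc[i, j] == pytest.approx(r_ref, abs=1e-12)
                n = len(x)
                t = r_ref * math.sqrt((n - 2) / (1 - r_ref ** 2))
                from scipy import stats as sps
                p_ref = 2 * sps.t.sf(abs(t), n - 2)
                assert p.loc[i, j] == pytest.approx(p_ref, rel=1e-9)
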