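"""Isotope envelopes, idotp and detection calls against formula/binomial oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from enteropep.ms1_targeted import (
    ISOTOPE_ABUNDANCES,
    IsotopeEnvelope,
    MS1Error,
    TargetIon,
    call_detection,
    elemental_composition,
    idotp,
    run_ms1,
    theoretical_envelope,
    total_abundance,
)

#: Independent residue-formula table (C, H, N, O, S) for the oracle —
#: residue (water-free) compositions.
RESIDUE_FORMULAS = {
    "G": (2, 3, 1, 1, 0), "A": (3, 5, 1, 1, 0), "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0), "V": (5, 9, 1, 1, 0), "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1), "L": (6, 11, 1, 1, 0), "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0), "D": (4, 5, 1, 3, 0), "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0), "E": (5, 7, 1, 3, 0), "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0), "F": (9, 9, 1, 1, 0), "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0), "W": (11, 10, 2, 1, 0),
}


def oracle_composition(sequence: str) -> dict[str, int]:
    counts = np.array([0, 2, 0, 1, 0])  # water: H2O
    for aa in sequence:
        counts = counts + np.array(RESIDUE_FORMULAS[aa])
    # order C,H,N,O,S -- note water added as H2, O1 above (indices 1 and 3)
    return {el: int(c) for el, c in zip("CHNOS", counts) if c}


def oracle_element_distribution(element: str, n: int) -> np.ndarray:
    """Exhaustive multinomial expansion of one element's isotopologues."""
    abund = ISOTOPE_ABUNDANCES[element]
    size = n * (len(abund) - 1) + 1
    out = np.zeros(size)
    if len(abund) == 2:
        p = abund[1]
        for k in range(n + 1):
            out[k] = math.comb(n, k) * (1 - p) ** (n - k) * p ** k
        return out
    # >2 isotopes: recurse over counts of each heavy isotope, accumulating
    # the multinomial coefficient stepwise
    heavies = list(range(1, len(abund)))

    def rec(remaining, offs, coeff, prob, shift):
        if not offs:
            out[shift] += coeff * prob * abund[0] ** remaining
            return
        off = offs[0]
        for k in range(remaining + 1):
            rec(remaining - k, offs[1:], coeff * math.comb(remaining, k),
                prob * abund[off] ** k, shift + off * k)

    rec(n, heavies, 1.0, 1.0, 0)
    return out


def oracle_envelope(composition: dict[str, int], n_isotopes: int = 5) -> np.ndarray:
    dist = np.array([1.0])
    for el, n in composition.items():
        dist = np.polymul(dist, oracle_element_distribution(el, n))
    dist = dist[:n_isotopes]
    return dist / dist.sum()


class TestComposition:
    def test_glycine_is_c2h5no2(self):
        assert elemental_composition(TargetIon("G")) == {"C": 2, "H": 5, "N": 1, "O": 2}

    def test_diglycine_loses_water(self):
        assert elemental_composition(TargetIon("GG")) == {"C": 4, "H": 8, "N": 2, "O": 3}

    def test_empty_sequence_rejected(self):
        with pytest.raises(MS1Error):
            elemental_composition(TargetIon(""))

    def test_amidation_replaces_hydroxyl(self):
        base = elemental_composition(TargetIon("GG"))
        amid = elemental_composition(TargetIon("GG", frozenset({"amidated_C_term"})))
        assert amid == {"C": 4, "H": 9, "N": 3, "O": 2}
        assert amid["O"] == base["O"] - 1 and amid["N"] == base["N"] + 1

    @pytest.mark.parametrize("seq", ["GAVLK", "HSQGTFTSDYSKYLDSRRAQDFVQWLMNT", "CWMS"])
    def test_matches_formula_oracle(self, seq):
        assert elemental_composition(TargetIon(seq)) == oracle_composition(seq)


class TestTheoreticalEnvelope:
    def test_single_hydrogen(self):
        env = theoretical_envelope({"H": 1})
        assert env.intensities[0] == pytest.approx(0.999885, abs=1e-6)
        assert env.intensities[1] == pytest.approx(0.000115, abs=1e-6)

    def test_single_carbon_ratio(self):
        env = theoretical_envelope({"C": 1})
        assert env.intensities[1] / env.intensities[0] == pytest.approx(0.0107 / 0.9893, rel=1e-9)

    def test_c100_matches_binomial(self):
        env = theoretical_envelope({"C": 100})
        np.testing.assert_allclose(env.intensities, oracle_envelope({"C": 100}), atol=1e-12)

    def test_large_composition_matches_convolution_oracle(self):
        comp = {"C": 200, "H": 300, "N": 60, "O": 60, "S": 2}
        env = theoretical_envelope(comp)
        np.testing.assert_allclose(env.intensities, oracle_envelope(comp), atol=1e-9)

    def test_normalized_and_monotone_in_carbon(self):
        prev = 1.0
        for n in (1, 10, 50, 100, 200):
            env = theoretical_envelope({"C": n})
            assert env.intensities.sum() == pytest.approx(1.0, abs=1e-12)
            assert env.intensities[0] < prev
            prev = env.intensities[0]


class TestIdotp:
    def test_proportional_envelopes_score_one(self):
        t = theoretical_envelope({"C": 30, "H": 50, "N": 10, "O": 10})
        for c in (0.5, 1.0, 1e6):
            o = IsotopeEnvelope(t.intensities * c)
            assert idotp(o, t) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_envelopes_score_zero(self):
        o = IsotopeEnvelope([1, 0, 0, 0, 0])
        t = IsotopeEnvelope([0, 1, 0, 0, 0])
        assert idotp(o, t) == 0.0

    def test_hand_arithmetic(self):
        o = IsotopeEnvelope([3, 4, 0, 0, 0])
        t = IsotopeEnvelope([1, 0, 0, 0, 0])
        assert idotp(o, t) == pytest.approx(0.6)

    def test_symmetry_and_all_zero_observation(self):
        a = IsotopeEnvelope([1, 2, 3, 0, 0])
        b = IsotopeEnvelope([2, 1, 0, 0, 1])
        assert idotp(a, b) == pytest.approx(idotp(b, a))
        assert idotp(IsotopeEnvelope([0, 0, 0, 0, 0]), b) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(MS1Error, match="mismatch"):
            idotp(IsotopeEnvelope([1, 0]), IsotopeEnvelope([1, 0, 0]))

    def test_noise_degrades_score_in_expectation(self):
        t = theoretical_envelope({"C": 50, "H": 80, "N": 15, "O": 15})
        rng = np.random.default_rng(5)
        means = []
        for sd in (0.0, 0.2, 0.5, 1.0):
            scores = []
            for _ in range(1000):
                noisy = t.intensities * np.exp(rng.normal(0, sd, 5))
                scores.append(idotp(IsotopeEnvelope(noisy), t))
            means.append(np.mean(scores))
        assert all(a >= b for a, b in zip(means, means[1:]))


class TestDetection:
    def _theo(self):
        return theoretical_envelope({"C": 60, "H": 90, "N": 15, "O": 20})

    def test_total_abundance_sum(self):
        assert total_abundance(IsotopeEnvelope([1, 2, 3, 4, 5])) == 15.0
        assert total_abundance(IsotopeEnvelope([0, 0, 0, 0, 0])) == 0.0

    def test_noiseless_envelope_returns_injected_total(self):
        theo = self._theo()
        T = 123456.789
        obs = IsotopeEnvelope(theo.intensities * T)
        res = call_detection(obs, theo, rt_observed=90.0)
        assert res.detected
        assert res.abundance == pytest.approx(T, rel=1e-12)

    @pytest.mark.parametrize("score_env,rt,expected", [
        ("exact", 90.0, True),    # clean envelope, centered RT
        ("exact", 89.0, True),    # inclusive lower RT bound
        ("exact", 91.0, True),    # inclusive upper RT bound
        ("exact", 91.0001, False),
        ("exact", 120.0, False),
        ("bad", 90.0, False),     # incoherent envelope below threshold
    ])
    def test_rt_window_rules(self, score_env, rt, expected):
        theo = self._theo()
        if score_env == "exact":
            obs = IsotopeEnvelope(theo.intensities * 10.0)
        else:
            obs = IsotopeEnvelope([0.0, 0.0, 0.1, 1.0, 1.0])
        res = call_detection(obs, theo, rt_observed=rt)
        assert res.detected is expected
        if not expected:
            assert res.abundance == 0.0  # n.d. maps to zero

    def test_threshold_boundary_inclusive(self):
        # construct an observation with idotp exactly at the threshold
        theo = IsotopeEnvelope(np.array([1.0, 0, 0, 0, 0]), normalized=True)
        x = 0.88
        obs = IsotopeEnvelope([x, np.sqrt(1 - x * x), 0, 0, 0])
        assert idotp(obs, theo) == pytest.approx(0.88, abs=1e-12)
        assert call_detection(obs, theo, idotp_threshold=0.88).detected
        assert not call_detection(obs, theo, idotp_threshold=0.88 + 1e-9).detected

    def test_missing_rt_skips_window_check(self):
        theo = self._theo()
        obs = IsotopeEnvelope(theo.intensities * 2.0)
        assert call_detection(obs, theo, rt_observed=None).detected

    def test_run_ms1_table_roundtrip(self):
        target = TargetIon("HSQGTFTSDYSKYLDSRRAQDFVQWLMNT", frozenset(), 4)
        theo = theoretical_envelope(elemental_composition(target))
        env = pd.DataFrame([{
            "sequence": target.sequence, "sample": "s1",
            **{f"m{i}": v * 50.0 for i, v in enumerate(theo.intensities)},
            "rt": 90.0,
        }])
        res = run_ms1([target], env)
        assert res.iloc[0]["detected"]
        assert res.iloc[0]["abundance"] == pytest.approx(50.0)
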