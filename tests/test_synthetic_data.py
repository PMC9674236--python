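"""Simulator mechanisms against brute-force oracles, and table generation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enteropep import bundled_registry
from enteropep.synthetic_data import (
    Genotype,
    NoiseModel,
    amidate,
    default_rules,
    dibasic_boundaries,
    digest_endo,
    generate_quant_table,
    knockout_design,
    label_species,
    simulate_peptidome,
    trim_amino_dpp4,
    trim_carboxy,
)

GLUCAGON = "HSQGTFTSDYSKYLDSRRAQDFVQWLMNT"


def oracle_boundaries(seq: str) -> list[int]:
    """Independent dibasic-site finder: explicit pair scan."""
    return [i + 2 for i in range(len(seq) - 1)
            if seq[i] in "KR" and seq[i + 1] in "KR"]


class TestEndoDigestion:
    def test_single_dibasic_site(self):
        assert [f for f, _, _ in digest_endo("AAKRGG", 1.0)] == ["AAKR", "GG"]

    def test_no_basic_residues_single_fragment(self):
        assert [f for f, _, _ in digest_endo("AAGGTT", 1.0)] == ["AAGGTT"]

    def test_proglucagon_complete_digest_matches_oracle(self, proglucagon):
        chain = proglucagon.sequence[20:]  # signal removed
        cuts = [0] + [b for b in oracle_boundaries(chain) if b < len(chain)] + [len(chain)]
        expected = [chain[a:b] for a, b in zip(cuts, cuts[1:])]
        assert [f for f, _, _ in digest_endo(chain, 1.0)] == expected

    def test_partial_digest_can_release_glucagon_with_its_dibasic_pair(self, proglucagon):
        # glucagon itself contains an internal dibasic pair, so the intact
        # glucagon+KR fragment never appears in a complete digest; at partial
        # efficiency it is released whenever the flanking sites fire and the
        # internal one does not
        chain = proglucagon.sequence[20:]
        rng = np.random.default_rng(42)
        seen = set()
        for _ in range(200):
            seen.update(f for f, _, _ in digest_endo(chain, 0.5, rng))
        assert GLUCAGON + "KR" in seen
        assert GLUCAGON + "KR" not in [f for f, _, _ in digest_endo(chain, 1.0)]

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=200)
    def test_complete_digest_invariants(self, seq):
        frags = digest_endo(seq, 1.0)
        assert "".join(f for f, _, _ in frags) == seq
        # every internal boundary follows a dibasic pair
        pos = 0
        for f, _, _ in frags[:-1]:
            pos += len(f)
            assert seq[pos - 2] in "KR" and seq[pos - 1] in "KR"
        assert dibasic_boundaries(seq) == oracle_boundaries(seq)

    def test_efficiency_zero_no_cleavage(self):
        assert [f for f, _, _ in digest_endo("AAKRGG", 0.0)] == ["AAKRGG"]


class TestCarboxyTrimming:
    def test_glucagon_kr_trims_to_glucagon(self):
        chain = trim_carboxy(GLUCAGON + "KR", enzyme_active=True)
        assert chain == [GLUCAGON + "K", GLUCAGON]

    def test_nonbasic_terminus_unchanged(self):
        assert trim_carboxy("AQDFT", enzyme_active=True) == ["AQDFT"]

    def test_inactive_enzyme_returns_substrate(self):
        assert trim_carboxy(GLUCAGON + "KR", enzyme_active=False) == [GLUCAGON + "KR"]

    def test_exhaustive_five_mers(self):
        # every 5-mer over {A, K, R}: chain must match stepwise removal
        for p in map("".join, itertools.product("AKR", repeat=5)):
            chain = trim_carboxy(p, enzyme_active=True)
            exp, q = [], p
            while q and q[-1] in "KR":
                q = q[:-1]
                if q:
                    exp.append(q)
            assert chain == (exp if exp else [p])
            # lengths strictly decrease by one per emitted step
            lengths = [len(c) for c in chain]
            assert lengths == sorted(lengths, reverse=True)
            if len(chain) > 1:
                assert all(a - b == 1 for a, b in zip(lengths, lengths[1:]))


class TestAminoTrimming:
    def test_glp1_like_start_removes_dipeptide(self):
        assert trim_amino_dpp4("HAEGTFTSD", enzyme_active=True) == ["EGTFTSD"]

    def test_ineligible_second_residue_unchanged(self):
        assert trim_amino_dpp4("HGEGTFTSD", enzyme_active=True) == ["HGEGTFTSD"]

    def test_iterative_removal(self):
        assert trim_amino_dpp4("TPAPQRS", enzyme_active=True, iterative=True) == \
            ["APQRS", "QRS"]

    def test_exhaustive_short_strings(self):
        for p in map("".join, itertools.product("TPAQ", repeat=4)):
            single = trim_amino_dpp4(p, enzyme_active=True)
            if p[1] in "PA":
                assert single == [p[2:]]
            else:
                assert single == [p]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            trim_amino_dpp4("AP")


class TestAmidation:
    def test_glycine_terminus_amidated(self):
        # mirrors the GLP-1 7-37 -> 7-36 amide relationship
        assert amidate("AWLVKGRG") == "AWLVKGR"

    def test_no_glycine_no_product(self):
        assert amidate("AWLVKGRT") is None

    def test_single_glycine_rejected(self):
        assert amidate("G") is None


class TestPeptidomeSimulation:
    def test_wild_type_fully_processed(self, registry):
        species = simulate_peptidome(registry, Genotype("WT", frozenset(), ("c",)))
        for sp in species:
            if sp.sequence[-1] in "KR":
                # an amidated C-terminal K/R is a legitimate mature form
                # (the amide blocks carboxypeptidase); nothing else may
                # retain a basic terminus at full efficiency
                assert sp.amidated

    def test_cpe_knockout_substrates_retain_basic_terminus(self, registry):
        wt = set(simulate_peptidome(registry, Genotype("WT", frozenset(), ("c",))))
        ko = simulate_peptidome(registry, Genotype("CPE_KO", frozenset({"CPE"}), ("c",)))
        accumulating = [sp for sp in ko if sp not in wt]
        assert accumulating
        assert all(sp.sequence[-1] in "KR" for sp in accumulating)

    def test_double_endo_knockout_leaves_chains_intact(self, registry):
        ko = simulate_peptidome(
            registry, Genotype("PCSK_KO", frozenset({"PCSK1", "PCSK2"}), ("c",)))
        by_acc = {}
        for sp in ko:
            by_acc.setdefault(sp.accession, []).append(sp)
        for acc, species in by_acc.items():
            rec = registry[acc]
            # no fragment boundary interior to the post-signal chain: exactly
            # one species per precursor, trimmed only at its edges by the
            # still-active exopeptidases
            assert len(species) == 1
            sp = species[0]
            assert sp.start - (rec.signal_end() + 1) in (0, 2)  # optional DPP4 trim
            assert sp.end >= len(rec) - 4  # a few C-terminal basics at most

    def test_single_pcsk_knockout_still_cleaves(self, registry):
        single = simulate_peptidome(registry, Genotype("P1_KO", frozenset({"PCSK1"}), ("c",)))
        wt = simulate_peptidome(registry, Genotype("WT", frozenset(), ("c",)))
        assert set(single) == set(wt)

    def test_truth_labels_consistent_with_membership(self, registry):
        design = knockout_design("CPE", seed=3)
        truth = label_species(registry, design)
        wt = {(s.sequence, s.modifications)
              for s in simulate_peptidome(registry, design.genotypes[0])}
        ko = {(s.sequence, s.modifications)
              for s in simulate_peptidome(registry, design.genotypes[1])}
        for _, row in truth.iterrows():
            key = (row["sequence"], row["modifications"])
            expected = ("constitutive" if key in wt and key in ko
                        else "mature" if key in wt else "KO-accumulating")
            assert row["label"] == expected


class TestQuantGeneration:
    def test_same_seed_identical_tables(self, registry):
        design = knockout_design("CPE", seed=11)
        t1, tr1 = generate_quant_table(design, registry)
        t2, tr2 = generate_quant_table(design, registry)
        pd.testing.assert_frame_equal(t1.values, t2.values)
        pd.testing.assert_frame_equal(tr1, tr2)

    def test_noiseless_shift_is_exact(self, registry):
        noise = NoiseModel(log2_sd_biological=0.0, log2_sd_technical=0.0,
                           ko_log2_shift=4.0, censor_quantile=0.0)
        design = knockout_design("CPE", seed=5)
        table, truth = generate_quant_table(design, registry, None, noise)
        log2 = np.log2(table.values.to_numpy())
        is_ko_sample = (table.samples["genotype"] == "CPE_KO").to_numpy()
        for i, label in enumerate(truth["label"]):
            fc = log2[i, is_ko_sample].mean() - log2[i, ~is_ko_sample].mean()
            expected = {"KO-accumulating": 4.0, "mature": -4.0, "constitutive": 0.0}[label]
            assert fc == pytest.approx(expected, abs=1e-9)

    def test_censoring_removes_lowest_quintile(self, registry):
        design = knockout_design("CPE", seed=7)
        full, _ = generate_quant_table(design, registry, None,
                                       NoiseModel(censor_quantile=0.0))
        censored, _ = generate_quant_table(design, registry, None,
                                           NoiseModel(censor_quantile=0.2))
        a = full.values.to_numpy().ravel()
        b = censored.values.to_numpy().ravel()
        missing = np.isnan(b)
        assert missing.mean() == pytest.approx(0.2, abs=0.02)
        # everything censored lies below everything retained
        assert np.nanmax(a[missing]) <= np.nanmin(a[~missing]) + 1e-9

    def test_background_peptides_do_not_map(self, registry):
        design = knockout_design("DPP4", seed=2)
        _, truth = generate_quant_table(design, registry, n_background=25)
        background = truth[truth["accession"] == ""]
        assert len(background) == 25
        assert all(not registry.locate(s) for s in background["sequence"])
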