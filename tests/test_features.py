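"""Feature extraction: position symbols, triplets, stability, distance, MFE."""

import collections

import numpy as np
import pytest

from mirduplex.candidates import DuplexCandidate, enumerate_candidates, locate_star
from mirduplex.features import (
    GAP,
    NO_VALUE,
    POSITION_ALPHABET,
    FeatureConfig,
    dis_feature,
    encode_position,
    extract_features,
    full_feature_names,
    mfe_features,
    positional_feature_names,
    positional_features,
    stability_5prime,
    triplet_features,
)
from mirduplex.hairpin import UNPAIRED, PremiRNA

from conftest import StubBackend, perfect_hairpin

L = 21


def make_candidate(pre, m, L=L):
    ss, se = locate_star(pre, m, L)
    arm = "5p" if m < pre.anatomy.terminal_loop[0] else "3p"
    return DuplexCandidate(pre.id, m, L, ss, se, arm)


class TestNameInventory:
    @pytest.mark.parametrize("s,expected", [(12, 90), (6, 66), (0, 42)])
    def test_positional_counts(self, s, expected):
        assert len(positional_feature_names(21, s)) == expected

    @pytest.mark.parametrize("s,total", [(12, 160), (6, 136)])
    def test_full_inventory(self, s, total):
        names = full_feature_names(21, s)
        assert len(names) == total == len(set(names))
        # 90/32/32/6 taxonomy at s=12
        if s == 12:
            triplets = [n for n in names if "(" in n or "..." in n]
            assert len(triplets) == 64
            assert sum(
                n.startswith("miRNA*_") and "(" not in n and "." not in n and "end" not in n
                for n in names
            ) == 21

    def test_alphabet_has_ten_symbols(self):
        assert len(POSITION_ALPHABET) == 10
        assert NO_VALUE in POSITION_ALPHABET and GAP in POSITION_ALPHABET


class TestEncodePosition:
    def test_paired_and_unpaired(self):
        pre = PremiRNA("t", "GAGAAAACUC", "((......))")
        assert encode_position(pre, 0) == "G|M"
        assert encode_position(pre, 2) == "G|L"

    def test_outside_sequence_is_novalue(self, hairpin46):
        assert encode_position(hairpin46, -1) == NO_VALUE
        assert encode_position(hairpin46, 46) == NO_VALUE


class TestPositionalFeatures:
    @pytest.mark.parametrize("s,expected", [(12, 90), (6, 66), (0, 42)])
    def test_symbol_counts(self, s, expected, hairpin46):
        cand = make_candidate(hairpin46, 0)
        symbols = positional_features(cand, hairpin46, FeatureConfig(flank_len=s))
        assert len(symbols) == expected
        assert set(symbols.values()) <= set(POSITION_ALPHABET)

    def test_flank_beyond_ends_is_novalue(self, hairpin46):
        cand = make_candidate(hairpin46, 0)
        symbols = positional_features(cand, hairpin46, FeatureConfig(flank_len=12))
        assert symbols["bef_miRNA_1"] == NO_VALUE  # nothing before position 0
        assert symbols["aft_miRNA_1"] != NO_VALUE

    def test_star_window_matches_partner_nucleotides_on_perfect_stem(self):
        # the star window is laid against the miRNA window via the pair
        # table: on a perfect stem each slot holds the partner nucleotide,
        # renumbered 5'->3' along the star strand
        pre = perfect_hairpin(stem=40, loop=5, seed=1)
        cand = make_candidate(pre, 2)
        symbols = positional_features(cand, pre, FeatureConfig(flank_len=0))
        partners = [int(pre.pair_table[i]) for i in range(2, 2 + L)]
        expected = [pre.sequence[p] for p in sorted(partners)]
        got = [symbols[f"miRNA*_{i}"].split("|")[0] for i in range(1, L + 1)]
        assert got == expected

    def test_mirna_side_bulge_yields_gap_symbols(self):
        # hairpin with a 2-nt bulge at miRNA positions 10-11: the opposite
        # strand is contiguous there, so the aligned star slots are gaps
        pt = np.full(46, UNPAIRED)
        for k in range(10):
            pt[k], pt[45 - k] = 45 - k, k          # outer helix
            pt[12 + k], pt[35 - k] = 35 - k, 12 + k  # inner helix; loop 22-25
        from mirduplex.hairpin import structure_from_pairs

        mod = PremiRNA("mod", "A" * 46, structure_from_pairs(pt), pair_table=pt)
        cand = make_candidate(mod, 0)
        symbols = positional_features(cand, mod, FeatureConfig(flank_len=0))
        star_symbols = [symbols[f"miRNA*_{i}"] for i in range(1, L + 1)]
        assert star_symbols.count(GAP) == 2
        assert all(s == "A|M" for i, s in enumerate(star_symbols) if s != GAP)

    def test_determinism(self, hairpin46):
        cand = make_candidate(hairpin46, 1)
        cfg = FeatureConfig(flank_len=6)
        assert positional_features(cand, hairpin46, cfg) == positional_features(
            cand, hairpin46, cfg
        )


class TestDis:
    def test_start_at_loop_boundary(self, hairpin46):
        loop_start = hairpin46.anatomy.terminal_loop[0]
        cand = make_candidate(hairpin46, 2)
        cand = DuplexCandidate("hp46", loop_start, L, *cand.star_span, arm="5p")
        assert dis_feature(cand, hairpin46.anatomy) == 0

    def test_seven_nt_upstream(self):
        pre = perfect_hairpin(stem=40, loop=5, seed=3)
        loop_start = pre.anatomy.terminal_loop[0]
        cand = make_candidate(pre, loop_start - 7)
        assert dis_feature(cand, pre.anatomy) == 7

    def test_matches_bruteforce_scan(self, tiny_dataset):
        for pre in tiny_dataset.premirnas:
            ls, le = pre.anatomy.terminal_loop
            loop_positions = range(ls, le)
            for c in tiny_dataset.candidates[pre.id][::5]:
                expected = min(abs(c.mirna_start - p) for p in loop_positions)
                assert dis_feature(c, pre.anatomy) == expected


class TestStability5Prime:
    def pre_with_end_pair(self, b5, b3):
        seq = b5 + "GGGGG" + "AAAA" + "CCCCC" + b3
        struct = "((((((....))))))"
        return PremiRNA("t", seq, struct)

    @pytest.mark.parametrize("b5,b3,code", [
        ("G", "C", 3), ("C", "G", 3), ("A", "U", 2), ("U", "A", 2),
        ("G", "U", 1), ("U", "G", 1),
    ])
    def test_pair_classes(self, b5, b3, code):
        pre = self.pre_with_end_pair(b5, b3)
        cand = make_candidate(pre, 0, L=6)
        mirna_code, _ = stability_5prime(cand, pre)
        assert mirna_code == code

    def test_unpaired_end_is_zero(self):
        pre = PremiRNA("t", "AGGGGGAAAACCCCCA", ".(((((....))))).")
        cand = make_candidate(pre, 0, L=6)
        assert stability_5prime(cand, pre)[0] == 0

    def test_star_end_code(self):
        pre = self.pre_with_end_pair("G", "C")
        cand = make_candidate(pre, 0, L=6)
        # star 5' end pairs whatever sits at its partner position
        star_code = stability_5prime(cand, pre)[1]
        assert star_code in (0, 1, 2, 3)


class TestMFE:
    def test_unpairable_windows_have_zero_mfe(self, vienna):
        pre = PremiRNA("t", "A" * 21 + "CCCC" + "A" * 21,
                       "." * 46, pair_table=np.full(46, -1))
        cand = DuplexCandidate("t", 0, 21, 25, 46, "5p")
        assert mfe_features(cand, pre, vienna) == (0.0, 0.0, 0.0)

    def test_complementary_windows_bind(self, vienna, hairpin46):
        cand = make_candidate(hairpin46, 0)
        mfe1, mfe2, mfe3 = mfe_features(cand, hairpin46, vienna)
        _, mfe_solo = vienna.fold(hairpin46.sequence[0:21])
        assert mfe1 < mfe_solo
        assert all(v <= 0 for v in (mfe1, mfe2, mfe3))

    def test_linker_realization_close_to_constrained(self, vienna, hairpin46):
        cand = make_candidate(hairpin46, 0)
        c = mfe_features(cand, hairpin46, vienna, FeatureConfig())
        l = mfe_features(cand, hairpin46, vienna,
                         FeatureConfig(mfe_realization="linker"))
        assert np.allclose(c, l, atol=1.0)

    def test_equals_direct_backend_cofold(self, vienna):
        # oracle: build the linked sequence by hand and fold with the same
        # constraint; extractor must reproduce it exactly
        pre = perfect_hairpin(stem=30, loop=4, seed=8)
        cand = make_candidate(pre, 3)
        a = pre.sequence[cand.mirna_start: cand.mirna_end]
        b = pre.sequence[cand.star_start: cand.star_end]
        lo, hi = (a, b) if cand.mirna_start <= cand.star_start else (b, a)
        _, expected = vienna.fold_constrained(lo + "NNNNNN" + hi, list(range(len(lo), len(lo) + 6)))
        assert mfe_features(cand, pre, vienna)[0] == expected


class TestTriplets:
    def test_single_triplet(self):
        out = triplet_features("ACG", "(((", prefix="miRNA")
        assert out["miRNA_C((("] == 1.0
        assert sum(out.values()) == 1.0

    def test_collapses_closing_brackets(self):
        out = triplet_features("ACG", ")))", prefix="miRNA")
        assert out["miRNA_C((("] == 1.0

    def test_frequencies_sum_to_one(self, hairpin46):
        out = triplet_features(hairpin46.sequence[:21], hairpin46.structure[:21])
        assert sum(out.values()) == pytest.approx(1.0)
        assert len(out) == 32

    def test_matches_naive_recount(self, tiny_dataset):
        rng = np.random.default_rng(0)
        for pre in tiny_dataset.premirnas[:3]:
            for c in tiny_dataset.candidates[pre.id][::7]:
                seq = pre.sequence[c.mirna_start: c.mirna_end]
                struct = pre.structure[c.mirna_start: c.mirna_end].replace(")", "(")
                naive = collections.Counter(
                    seq[t + 1] + struct[t: t + 3] for t in range(len(seq) - 2)
                )
                ours = triplet_features(seq, pre.structure[c.mirna_start: c.mirna_end])
                for key, count in naive.items():
                    assert ours[f"miRNA_{key}"] == pytest.approx(count / (len(seq) - 2))

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError):
            triplet_features("AC", "((")


class TestExtractFeatures:
    def test_full_inventory_at_s12(self, vienna, hairpin46):
        cand = make_candidate(hairpin46, 0)
        fv = extract_features(cand, hairpin46, FeatureConfig(flank_len=12), vienna)
        assert len(fv) == 160
        assert set(fv) == set(full_feature_names(21, 12))

    def test_inventory_at_s6(self, vienna, hairpin46):
        cand = make_candidate(hairpin46, 0)
        fv = extract_features(cand, hairpin46, FeatureConfig(flank_len=6), vienna)
        assert len(fv) == 136

    def test_determinism(self, vienna, hairpin46):
        cand = make_candidate(hairpin46, 2)
        cfg = FeatureConfig(flank_len=12)
        assert extract_features(cand, hairpin46, cfg, vienna) == extract_features(
            cand, hairpin46, cfg, vienna
        )

    def test_stub_backend_usable(self, hairpin46):
        cand = make_candidate(hairpin46, 0)
        fv = extract_features(cand, hairpin46, FeatureConfig(flank_len=6),
                              StubBackend("." * 100, -4.0))
        assert fv["MFE_1"] == -4.0
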