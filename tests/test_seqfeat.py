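"""Sequence-feature operations against independent brute-force oracles."""

import math
import re
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idrkit.records import CANONICAL, ProteinRecord, SequenceError
from idrkit.seqfeat import (BoundaryLine, ChargeConvention, MotifConfig,
                            ResidueScale, charge_hydropathy_point,
                            complexity_profile, composition_fraction,
                            find_homopolymer_runs, formal_net_charge,
                            hydropathy_profile, kyte_doolittle,
                            max_run_length, scan_motifs)

sequences = st.text(alphabet=CANONICAL, min_size=1, max_size=120)


# ---------------------------------------------------------------------------
# oracles: deliberately naive, index-by-index implementations


def runs_oracle(seq, residue, min_length):
    """Linear scan with explicit state, unlike the regex implementation."""
    out, start = [], None
    for i, c in enumerate(seq + "$"):
        if c == residue and start is None:
            start = i
        elif c != residue and start is not None:
            if i - start >= min_length:
                out.append((start, i - start))
            start = None
    return out


def window_mean_oracle(seq, values, window):
    half = window // 2
    out = []
    for i in range(len(seq)):
        if i < half or i >= len(seq) - half:
            out.append(float("nan"))
        else:
            chunk = seq[i - half:i + half + 1]
            out.append(sum(values[c] for c in chunk) / window)
    return out


def entropy_oracle(chunk):
    n = len(chunk)
    return -sum((k / n) * math.log2(k / n) for k in Counter(chunk).values())


# ---------------------------------------------------------------------------
# homopolymer runs


class TestHomopolymerRuns:
    def test_musashi_single_octa_alanine(self, musashi):
        runs = find_homopolymer_runs(musashi, "A", min_length=5)
        assert len(runs) == 1
        assert runs[0].length == 8
        assert runs[0].start == 274
        assert runs[0].end == 281

    def test_run_below_threshold_dropped(self):
        rec = ProteinRecord("p", "AAAA")
        assert find_homopolymer_runs(rec, "A", min_length=5) == []

    def test_ambiguous_letters_break_runs(self):
        rec = ProteinRecord("p", "AAXAA")
        runs = find_homopolymer_runs(rec, "A", min_length=2)
        assert [(r.start, r.length) for r in runs] == [(1, 2), (4, 2)]

    def test_invalid_residue_argument(self, musashi):
        with pytest.raises(SequenceError):
            find_homopolymer_runs(musashi, "X", 1)
        with pytest.raises(SequenceError):
            find_homopolymer_runs(musashi, "AA", 1)

    def test_matches_oracle_on_random_sequences(self, random_records):
        for rec in random_records(50, length=300, seed=11):
            for residue in "ALG":
                got = [(r.start - 1, r.length)
                       for r in find_homopolymer_runs(rec, residue, 2)]
                assert got == runs_oracle(rec.sequence, residue, 2)

    def test_max_run_consistent_with_runs(self, random_records):
        for rec in random_records(20, length=200, seed=5):
            runs = find_homopolymer_runs(rec, "A", 1)
            expected = max((r.length for r in runs), default=0)
            assert max_run_length(rec, "A") == expected

    def test_max_run_absent_residue(self):
        assert max_run_length(ProteinRecord("p", "GGGG"), "A") == 0

    @given(s1=sequences, s2=sequences)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_concatenation_property(self, s1, s2):
        """Runs across a non-A junction are the union of per-part runs."""
        joined = s1 + "G" + s2
        rec = ProteinRecord("p", joined)
        got = [(r.start, r.length) for r in find_homopolymer_runs(rec, "A", 1)]
        left = [(r.start, r.length)
                for r in find_homopolymer_runs(ProteinRecord("a", s1), "A", 1)]
        right = [(r.start + len(s1) + 1, r.length)
                 for r in find_homopolymer_runs(ProteinRecord("b", s2), "A", 1)]
        assert got == left + right


# ---------------------------------------------------------------------------
# profiles


class TestHydropathyProfile:
    def test_homopolymer_window_equals_scale_value(self):
        rec = ProteinRecord("p", "IIIIIIIII")
        prof = hydropathy_profile(rec, window=9)
        defined = prof.dropna()
        assert list(defined.index) == [5]
        assert defined.iloc[0] == pytest.approx(4.5)

    def test_constant_sequence_constant_profile(self):
        rec = ProteinRecord("p", "G" * 15)
        prof = hydropathy_profile(rec, window=9)
        assert prof.dropna().nunique() == 1
        assert prof.dropna().iloc[0] == pytest.approx(-0.4)
        assert prof.isna().sum() == 8  # 4 on each edge

    @pytest.mark.parametrize("window", [2, 8, 31])
    def test_bad_windows_rejected(self, window):
        with pytest.raises(ValueError):
            hydropathy_profile(ProteinRecord("p", "MKVLIMFPMKVLIMFP"),
                               window=window)

    def test_matches_window_mean_oracle(self, random_records):
        values = kyte_doolittle().values
        for rec in random_records(20, length=30, seed=21):
            prof = hydropathy_profile(rec, window=9)
            expected = window_mean_oracle(rec.sequence, values, 9)
            np.testing.assert_allclose(prof.to_numpy(), expected,
                                       rtol=1e-9, atol=1e-12)

    def test_full_protein_indexing(self):
        rec = ProteinRecord("p", "IIIIIIIII", numbering_offset=194)
        prof = hydropathy_profile(rec, window=9)
        assert prof.index[0] == 194
        assert prof.dropna().index[0] == 198


class TestComplexityProfile:
    def test_single_letter_window_zero_entropy(self):
        prof = complexity_profile(ProteinRecord("p", "A" * 12), window=12)
        assert prof.iloc[0] == pytest.approx(0.0)

    def test_all_distinct_window_log2_n(self):
        prof = complexity_profile(ProteinRecord("p", "ACDEFGHIKLMN"), window=12)
        assert prof.iloc[0] == pytest.approx(math.log2(12))

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            complexity_profile(ProteinRecord("p", "MKV"), window=4)

    def test_matches_entropy_oracle(self, random_records):
        for rec in random_records(10, length=60, seed=31):
            prof = complexity_profile(rec, window=12)
            for start, got in prof.items():
                chunk = rec.sequence[start - 1:start + 11]
                assert got == pytest.approx(entropy_oracle(chunk))


# ---------------------------------------------------------------------------
# charge and composition


class TestCharge:
    def test_musashi_net_charge(self, musashi):
        assert formal_net_charge(musashi) == 2

    def test_balanced(self):
        assert formal_net_charge(ProteinRecord("p", "KRDE")) == 0

    def test_histidine_variant(self):
        rec = ProteinRecord("p", "KHHD")
        assert formal_net_charge(rec) == 0
        assert formal_net_charge(
            rec, ChargeConvention(histidine_positive=True)) == 2

    def test_matches_counting_oracle(self, random_records):
        for rec in random_records(30, length=100, seed=41):
            s = rec.sequence
            expected = s.count("K") + s.count("R") - s.count("D") - s.count("E")
            assert formal_net_charge(rec) == expected


class TestComposition:
    def test_musashi_proline_percent(self, musashi):
        assert round(composition_fraction(musashi, {"P"})) == 12

    def test_full_alphabet_is_everything(self, random_records):
        (rec,) = random_records(1, seed=51)
        assert composition_fraction(rec, set(CANONICAL)) == pytest.approx(100.0)

    def test_singletons_sum_to_100(self, musashi):
        total = sum(composition_fraction(musashi, {aa}) for aa in CANONICAL)
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_ambiguous_excluded_from_denominator(self):
        rec = ProteinRecord("p", "PPXX")
        assert composition_fraction(rec, {"P"}) == pytest.approx(100.0)


class TestChargeHydropathyPoint:
    def test_musashi_classifies_folded_like(self, musashi):
        point = charge_hydropathy_point(musashi)
        assert point.classification == "folded_like"
        assert point.mean_abs_net_charge_per_residue == pytest.approx(2 / 169)

    def test_poly_glutamate_disordered_like(self):
        point = charge_hydropathy_point(ProteinRecord("p", "E" * 50))
        assert point.classification == "disordered_like"
        assert point.mean_abs_net_charge_per_residue == pytest.approx(1.0)

    def test_boundary_tie_rule(self):
        """A point exactly on the line classifies disordered; below, folded."""
        line = BoundaryLine(slope=2.785, intercept=-1.151)
        h = 0.5
        r_on = line.slope * h + line.intercept
        assert line.classify(r_on, h) == "disordered_like"
        assert line.classify(r_on - 1e-9, h) == "folded_like"
        assert line.classify(r_on + 1e-9, h) == "disordered_like"

    @given(sequences)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_invariant_under_permutation(self, seq):
        rec = ProteinRecord("p", seq)
        shuffled = ProteinRecord("q", seq[::-1])
        a = charge_hydropathy_point(rec)
        b = charge_hydropathy_point(shuffled)
        assert a.mean_abs_net_charge_per_residue == \
            pytest.approx(b.mean_abs_net_charge_per_residue)
        assert a.mean_scaled_hydropathy == pytest.approx(b.mean_scaled_hydropathy)
        assert a.classification == b.classification


# ---------------------------------------------------------------------------
# motifs


def motif_oracle(seq, cfg=MotifConfig()):
    """Independent regex set, written separately from the scanner."""
    hits = []
    for m in re.finditer("(?:(?:SR)|(?:RS)){2,}", seq):
        hits.append(("SR_repeat", m.start(), m.end() - 1))
    for m in re.finditer("RGG|(?<=G)RG", seq):
        hits.append(("RG_RGG", m.start(), m.end() - 1))
    for m in re.finditer("[GS]Y[GS]", seq):
        hits.append(("GS_Y_GS", m.start(), m.end() - 1))
    return sorted(hits)


class TestScanMotifs:
    def test_musashi_has_no_motifs(self, musashi):
        assert scan_motifs(musashi) == []

    def test_canonical_rgg(self):
        hits = scan_motifs(ProteinRecord("p", "GRGGS"), classes=["RG_RGG"])
        assert [(h.matched, h.start, h.end) for h in hits] == [("RGG", 2, 4)]

    def test_sr_repeat_needs_two_dipeptides(self):
        assert scan_motifs(ProteinRecord("p", "ASRT"), ["SR_repeat"]) == []
        hits = scan_motifs(ProteinRecord("p", "ASRSRT"), ["SR_repeat"])
        assert [h.matched for h in hits] == ["SRSR"]

    def test_qn_rich_window_rule(self):
        rec = ProteinRecord("p", "AAQQNQQNQQAAAAAAAAAA")
        hits = scan_motifs(rec, ["QN_rich"])
        assert len(hits) == 1
        assert hits[0].start == 1  # merged qualifying windows
        rec2 = ProteinRecord("p", "QQNQQA" + "G" * 10)
        assert scan_motifs(rec2, ["QN_rich"]) == []

    def test_aromatic_superset_config(self, musashi):
        """Broadening the GS-aromatic-GS class to F/Y/W finds the GFG at 343."""
        hits = scan_motifs(musashi, ["GS_Y_GS"],
                           config=MotifConfig(gs_aromatics="FYW"))
        assert [(h.start, h.matched) for h in hits] == [(343, "GFG")]

    def test_unknown_class_rejected(self, musashi):
        with pytest.raises(ValueError):
            scan_motifs(musashi, ["prion_like"])

    def test_hit_matched_equals_slice(self, random_records):
        for rec in random_records(30, length=150, seed=61):
            for h in scan_motifs(rec):
                s, e = h.start - 1, h.end  # offset 1 -> 0-based slice
                assert rec.sequence[s:e] == h.matched

    def test_matches_oracle_on_random_sequences(self, random_records):
        classes = ["SR_repeat", "RG_RGG", "GS_Y_GS"]
        for rec in random_records(100, length=200, seed=71):
            got = sorted((h.motif_class, h.start - 1, h.end - 1)
                         for h in scan_motifs(rec, classes))
            assert got == motif_oracle(rec.sequence)


# ---------------------------------------------------------------------------
# scales


class TestResidueScale:
    def test_requires_all_twenty(self):
        with pytest.raises(ValueError):
            ResidueScale("partial", {"A": 1.0})

    def test_min_max_scaling(self):
        scaled = kyte_doolittle().scaled().values
        assert min(scaled.values()) == pytest.approx(0.0)
        assert max(scaled.values()) == pytest.approx(1.0)
        assert scaled["I"] == pytest.approx(1.0)  # most hydrophobic
        assert scaled["R"] == pytest.approx(0.0)  # least
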