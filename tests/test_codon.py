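"""Codon recoding: translation fidelity, replacement policies, masking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from slamkit.codon import (
    AlphabetError,
    CdsSequence,
    CodonUsageTable,
    FrameError,
    GeneticCode,
    ProtectedIntervals,
    STANDARD_CODE,
    STOP,
    nucleotide_identity,
    recode_cds,
    translate,
)
from slamkit.synthetic import gen_cds


class TestGeneticCode:
    def test_standard_code_has_64_codons_and_3_stops(self):
        code = GeneticCode.standard()
        assert len(code.mapping) == 64
        assert code.family(STOP) == ("TAA", "TAG", "TGA")

    def test_single_codon_families(self):
        assert STANDARD_CODE.family("M") == ("ATG",)
        assert STANDARD_CODE.family("W") == ("TGG",)


class TestUsageTable:
    def test_family_frequencies_sum_to_one(self, usage):
        for aa in set(STANDARD_CODE.mapping.values()):
            total = sum(usage[c] for c in STANDARD_CODE.family(aa))
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_incomplete_table_rejected(self):
        with pytest.raises(ValueError, match="missing codons"):
            CodonUsageTable(frequencies={"ATG": 1.0})


class TestTranslate:
    @pytest.mark.parametrize(
        "seq,protein,trailing",
        [
            ("ATGAAA", "MK", False),
            ("ATGTGA", "M", True),
            ("ATGTAAAAA", "M", False),  # internal stop terminates, not trailing
        ],
    )
    def test_examples(self, seq, protein, trailing):
        res = translate(CdsSequence(id="x", seq=seq))
        assert res.protein == protein
        assert res.trailing_stop is trailing

    def test_full_length_orf_yields_1173_residues(self, usage):
        """A 3,519-nt stop-free CDS encodes exactly 1,173 residues."""
        cds = gen_cds(1173, usage, seed=7)
        orf = CdsSequence(id="orf", seq=cds.seq[:-3])  # drop the trailing stop
        assert len(orf) == 3519
        res = translate(orf)
        assert len(res.protein) == 1173
        assert res.stop_index is None

    def test_frame_and_alphabet_errors(self):
        with pytest.raises(FrameError):
            CdsSequence(id="x", seq="ATGA")
        with pytest.raises(AlphabetError):
            CdsSequence(id="x", seq="ATGNNN")


class TestRecode:
    def test_met_trp_only_cds_unchanged(self, usage):
        res = recode_cds(CdsSequence(id="x", seq="ATGTGG"), usage)
        assert res.recoded.seq == "ATGTGG"
        assert res.changed_codon_count == 0

    def test_two_member_family_swap_is_forced(self, usage):
        # Glu family {GAA, GAG}: the only synonymous alternative must be taken
        assert recode_cds(CdsSequence(id="x", seq="GAA"), usage).recoded.seq == "GAG"
        assert recode_cds(CdsSequence(id="x", seq="GAG"), usage).recoded.seq == "GAA"

    def test_protected_codons_absent_from_log(self, usage):
        cds = gen_cds(20, usage, seed=0)
        protected = ProtectedIntervals([(15, 30)])  # codons 5-9
        res = recode_cds(cds, usage, protected)
        touched = {pos for pos, _, _ in res.per_codon_log}
        assert touched.isdisjoint(range(5, 10))
        assert res.recoded.seq[15:30] == cds.seq[15:30]

    def test_unaligned_interval_expanded_with_warning(self, usage):
        cds = gen_cds(20, usage, seed=0)
        with pytest.warns(UserWarning, match="codon-aligned"):
            res = recode_cds(cds, usage, ProtectedIntervals([(16, 20)]))
        # covering codons 5 and 6 are fully preserved
        assert res.recoded.seq[15:21] == cds.seq[15:21]

    def test_internal_stop_left_unchanged_with_warning(self, usage):
        cds = CdsSequence(id="gfp_stop", seq="ATGTGAAAA")
        with pytest.warns(UserWarning, match="internal stop"):
            res = recode_cds(cds, usage)
        assert res.recoded.seq[3:6] == "TGA"
        assert translate(res.recoded).protein == translate(cds).protein

    def test_all_lysine_cds_identity_is_two_thirds(self, usage):
        # Lys family {AAA, AAG}: every codon flips its third base only
        cds = CdsSequence(id="polyK", seq="AAA" * 30)
        res = recode_cds(cds, usage)
        assert res.recoded.seq == "AAG" * 30
        assert res.nucleotide_identity == pytest.approx(60 / 90)

    @pytest.mark.parametrize("seed", range(100))
    def test_translation_preserved_over_seeds(self, usage, seed):
        """Recoding never alters the encoded protein (both policies)."""
        cds = gen_cds(50, usage, seed=seed)
        for policy in ("max-frequency-alternative", "usage-weighted-sample"):
            res = recode_cds(cds, usage, policy=policy, seed=seed)
            orig = translate(cds)
            new = translate(res.recoded)
            assert new.protein == orig.protein
            assert new.trailing_stop == orig.trailing_stop

    def test_maximal_replacement_on_long_cds(self, usage):
        """A codon stays iff it is ATG, TGG, a stop, or protected."""
        cds = gen_cds(1200, usage, seed=11)
        protected = ProtectedIntervals([(300, 360)])
        res = recode_cds(cds, usage, protected)
        changed = {pos for pos, _, _ in res.per_codon_log}
        mask = set(range(100, 120))
        for i, codon in enumerate(cds.codons()):
            keep = codon in ("ATG", "TGG") or STANDARD_CODE[codon] == STOP or i in mask
            assert (i not in changed) == keep, f"codon {i} ({codon})"
        for pos, old, new in res.per_codon_log:
            assert old != new
            assert STANDARD_CODE[old] == STANDARD_CODE[new]

    def test_determinism(self, usage):
        cds = gen_cds(200, usage, seed=5)
        a = recode_cds(cds, usage, policy="usage-weighted-sample", seed=42)
        b = recode_cds(cds, usage, policy="usage-weighted-sample", seed=42)
        assert a == b

    def test_usage_weighted_replacement_distribution(self, usage):
        """Sampled replacements follow the renormalized family frequencies."""
        cds = CdsSequence(id="gly", seq="GGA")  # Gly family minus GGA: GGT/GGC/GGG
        counts = {}
        n = 600
        for seed in range(n):
            new = recode_cds(
                cds, usage, policy="usage-weighted-sample", seed=seed
            ).recoded.seq
            counts[new] = counts.get(new, 0) + 1
        alts = ["GGT", "GGC", "GGG"]
        weights = np.array([usage[c] for c in alts])
        expected = n * weights / weights.sum()
        observed = np.array([counts.get(c, 0) for c in alts])
        assert stats.chisquare(observed, expected).pvalue > 1e-3

    def test_unknown_policy_rejected(self, usage):
        with pytest.raises(ValueError, match="policy"):
            recode_cds(CdsSequence(id="x", seq="AAA"), usage, policy="random")

    def test_out_of_bounds_interval_rejected(self, usage):
        with pytest.raises(ValueError, match="exceeds"):
            recode_cds(CdsSequence(id="x", seq="AAA"), usage, ProtectedIntervals([(0, 6)]))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), n=st.integers(1000, 1100))
def test_protein_conservation_property(seed, n):
    """For arbitrary long random CDS, recoding preserves the translation."""
    usage = load_usage_cached()
    cds = gen_cds(n, usage, seed=seed)
    res = recode_cds(cds, usage, policy="usage-weighted-sample", seed=seed)
    assert translate(res.recoded).protein == translate(cds).protein


_USAGE_CACHE = []


def load_usage_cached():
    if not _USAGE_CACHE:
        from slamkit.codon import load_dmel_usage

        _USAGE_CACHE.append(load_dmel_usage())
    return _USAGE_CACHE[0]


class TestNucleotideIdentity:
    def test_identity_and_mismatch(self):
        a = CdsSequence(id="a", seq="AAA")
        assert nucleotide_identity(a, a) == 1.0
        assert nucleotide_identity(a, CdsSequence(id="b", seq="AAG")) == pytest.approx(2 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            nucleotide_identity(
                CdsSequence(id="a", seq="AAA"), CdsSequence(id="b", seq="AAAAAA")
            )
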