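"""Fragment index, peak matching, MS2 localization, uniqueness, landscape."""

import numpy as np
import pytest

from trnamod.chem import CYANOETHYL
from trnamod.digestion import default_rules
from trnamod.mapper import (
    Peak,
    TRnaReference,
    assemble_landscape,
    build_fragment_index,
    classify_uniqueness,
    localize,
    match_peaks,
    read_peaklist,
    read_references,
    write_peaklist,
    write_references,
)
from trnamod.masscalc import cid_products, oligo_mz
from trnamod.modseq import parse_bracket_notation, to_bracket_notation


@pytest.fixture(scope="module")
def t1(registry):
    return default_rules(registry)[1]


class TestFragmentIndex:
    def test_toy_enumeration(self, t1):
        ref = TRnaReference("toy1-AAA", "GGCUUCGGCC", five_prime="OH")
        index = build_fragment_index([ref], t1, allowed={"U": ["Ψ"]}, k=1, ce=True)
        texts = {to_bracket_notation(e.sequence) for e in index.entries}
        assert "CUUCGp" in texts
        assert "C[Ψ-CE]UCGp" in texts and "CU[Ψ-CE]CGp" in texts
        # brute force: the fragment has exactly two U positions
        psi_variants = [t for t in texts if "Ψ" in t and t.startswith("C")]
        assert len(psi_variants) == 2

    def test_k0_gives_unmodified_digest_only(self, t1):
        ref = TRnaReference("toy1-AAA", "GGCUUCGGCC", five_prime="OH")
        index = build_fragment_index([ref], t1, allowed={"U": ["Ψ"]}, k=0)
        assert all(e.n_mods == 0 for e in index.entries)

    def test_ce_flag_shifts_psi_entries(self, t1):
        ref = TRnaReference("toy1-AAA", "GGCUUCGGCC", five_prime="OH")
        on = build_fragment_index([ref], t1, allowed={"U": ["Ψ"]}, k=1, ce=True)
        off = build_fragment_index([ref], t1, allowed={"U": ["Ψ"]}, k=1, ce=False)
        by_key = lambda idx: {
            (e.start, e.end, e.placements and e.placements[0][:2]): e.neutral_mass
            for e in idx.entries
            if e.n_mods == 1
        }
        masses_on, masses_off = by_key(on), by_key(off)
        assert set(masses_on) == set(masses_off)
        for key in masses_on:
            assert masses_on[key] - masses_off[key] == pytest.approx(CYANOETHYL, abs=1e-9)

    def test_invalid_inputs(self, t1):
        ref = TRnaReference("toy1-AAA", "GGCUUCGGCC")
        with pytest.raises(ValueError):
            build_fragment_index([ref], t1, k=-1)
        with pytest.raises(ValueError):
            build_fragment_index([], t1)

    def test_occurrence_counting_matches_bruteforce(self, t1):
        """Index substring counting equals a position-by-position scan."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            refs = [
                TRnaReference(
                    f"R{i + 1}-AAA", "".join(rng.choice(list("ACGU"), size=90))
                )
                for i in range(rng.integers(2, 20))
            ]
            index = build_fragment_index(refs, t1, allowed={}, k=0)
            for needle_len in (3, 4, 6):
                start = int(rng.integers(0, 90 - needle_len))
                needle = refs[0].sequence[start : start + needle_len]
                naive = []
                for ref in refs:
                    for pos in range(len(ref.sequence) - needle_len + 1):
                        if ref.sequence[pos : pos + needle_len] == needle:
                            naive.append((ref.id, pos + 1))
                assert sorted(index.occurrences(needle)) == sorted(naive)


class TestMatchPeaks:
    def _index(self, t1):
        ref = TRnaReference("Thr1-CGU", "AAGCUUCCGAAACCAGG", five_prime="OH")
        return ref, build_fragment_index([ref], t1, allowed={"U": ["Ψ"]}, k=1, ce=True)

    def test_published_value_matches(self, t1):
        """A peak at the printed m/z of CU[Ψ-CE]CCGp hits the Ψ hypothesis."""
        ref, index = self._index(t1)
        matches = match_peaks([Peak(970.620, 2)], index, tol_ppm=10)
        assert len(matches) == 1
        texts = {to_bracket_notation(c.entry.sequence) for c in matches[0].candidates}
        assert "CU[Ψ-CE]CCGp" in texts

    def test_no_match_is_empty(self, t1):
        _, index = self._index(t1)
        assert match_peaks([Peak(500.0, 1)], index, tol_ppm=10) == []

    def test_positional_isomers_both_returned(self, t1):
        ref, index = self._index(t1)
        seq = parse_bracket_notation("CU[Ψ-CE]CCGp")
        mz = oligo_mz(seq, 2)
        matches = match_peaks([Peak(mz, 2)], index, tol_ppm=10)
        placements = {c.entry.placements for c in matches[0].candidates}
        assert len(placements) == 2  # Ψ on either U of the CUUCCG stretch

    def test_decoys_do_not_perturb_true_matches(self, t1):
        ref, index = self._index(t1)
        seq = parse_bracket_notation("CU[Ψ-CE]CCGp")
        true_peak = Peak(oligo_mz(seq, 2), 2)
        rng = np.random.default_rng(11)
        decoys = [Peak(float(rng.uniform(300, 2000)), 1) for _ in range(50)]
        alone = match_peaks([true_peak], index)
        with_decoys = match_peaks([true_peak] + decoys, index)
        by_peak = [m for m in with_decoys if m.peak is true_peak]
        assert len(by_peak) == 1
        assert by_peak[0].candidates == alone[0].candidates


class TestLocalize:
    def _match_with_isomers(self, t1, registry):
        ref = TRnaReference("Thr1-CGU", "AAGCUUCCGAAACCAGG", five_prime="OH")
        index = build_fragment_index([ref], t1, allowed={"U": ["Ψ"]}, k=1, ce=True)
        true_seq = parse_bracket_notation("CU[Ψ-CE]CCGp")
        mz = oligo_mz(true_seq, 2)
        match = match_peaks([Peak(mz, 2)], index)[0]
        assert len(match.candidates) == 2
        return match, true_seq, mz

    def test_full_ladder_resolves_isomer(self, t1, registry):
        match, true_seq, mz = self._match_with_isomers(t1, registry)
        ladder = [
            Peak(ion.mz, 1, level="MS2", precursor_mz=mz)
            for ion in cid_products(true_seq, (1,), registry, series=("c", "y"))
        ]
        resolved = localize(match, ladder)
        assert len(resolved.candidates) == 1
        assert to_bracket_notation(resolved.candidates[0].entry.sequence) == "CU[Ψ-CE]CCGp"
        assert resolved.ms2_support

    def test_non_discriminating_ions_leave_both(self, t1, registry):
        match, true_seq, mz = self._match_with_isomers(t1, registry)
        # ions from the shared 3' side only (y1/y2: CGp side, no Ψ)
        shared = [
            Peak(ion.mz, 1, level="MS2", precursor_mz=mz)
            for ion in cid_products(true_seq, (1,), registry, series=("y",))
            if ion.index <= 2
        ]
        resolved = localize(match, shared)
        assert len(resolved.candidates) == 2
        assert not resolved.ms2_support

    def test_empty_ms2_returns_unchanged(self, t1, registry):
        match, _, _ = self._match_with_isomers(t1, registry)
        resolved = localize(match, [])
        assert resolved.candidates == match.candidates
        assert not resolved.ms2_support


class TestUniqueness:
    def _entry_for(self, refs, t1, fragment_text):
        index = build_fragment_index(refs, t1, allowed={"U": ["Ψ"]}, k=1, ce=True)
        target = [
            e
            for e in index.entries
            if to_bracket_notation(e.sequence) == fragment_text
        ]
        assert target
        return target[0], index

    def test_unique(self, t1):
        refs = [
            TRnaReference("A1-AAA", "GGCAUCGGCC"),
            TRnaReference("B1-CCC", "GGAAACGGAA"),
        ]
        entry, index = self._entry_for(refs, t1, "CA[Ψ-CE]CGp")
        assert classify_uniqueness(entry, index) == "unique"

    def test_shared_consistent_across_isoacceptors(self, t1):
        refs = [
            TRnaReference("A1-AAA", "GGCAUCGGCC"),
            TRnaReference("A2-AAA", "GGCAUCGGAA"),
        ]
        entry, index = self._entry_for(refs, t1, "CA[Ψ-CE]CGp")
        assert classify_uniqueness(entry, index) == "shared_consistent"

    def test_ambiguous_at_different_offsets(self, t1):
        refs = [
            TRnaReference("A1-AAA", "GGCAUCGGCC"),
            TRnaReference("B1-CCC", "GAACAUCGAA"),
        ]
        entry, index = self._entry_for(refs, t1, "CA[Ψ-CE]CGp")
        assert classify_uniqueness(entry, index) == "ambiguous"


class TestLandscape:
    def test_single_supported_match(self, t1, registry):
        ref = TRnaReference("Thr1-CGU", "AAGCUUCCGAAACCAGG", five_prime="OH")
        index = build_fragment_index([ref], t1, allowed={"U": ["Ψ"]}, k=1, ce=True)
        seq = parse_bracket_notation("CU[Ψ-CE]CCGp")
        mz = oligo_mz(seq, 2)
        ladder = [
            Peak(i.mz, 1, level="MS2", precursor_mz=mz)
            for i in cid_products(seq, (1,), registry, series=("c", "y"))
        ]
        matches = [localize(m, ladder) for m in match_peaks([Peak(mz, 2)], index)]
        landscape = assemble_landscape(matches, index)
        assert landscape.pairs() == {("6", "Ψ")}
        assert not landscape.ambiguous

    def test_unresolved_match_reported_ambiguous(self, t1):
        ref = TRnaReference("Thr1-CGU", "AAGCUUCCGAAACCAGG", five_prime="OH")
        index = build_fragment_index([ref], t1, allowed={"U": ["Ψ"]}, k=1, ce=True)
        mz = oligo_mz(parse_bracket_notation("CU[Ψ-CE]CCGp"), 2)
        matches = [localize(m, []) for m in match_peaks([Peak(mz, 2)], index)]
        landscape = assemble_landscape(matches, index)
        assert landscape.pairs() == set()
        assert len(landscape.ambiguous) == 1

    def test_frame_output_columns(self, t1):
        ref = TRnaReference("Thr1-CGU", "AAGCUUCCGAAACCAGG", five_prime="OH")
        index = build_fragment_index([ref], t1, allowed={"U": ["Ψ"]}, k=1, ce=True)
        landscape = assemble_landscape([], index)
        assert list(landscape.to_frame().columns) == [
            "position",
            "modification",
            "support",
            "uniqueness",
            "references",
            "compartments",
        ]


class TestIO:
    def test_fasta_round_trip(self, tmp_path):
        refs = [
            TRnaReference("Leu3-UAG", "GGCAUCGGCC", compartment="mitochondrial"),
            TRnaReference("Thr1-CGU", "GGAAACGGTT"),  # T normalized to U
        ]
        path = tmp_path / "refs.fasta"
        write_references(refs, path)
        loaded = read_references(path)
        assert [r.id for r in loaded] == ["Leu3-UAG", "Thr1-CGU"]
        assert loaded[0].compartment == "mitochondrial"
        assert loaded[1].sequence.endswith("UU")

    def test_peaklist_round_trip(self, tmp_path):
        peaks = [
            Peak(970.620, 2, intensity=12.5),
            Peak(485.1, 1, level="MS2", precursor_mz=970.620),
        ]
        path = tmp_path / "peaks.tsv"
        write_peaklist(peaks, path, header_comment="unit test")
        loaded = read_peaklist(path)
        assert loaded[0].mz == pytest.approx(970.620)
        assert loaded[1].level == "MS2"
        assert loaded[1].precursor_mz == pytest.approx(970.620)
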