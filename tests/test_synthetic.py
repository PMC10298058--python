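"""Seeded generators: determinism, contracts, and noise statistics."""

import numpy as np
import pytest

from trnamod.digestion import default_rules, digest
from trnamod.masscalc import ppm_error
from trnamod.synthetic import (
    GroundTruth,
    PlantedSite,
    PlantingProfile,
    generate_reference_set,
    plant_modifications,
    simulate_expression,
    simulate_peaklist,
)


@pytest.fixture(scope="module")
def t1(registry):
    return default_rules(registry)[1]


class TestReferenceSet:
    @pytest.mark.parametrize("style", ["uniform", "trna"])
    def test_deterministic_under_seed(self, style):
        a = generate_reference_set(5, seed=42, style=style)
        b = generate_reference_set(5, seed=42, style=style)
        assert [(r.id, r.sequence) for r in a] == [(r.id, r.sequence) for r in b]

    @pytest.mark.parametrize("style", ["uniform", "trna"])
    def test_lengths_in_range(self, style):
        for ref in generate_reference_set(8, (70, 90), seed=3, style=style):
            assert 70 <= len(ref) <= 90

    def test_t1_digest_yields_multiple_fragments(self, t1):
        """The G-density guarantee keeps every reference digestible."""
        for style in ("uniform", "trna"):
            for ref in generate_reference_set(6, seed=11, style=style):
                assert len(digest(ref.to_modseq(), t1)) >= 3

    def test_trna_style_position_map(self):
        refs = generate_reference_set(6, seed=5, style="trna")
        for ref in refs:
            insert = len(ref) - 76
            assert ref.label(1) == "1"
            if insert:
                assert ref.label(46) == "e1"
            assert ref.label(len(ref)) == "76"
            # conserved T-loop motif lands at canonical 53-57
            raw53 = next(i for i in range(1, len(ref) + 1) if ref.label(i) == "53")
            assert ref.sequence[raw53 - 1 : raw53 + 4] == "GUUCG"

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_reference_set(0)
        with pytest.raises(ValueError):
            generate_reference_set(3, (90, 70))
        with pytest.raises(ValueError):
            generate_reference_set(3, style="bogus")


class TestPlanting:
    def test_sites_respect_base_compatibility(self, registry):
        refs = generate_reference_set(6, seed=21)
        truth = plant_modifications(refs, seed=22)
        by_id = {r.id: r for r in refs}
        for site in truth.sites:
            ref = by_id[site.ref_id]
            assert ref.sequence[site.position - 1] == registry[site.species].parent_base
            if registry[site.species].ce_reactive:
                assert site.ce_labeled

    def test_anticodon_loop_concentration(self):
        """The default profile concentrates sites at the anticodon loop."""
        loop = {str(p) for p in range(32, 39)}
        n_loop = n_total = 0
        for seed in range(30):
            refs = generate_reference_set(5, seed=seed)
            truth = plant_modifications(refs, seed=seed + 1000)
            for site in truth.sites:
                n_total += 1
                n_loop += site.label in loop
        assert n_loop / n_total >= 0.60

    def test_empty_profile_plants_nothing(self):
        refs = generate_reference_set(3, seed=1)
        profile = PlantingProfile(site_probs={}, species_by_base={})
        truth = plant_modifications(refs, profile, seed=2)
        assert truth.sites == ()

    def test_incompatible_species_is_error(self):
        refs = generate_reference_set(3, seed=1)
        profile = PlantingProfile(
            site_probs={"34": 1.0}, species_by_base={"G": ("Ψ",)}
        )
        with pytest.raises(ValueError, match="parent base"):
            plant_modifications(refs, profile, seed=2)

    def test_unregistered_species_is_error(self):
        refs = generate_reference_set(3, seed=1)
        profile = PlantingProfile(
            site_probs={"34": 1.0}, species_by_base={"A": ("nope",)}
        )
        with pytest.raises(KeyError, match="nope"):
            plant_modifications(refs, profile, seed=2)

    def test_site_outside_reference_is_error(self):
        refs = generate_reference_set(1, seed=1)
        with pytest.raises(ValueError):
            GroundTruth(tuple(refs), (PlantedSite(refs[0].id, 999, "999", "Ψ"),))

    def test_density_cap_per_digestion_fragment(self, t1):
        for seed in range(10):
            refs = generate_reference_set(5, seed=seed)
            truth = plant_modifications(refs, seed=seed + 50)
            for ref in refs:
                positions = {s.position for s in truth.sites_of(ref.id)}
                for frag in digest(truth.modified_sequence(ref.id), t1):
                    inside = [p for p in positions if frag.start <= p <= frag.end]
                    assert len(inside) <= 3


class TestPeaklist:
    def _truth(self, seed=31):
        refs = generate_reference_set(4, seed=seed)
        return plant_modifications(refs, seed=seed + 1)

    def test_noiseless_peaks_exact(self, t1, registry):
        truth = self._truth()
        peaks, table = simulate_peaklist(
            truth, t1, ppm_sigma=0.0, dropout=0.0, decoy_rate=0.0, seed=5
        )
        frag_rows = table[table.kind == "fragment"]
        assert len(frag_rows) == len([p for p in peaks if p.level == "MS1"])
        for row in frag_rows.itertuples(index=False):
            assert ppm_error(row.observed_mz, row.theoretical_mz) == pytest.approx(0.0)

    def test_determinism(self, t1):
        truth = self._truth()
        p1, t1_table = simulate_peaklist(truth, t1, seed=9)
        p2, t2_table = simulate_peaklist(truth, t1, seed=9)
        assert [(p.mz, p.charge, p.level) for p in p1] == [
            (p.mz, p.charge, p.level) for p in p2
        ]
        assert t1_table.equals(t2_table)

    def test_dropout_rate_binomial(self, t1):
        truth = self._truth()
        total = observed = 0
        for seed in range(40):
            _, table = simulate_peaklist(
                truth, t1, dropout=0.5, decoy_rate=0.0, seed=seed
            )
            n_frag = sum(
                len(digest(truth.modified_sequence(r.id), t1)) for r in truth.references
            )
            total += n_frag
            observed += (table.kind == "fragment").sum()
        rate = observed / total
        assert abs(rate - 0.5) < 3 * np.sqrt(0.25 / total)

    def test_decoys_labelled_in_truth_table(self, t1):
        truth = self._truth()
        peaks, table = simulate_peaklist(truth, t1, decoy_rate=0.3, seed=13)
        decoys = table[table.kind == "decoy"]
        assert len(decoys) > 0
        assert (decoys.fragment == "").all()
        n_frag_peaks = (table.kind == "fragment").sum()
        assert len(peaks) >= n_frag_peaks + len(decoys)

    def test_ms2_ladders_link_to_precursor(self, t1):
        truth = self._truth()
        peaks, _ = simulate_peaklist(
            truth, t1, ppm_sigma=0.0, dropout=0.0, decoy_rate=0.0, seed=2
        )
        ms1 = {round(p.mz, 6) for p in peaks if p.level == "MS1"}
        ms2 = [p for p in peaks if p.level == "MS2"]
        assert ms2
        assert all(round(p.precursor_mz, 6) in ms1 for p in ms2)

    def test_invalid_rates(self, t1):
        truth = self._truth()
        with pytest.raises(ValueError):
            simulate_peaklist(truth, t1, dropout=1.5)
        with pytest.raises(ValueError):
            simulate_peaklist(truth, t1, ppm_sigma=-1)
        with pytest.raises(ValueError):
            simulate_peaklist(truth, t1, replicates=0)


class TestExpression:
    def test_bit_reproducible(self):
        a, _ = simulate_expression(seed=8)
        b, _ = simulate_expression(seed=8)
        assert a.values.equals(b.values)

    def test_shape_and_metadata(self):
        matrix, truth = simulate_expression(n_genes=10, n_background=20, seed=1)
        assert matrix.values.shape == (30, 8)
        assert len(truth["candidates"]) == 10
        assert set(matrix.metadata["variety"]) == {"BD", "XS"}

    def test_planted_outside_gene_set_is_error(self):
        with pytest.raises(ValueError, match="not among"):
            simulate_expression(n_genes=5, planted_positive="g999")

    def test_null_mode_has_no_trend_truth(self):
        matrix, truth = simulate_expression(planted_positive=None, n_genes=20, seed=3)
        assert truth["planted"] is None
        assert matrix.values.shape[0] == 20
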