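"""End-to-end orchestration: digest hypotheses -> match -> localize -> landscape.

Also the synthetic recovery benchmark used to validate the mapper: plant
modifications into a generated tRNA-like pool, simulate duplicate
cyanoethylated RNase T1 injections, run the full mapping pipeline, and
score the landscape against the planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .chem import ModificationRegistry, default_registry
from .digestion import CleavageRule, default_rules
from .mapper import (
    FragmentIndex,
    FragmentMatch,
    ModificationLandscape,
    Peak,
    TRnaReference,
    assemble_landscape,
    build_fragment_index,
    localize,
    match_peaks,
)
from .synthetic import (
    GroundTruth,
    PlantingProfile,
    generate_reference_set,
    plant_modifications,
    simulate_peaklist,
)

__all__ = [
    "MappingResult",
    "map_modifications",
    "RecoveryReport",
    "run_recovery_benchmark",
    "score_landscape",
    "anticodon_mapping_example",
]


@dataclass
class MappingResult:
    index: FragmentIndex
    matches: list[FragmentMatch]
    landscape: ModificationLandscape


def map_modifications(
    references: Sequence[TRnaReference],
    peaks: Sequence[Peak],
    rule: CleavageRule | None = None,
    allowed: Mapping[str, Sequence[str]] | None = None,
    k: int = 3,
    ce: bool = True,
    tol_ppm: float = 10.0,
    require_ms2: bool = True,
    registry: ModificationRegistry | None = None,
) -> MappingResult:
    """Run the full mapping pipeline over one peak list."""
    registry = registry if registry is not None else default_registry()
    if rule is None:
        _, rule = default_rules(registry)
    index = build_fragment_index(references, rule, allowed=allowed, k=k, ce=ce, registry=registry)
    ms1 = [p for p in peaks if p.level == "MS1"]
    ms2 = [p for p in peaks if p.level == "MS2"]
    matches = [localize(m, ms2, tol_ppm, registry) for m in match_peaks(ms1, index, tol_ppm)]
    landscape = assemble_landscape(matches, index, require_ms2=require_ms2)
    return MappingResult(index, matches, landscape)


#: Synthetic 76-nt Leu-family reference (anticodon UAG at 34-36) used by the
#: worked example below; positions 37-42 spell the anticodon-arm fragment.
_EXAMPLE_LEU_REFERENCE = (
    "GCCGAAAUAGCUCAGUUGGGAGAGCACAACACUUAG"  # 1-36, ends at the anticodon
    "GCUCUG"  # 37-42: the RNase T1 fragment carrying m1G37 / Psi39
    "GUCACAGUUCGAAUCUGUGAUUCGGCACCA"  # 43-72 + CCA
)


def anticodon_mapping_example(
    registry: ModificationRegistry | None = None,
) -> tuple[MappingResult, "TRnaReference"]:
    """Worked example: localize m^1^G and Ψ on an anticodon-arm fragment.

    A cyanoethylated RNase T1 digest of a synthetic Leu(UAG) reference
    yields the fragment [m^1^G]C[Ψ-CE]CUGp (the 1-methylguanosine blocks
    cleavage after position 37, fusing it to the following fragment).
    Its MS1 peak at z = -2 plus full c/y product-ion ladders localize the
    methylation to residue 1 and the pseudouridine to residue 3 of the
    fragment, i.e. positions 37 and 39 of the parent tRNA.
    """
    from .masscalc import cid_products, oligo_mz
    from .modseq import parse_bracket_notation

    registry = registry if registry is not None else default_registry()
    reference = TRnaReference("Leu3-UAG", _EXAMPLE_LEU_REFERENCE)
    fragment = parse_bracket_notation("[m^1^G]C[Ψ-CE]CUGp", registry)
    precursor_mz = oligo_mz(fragment, 2, registry=registry)
    peaks = [Peak(precursor_mz, 2, level="MS1")]
    peaks += [
        Peak(ion.mz, 1, level="MS2", precursor_mz=precursor_mz)
        for ion in cid_products(fragment, (1,), registry, series=("c", "y"))
    ]
    result = map_modifications(
        [reference],
        peaks,
        allowed={"G": ("m^1^G",), "U": ("Ψ",), "A": (), "C": ()},
        k=3,
        ce=True,
        registry=registry,
    )
    return result, reference


@dataclass
class RecoveryReport:
    n_sites: int
    n_recovered: int
    false_positions: int
    landscape_pairs: set[tuple[str, str]]

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_sites if self.n_sites else 1.0


def score_landscape(
    truth: GroundTruth, results: MappingResult | Sequence[MappingResult]
) -> RecoveryReport:
    """Recovery of planted (reference, position label, species) triples.

    A planted site counts as recovered when some landscape-contributing
    match (in any of the supplied runs) has a retained candidate placing
    that species at that label in that reference.  A false position is a
    landscape (label, species) pair that was never planted anywhere in
    the pool.
    """
    if isinstance(results, MappingResult):
        results = [results]
    refs = {r.id: r for r in truth.references}
    truth_triples = truth.site_triples()
    truth_pairs = {(label, species) for _, label, species in truth_triples}
    landscape_pairs: set[tuple[str, str]] = set()
    supported: set[tuple[str, str, str]] = set()
    for result in results:
        landscape_pairs |= result.landscape.pairs()
        contributing = {
            match_id
            for by_species in result.landscape.entries.values()
            for entry in by_species.values()
            for match_id in entry.support
        }
        for match_id in contributing:
            for candidate in result.matches[match_id].candidates:
                ref = refs.get(candidate.entry.ref_id)
                if ref is None:
                    continue
                for pos, species, _ in candidate.entry.placements:
                    supported.add((candidate.entry.ref_id, ref.label(pos), species))
    n_recovered = len(truth_triples & supported)
    false_positions = len(landscape_pairs - truth_pairs)
    return RecoveryReport(len(truth_triples), n_recovered, false_positions, landscape_pairs)


def _mass_visible_allowed(
    species_by_base: Mapping[str, Sequence[str]],
    ce: bool,
    registry: ModificationRegistry,
) -> dict[str, tuple[str, ...]]:
    """Drop hypotheses that are mass-silent in this run (Ψ without CE)."""
    from .chem import CYANOETHYL

    allowed: dict[str, tuple[str, ...]] = {}
    for base, names in species_by_base.items():
        base_mass = registry[base].monoisotopic_mass
        visible = []
        for name in names:
            entry = registry[name]
            delta = entry.monoisotopic_mass - base_mass
            if ce and entry.ce_reactive:
                delta += CYANOETHYL
            if abs(delta) > 0.05:
                visible.append(entry.short_name)
        allowed[base] = tuple(visible)
    return allowed


def run_recovery_benchmark(
    seed: int,
    n_refs: int = 5,
    ppm_sigma: float = 2.0,
    dropout: float = 0.1,
    decoy_rate: float = 0.2,
    tol_ppm: float = 10.0,
    replicates: int = 2,
    k: int = 3,
    profile: PlantingProfile | None = None,
    registry: ModificationRegistry | None = None,
) -> tuple[RecoveryReport, GroundTruth, list[MappingResult]]:
    """One seeded end-to-end run: generate, plant, simulate, map, score.

    The simulated study mirrors the standard two-digest protocol: the
    cyanoethylated pool cut with RNase T1 and the natural pool cut with
    RNase A, each observed in duplicate injections (independent per-peak
    detection), matched at the instrument tolerance with the planted
    species as the hypothesis sets (mass-silent hypotheses such as
    un-derivatized Ψ are excluded from the natural run).  The two
    landscapes are combined for scoring.
    """
    registry = registry if registry is not None else default_registry()
    profile = profile or PlantingProfile()
    seeds = [seed * 10 + i for i in range(4)]
    references = generate_reference_set(n_refs, seed=seeds[0], style="trna")
    truth = plant_modifications(references, profile, seed=seeds[1], ce=True, registry=registry)
    rnase_a, rnase_t1 = default_rules(registry)
    results: list[MappingResult] = []
    for rule, run_ce, run_seed in (
        (rnase_t1, True, seeds[2]),
        (rnase_a, False, seeds[3]),
    ):
        peaks, _ = simulate_peaklist(
            truth,
            rule,
            ce=run_ce,
            ppm_sigma=ppm_sigma,
            dropout=dropout,
            decoy_rate=decoy_rate,
            seed=run_seed,
            replicates=replicates,
            registry=registry,
        )
        allowed = _mass_visible_allowed(profile.species_by_base, run_ce, registry)
        results.append(
            map_modifications(
                references,
                peaks,
                rule=rule,
                allowed=allowed,
                k=k,
                ce=run_ce,
                tol_ppm=tol_ppm,
                require_ms2=True,
                registry=registry,
            )
        )
    return score_landscape(truth, results), truth, results
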