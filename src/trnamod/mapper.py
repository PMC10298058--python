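"""Positioning modifications on a tRNA reference set from oligonucleotide MS data.

The workflow re-implemented here is theoretical-first: enumerate, over
every digestion fragment of every reference, all modification
assignments up to a cap ``k``; index the resulting neutral masses; match
observed MS1 peaks inside a ppm window; localize positional isomers with
CID product ions; classify each fragment's placement as unique, shared
but position-consistent (the isoacceptor case), or ambiguous; and
aggregate the consistent assignments into a per-position modification
landscape.

A modification hypothesis must be cleavage-consistent: an internal
residue of a fragment may not be cleavable under the digestion rule
(an internal G must carry a blocking modification, a cyanoethylated
inosine blocks RNase T1, ...), and the 3'-terminal residue must remain
cleavable unless the fragment ends at the parent 3' end.  Missed
cleavages therefore arise exactly where a blocking modification is
hypothesized.
"""

from __future__ import annotations

import itertools
import json
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chem import ModificationRegistry, default_registry
from .digestion import CleavageRule, digest
from .masscalc import (
    cid_products,
    mz_from_neutral,
    neutral_from_mz,
    oligo_neutral_mass,
    ppm_error,
    residue_phosphate_mass,
)
from .modseq import ModifiedResidue, ModifiedSequence

__all__ = [
    "TRnaReference",
    "Peak",
    "IndexEntry",
    "FragmentIndex",
    "CandidateMatch",
    "FragmentMatch",
    "ModificationLandscape",
    "build_fragment_index",
    "match_peaks",
    "localize",
    "classify_uniqueness",
    "assemble_landscape",
    "read_references",
    "write_references",
    "read_peaklist",
    "write_peaklist",
]

COMPARTMENTS = ("cytoplasmic", "mitochondrial", "chloroplastic", "unknown")


@dataclass(frozen=True)
class TRnaReference:
    """An unmodified tRNA reference sequence.

    ``position_map`` optionally converts raw 1-based coordinates to
    canonical tRNA position labels (supporting insertions such as the
    variable-loop ``e`` positions); without it, labels are the raw
    coordinates as strings.  Mature tRNAs carry a 5'-monophosphate and a
    3'-hydroxyl (the CCA end).
    """

    id: str
    sequence: str
    compartment: str = "unknown"
    position_map: tuple[tuple[int, str], ...] | None = None
    five_prime: str = "p"
    three_prime: str = "OH"

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        if not seq or set(seq) - set("ACGU"):
            raise ValueError(f"reference {self.id!r} contains non-ACGU characters")
        object.__setattr__(self, "sequence", seq)
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.position_map is not None and isinstance(self.position_map, dict):
            object.__setattr__(self, "position_map", tuple(sorted(self.position_map.items())))

    def __len__(self) -> int:
        return len(self.sequence)

    def label(self, position: int) -> str:
        """Canonical label of a raw 1-based position."""
        if self.position_map is not None:
            for raw, lab in self.position_map:
                if raw == position:
                    return lab
        return str(position)

    def to_modseq(
        self, planted: Mapping[int, tuple[str, bool]] | None = None
    ) -> ModifiedSequence:
        """The reference as a :class:`ModifiedSequence`, optionally modified.

        ``planted`` maps raw position -> (species short name, ce_labeled).
        """
        residues = []
        planted = planted or {}
        for i, base in enumerate(self.sequence, start=1):
            if i in planted:
                species, ce = planted[i]
                residues.append(ModifiedResidue(base, species, ce_labeled=ce))
            else:
                residues.append(ModifiedResidue(base))
        return ModifiedSequence(tuple(residues), self.five_prime, self.three_prime)


@dataclass(frozen=True)
class Peak:
    """An observed (m/z, charge) record; MS2 peaks link to their precursor m/z."""

    mz: float
    charge: int
    intensity: float | None = None
    level: str = "MS1"
    precursor_mz: float | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.level not in ("MS1", "MS2"):
            raise ValueError(f"level must be MS1 or MS2, got {self.level!r}")


# ---------------------------------------------------------------------------
# reference / peak list I/O
# ---------------------------------------------------------------------------

def read_references(path: str | Path) -> list[TRnaReference]:
    """Read references from FASTA; T is normalized to U.

    A ``compartment=<name>`` token in the description is honoured.
    """
    refs = []
    for record in SeqIO.parse(str(path), "fasta"):
        compartment = "unknown"
        for token in record.description.split():
            if token.startswith("compartment="):
                compartment = token.split("=", 1)[1]
        refs.append(TRnaReference(record.id, str(record.seq), compartment))
    if not refs:
        raise ValueError(f"no FASTA records found in {path}")
    return refs


def write_references(references: Iterable[TRnaReference], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=f"compartment={r.compartment}")
        for r in references
    ]
    SeqIO.write(records, str(path), "fasta")


PEAK_COLUMNS = ("mz", "z", "intensity", "level", "precursor_mz")


def read_peaklist(path: str | Path) -> list[Peak]:
    """Read a delimited peak list with columns mz, z[, intensity, level, precursor_mz]."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    peaks = []
    for row in frame.itertuples(index=False):
        peaks.append(
            Peak(
                mz=float(row.mz),
                charge=int(row.z),
                intensity=None if pd.isna(getattr(row, "intensity", np.nan)) else float(row.intensity),
                level=getattr(row, "level", "MS1"),
                precursor_mz=None
                if pd.isna(getattr(row, "precursor_mz", np.nan))
                else float(row.precursor_mz),
            )
        )
    return peaks


def write_peaklist(peaks: Iterable[Peak], path: str | Path, header_comment: str = "") -> None:
    rows = []
    for p in peaks:
        rows.append(
            {
                "mz": p.mz,
                "z": p.charge,
                "intensity": p.intensity,
                "level": p.level,
                "precursor_mz": p.precursor_mz,
            }
        )
    frame = pd.DataFrame(rows, columns=list(PEAK_COLUMNS))
    with open(path, "w", encoding="utf-8") as handle:
        if header_comment:
            handle.write(f"# {header_comment}\n")
        frame.to_csv(handle, sep="\t", index=False)


# ---------------------------------------------------------------------------
# fragment index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndexEntry:
    """One modification hypothesis for one digestion fragment."""

    ref_id: str
    start: int
    end: int
    sequence: ModifiedSequence
    placements: tuple[tuple[int, str, bool], ...]  # (raw position, species, CE)
    neutral_mass: float

    @property
    def n_mods(self) -> int:
        return len(self.placements)

    def unmodified_string(self) -> str:
        return self.sequence.unmodified_string()


class FragmentIndex:
    """Neutral-mass-sorted hypothesis index, queryable by ppm window."""

    def __init__(
        self,
        entries: Sequence[IndexEntry],
        references: Sequence[TRnaReference],
        rule: CleavageRule,
    ) -> None:
        self.entries = sorted(entries, key=lambda e: e.neutral_mass)
        self.masses = np.array([e.neutral_mass for e in self.entries])
        self.references = {r.id: r for r in references}
        self.rule = rule

    def __len__(self) -> int:
        return len(self.entries)

    def query(self, neutral_mass: float, tol_ppm: float) -> list[IndexEntry]:
        delta = neutral_mass * tol_ppm * 1e-6
        lo = bisect_left(self.masses, neutral_mass - delta)
        hi = bisect_right(self.masses, neutral_mass + delta)
        return self.entries[lo:hi]

    def occurrences(self, unmodified: str) -> list[tuple[str, int]]:
        """All (ref id, 1-based start) substring occurrences over the references."""
        hits = []
        for ref in self.references.values():
            pos = ref.sequence.find(unmodified)
            while pos != -1:
                hits.append((ref.id, pos + 1))
                pos = ref.sequence.find(unmodified, pos + 1)
        return hits


def _residue_options(
    base: str,
    allowed: Mapping[str, Sequence[str]],
    rule: CleavageRule,
    ce: bool,
    registry: ModificationRegistry,
) -> list[tuple[str, bool, float, bool]]:
    """(species, ce_labeled, delta mass, cleavable) options for one base."""
    options = []
    plain_mass = residue_phosphate_mass(ModifiedResidue(base), registry)
    for name in allowed.get(base, ()):
        entry = registry[name]
        if entry.parent_base != base:
            raise ValueError(
                f"species {name!r} has parent {entry.parent_base}, cannot sit on {base}"
            )
        labeled = ce and entry.ce_reactive
        residue = ModifiedResidue(base, entry.short_name, ce_labeled=labeled)
        delta = residue_phosphate_mass(residue, registry) - plain_mass
        options.append((entry.short_name, labeled, delta, rule.cleaves_after(residue)))
    return options


def build_fragment_index(
    references: Sequence[TRnaReference],
    rule: CleavageRule,
    allowed: Mapping[str, Sequence[str]] | None = None,
    k: int = 3,
    ce: bool = True,
    registry: ModificationRegistry | None = None,
) -> FragmentIndex:
    """Enumerate cleavage-consistent modification hypotheses over all digests.

    ``allowed`` maps each base to the candidate modification names for it
    (default: every non-canonical registry species, grouped by parent
    base).  ``k`` caps simultaneous modifications per fragment.  With
    ``ce`` on, hypothesized Ψ/I (and other CE-reactive species) carry the
    cyanoethyl adduct.
    """
    if k < 0:
        raise ValueError("hypothesis cap k must be >= 0")
    if not references:
        raise ValueError("empty reference set")
    registry = registry if registry is not None else default_registry()
    if allowed is None:
        grouped: dict[str, list[str]] = {b: [] for b in "ACGU"}
        for mod in registry:
            if not mod.canonical:
                grouped[mod.parent_base].append(mod.short_name)
        allowed = grouped

    option_cache = {
        base: _residue_options(base, allowed, rule, ce, registry) for base in "ACGU"
    }
    entries: list[IndexEntry] = []
    for ref in references:
        parent = ref.to_modseq()
        n = len(parent)
        units = digest(parent, rule, parent_id=ref.id, missed_cleavages=0)
        bounds = [(f.start, f.end) for f in units]
        for i in range(len(bounds)):
            for j in range(i, min(i + k + 1, len(bounds))):
                start, end = bounds[i][0], bounds[j][1]
                five = parent.five_prime if start == 1 else "OH"
                three = parent.three_prime if end == n else rule.product_three_prime
                base_seq = parent.subsequence(start, end, five, three)
                base_mass = oligo_neutral_mass(base_seq, registry)
                length = end - start + 1
                at_parent_end = end == n
                # internal positions that cleave when unmodified must be blocked
                must_block = [
                    p
                    for p in range(length - 1)
                    if rule.cleaves_after(base_seq.residues[p])
                ]
                if len(must_block) > k:
                    continue
                free = [p for p in range(length) if p not in must_block]
                positional_options: dict[int, list[tuple[str, bool, float]]] = {}
                for p in range(length):
                    opts = option_cache[base_seq.residues[p].base]
                    if p == length - 1 and not at_parent_end:
                        usable = [(s, c, d) for s, c, d, cleaves in opts if cleaves]
                    elif p == length - 1:
                        usable = [(s, c, d) for s, c, d, _ in opts]
                    else:
                        usable = [(s, c, d) for s, c, d, cleaves in opts if not cleaves]
                    positional_options[p] = usable
                if any(not positional_options[p] for p in must_block):
                    continue
                if not must_block:
                    entries.append(
                        IndexEntry(ref.id, start, end, base_seq, (), base_mass)
                    )
                budget = k - len(must_block)
                for extra in range(0, budget + 1):
                    for combo in itertools.combinations(free, extra):
                        positions = tuple(sorted(must_block + list(combo)))
                        if not positions:
                            continue
                        pools = [positional_options[p] for p in positions]
                        if any(not pool for pool in pools):
                            continue
                        for assignment in itertools.product(*pools):
                            placements = tuple(
                                (start + p, s, c)
                                for p, (s, c, _) in zip(positions, assignment)
                            )
                            delta = sum(d for _, _, d in assignment)
                            residues = list(base_seq.residues)
                            for p, (s, c, _) in zip(positions, assignment):
                                residues[p] = ModifiedResidue(residues[p].base, s, c)
                            seq = replace(base_seq, residues=tuple(residues))
                            entries.append(
                                IndexEntry(
                                    ref.id, start, end, seq, placements, base_mass + delta
                                )
                            )
    return FragmentIndex(entries, references, rule)


# ---------------------------------------------------------------------------
# matching, localization, classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateMatch:
    entry: IndexEntry
    theoretical_mz: float
    ppm: float


@dataclass(frozen=True)
class FragmentMatch:
    """An observed MS1 peak with its candidate fragment hypotheses."""

    peak: Peak
    candidates: tuple[CandidateMatch, ...]
    ms2_support: bool = False
    localized: bool = False

    @property
    def best(self) -> CandidateMatch:
        return self.candidates[0]


def _sort_candidates(candidates: list[CandidateMatch]) -> tuple[CandidateMatch, ...]:
    return tuple(
        sorted(
            candidates,
            key=lambda c: (abs(c.ppm), c.entry.n_mods, c.entry.placements),
        )
    )


def match_peaks(
    peaks: Iterable[Peak], index: FragmentIndex, tol_ppm: float = 10.0
) -> list[FragmentMatch]:
    """Match MS1 peaks against the index inside a ppm window.

    Candidates per peak are ordered by |ppm| then by modification count
    (parsimony); peaks without any candidate yield no match.  Matching is
    per-peak, so adding decoy peaks never perturbs the matches of genuine
    peaks.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    matches = []
    for peak in peaks:
        if peak.level != "MS1":
            continue
        neutral = neutral_from_mz(peak.mz, peak.charge, "negative")
        candidates = []
        for entry in index.query(neutral, tol_ppm):
            theo = mz_from_neutral(entry.neutral_mass, peak.charge, "negative")
            ppm = ppm_error(peak.mz, theo)
            if abs(ppm) <= tol_ppm:
                candidates.append(CandidateMatch(entry, theo, ppm))
        if candidates:
            matches.append(FragmentMatch(peak, _sort_candidates(candidates)))
    return matches


def _ms2_for(match: FragmentMatch, ms2_peaks: Sequence[Peak], tol_ppm: float) -> list[Peak]:
    linked = [
        p
        for p in ms2_peaks
        if p.level == "MS2"
        and p.precursor_mz is not None
        and abs(ppm_error(p.precursor_mz, match.peak.mz)) <= tol_ppm
    ]
    if linked:
        return linked
    return [p for p in ms2_peaks if p.level == "MS2" and p.precursor_mz is None]


def localize(
    match: FragmentMatch,
    ms2_peaks: Sequence[Peak],
    tol_ppm: float = 10.0,
    registry: ModificationRegistry | None = None,
) -> FragmentMatch:
    """Score candidate placements against CID product ions.

    Each candidate is scored by the number of theoretical c/d/y/w ions
    (z = 1, 2) matched within tolerance; candidates achieving the maximum
    score are retained.  ``ms2_support`` is set when every retained
    candidate carries one identical modified sequence (isoacceptors
    sharing a fragment count as one placement pattern) and at least one
    matched ion discriminates that pattern from the alternatives (any
    matched ion, when there was no sequence-distinct alternative).
    """
    from .modseq import to_bracket_notation  # deferred: avoids import cycle

    registry = registry if registry is not None else default_registry()
    peaks = _ms2_for(match, ms2_peaks, tol_ppm)
    if not peaks:
        return replace(match, ms2_support=False, localized=False)
    observed = np.sort(np.array([p.mz for p in peaks]))

    def matched_mzs(candidate: CandidateMatch) -> set[float]:
        if len(candidate.entry.sequence) < 2:
            return set()
        hits = set()
        for ion in cid_products(candidate.entry.sequence, (1, 2), registry):
            lo = np.searchsorted(observed, ion.mz * (1 - tol_ppm * 1e-6))
            hi = np.searchsorted(observed, ion.mz * (1 + tol_ppm * 1e-6))
            if hi > lo:
                hits.add(round(ion.mz, 6))
        return hits

    hits_by_pattern: dict[str, set[float]] = {}
    per_candidate: list[tuple[CandidateMatch, str, set[float]]] = []
    for candidate in match.candidates:
        pattern = to_bracket_notation(candidate.entry.sequence)
        if pattern not in hits_by_pattern:
            hits_by_pattern[pattern] = matched_mzs(candidate)
        per_candidate.append((candidate, pattern, hits_by_pattern[pattern]))
    best = max(len(h) for _, _, h in per_candidate)
    survivors = [(c, p, h) for c, p, h in per_candidate if len(h) == best]
    retained = _sort_candidates([c for c, _, _ in survivors])
    winner_patterns = {p for _, p, _ in survivors}
    support = False
    if len(winner_patterns) == 1:
        winner = next(iter(survivors))
        winner_hits = winner[2]
        # a genuine precursor matches most of its ladder; a stray
        # coincidental ion must not count as confirmation
        n = len(winner[0].entry.sequence)
        min_ions = 1 if n <= 2 else max(2, (n - 1) // 2)
        others = [h for p, h in hits_by_pattern.items() if p not in winner_patterns]
        if len(winner_hits) >= min_ions:
            if not others:
                support = True
            else:
                shared = winner_hits.intersection(*others)
                support = bool(winner_hits - shared)
    return replace(match, candidates=retained, ms2_support=support, localized=True)


def classify_uniqueness(
    entry: IndexEntry, index_or_refs: FragmentIndex | Sequence[TRnaReference]
) -> str:
    """unique / shared_consistent / ambiguous placement of one hypothesis.

    The fragment's unmodified residue string is counted over all
    references; multiple occurrences are consistent only if every
    positioned modification maps to one identical position label at every
    occurrence (the isoacceptor pattern).
    """
    if isinstance(index_or_refs, FragmentIndex):
        refs = index_or_refs.references
        occurrences = index_or_refs.occurrences(entry.unmodified_string())
    else:
        refs = {r.id: r for r in index_or_refs}
        occurrences = []
        needle = entry.unmodified_string()
        for ref in refs.values():
            pos = ref.sequence.find(needle)
            while pos != -1:
                occurrences.append((ref.id, pos + 1))
                pos = ref.sequence.find(needle, pos + 1)
    if len(occurrences) == 1:
        return "unique"
    label_sets = []
    for ref_id, occ_start in occurrences:
        ref = refs[ref_id]
        labels = frozenset(
            (ref.label(occ_start + (pos - entry.start)), species)
            for pos, species, _ in entry.placements
        )
        label_sets.append(labels)
    if all(labels == label_sets[0] for labels in label_sets):
        return "shared_consistent"
    return "ambiguous"


@dataclass
class LandscapeEntry:
    position: str
    species: str
    support: list[int] = field(default_factory=list)
    refs: set[str] = field(default_factory=set)
    compartments: set[str] = field(default_factory=set)
    uniqueness: set[str] = field(default_factory=set)


@dataclass
class ModificationLandscape:
    """Aggregated position -> modification assignments plus an ambiguity report."""

    entries: dict[str, dict[str, LandscapeEntry]] = field(default_factory=dict)
    ambiguous: list[FragmentMatch] = field(default_factory=list)

    def add(
        self,
        position: str,
        species: str,
        match_id: int,
        refs: Iterable[str],
        compartments: Iterable[str],
        uniqueness: str,
    ) -> None:
        slot = self.entries.setdefault(position, {}).setdefault(
            species, LandscapeEntry(position, species)
        )
        slot.support.append(match_id)
        slot.refs.update(refs)
        slot.compartments.update(compartments)
        slot.uniqueness.add(uniqueness)

    def pairs(self) -> set[tuple[str, str]]:
        return {
            (position, species)
            for position, by_species in self.entries.items()
            for species in by_species
        }

    def to_records(self) -> list[dict]:
        records = []
        for position in sorted(self.entries, key=_position_sort_key):
            for species, entry in sorted(self.entries[position].items()):
                records.append(
                    {
                        "position": position,
                        "modification": species,
                        "support": len(entry.support),
                        "uniqueness": ";".join(sorted(entry.uniqueness)),
                        "references": ";".join(sorted(entry.refs)),
                        "compartments": ";".join(sorted(entry.compartments)),
                    }
                )
        return records

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.to_records(),
            columns=[
                "position",
                "modification",
                "support",
                "uniqueness",
                "references",
                "compartments",
            ],
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_records(), indent=1, ensure_ascii=False))


def _position_sort_key(label: str):
    digits = "".join(ch for ch in label if ch.isdigit())
    return (int(digits) if digits else 0, label)


def assemble_landscape(
    matches: Sequence[FragmentMatch],
    references: Sequence[TRnaReference] | FragmentIndex,
    require_ms2: bool = True,
) -> ModificationLandscape:
    """Aggregate localized matches into the modification landscape.

    A match contributes iff every retained candidate asserts one
    identical (position label, species) set and (by default) the
    placement has MS2 support; everything else lands in the ambiguity
    report.  Because the index enumerates every cleavage-consistent
    hypothesis, the retained candidate set is the complete ambiguity
    measure at the observed mass: a single candidate is a unique
    placement, several candidates agreeing on one label set are the
    shared-consistent isoacceptor case.
    """
    if isinstance(references, FragmentIndex):
        refs = references.references
    else:
        refs = {r.id: r for r in references}
    landscape = ModificationLandscape()
    for match_id, match in enumerate(matches):
        modified = [c for c in match.candidates if c.entry.placements]
        if not modified:
            continue
        if len(modified) != len(match.candidates):
            # modified and unmodified explanations coexist: undecidable
            landscape.ambiguous.append(match)
            continue
        label_sets = []
        for candidate in modified:
            ref = refs[candidate.entry.ref_id]
            label_sets.append(
                frozenset(
                    (ref.label(pos), species)
                    for pos, species, _ in candidate.entry.placements
                )
            )
        consensus = all(s == label_sets[0] for s in label_sets)
        if not consensus or (require_ms2 and not match.ms2_support):
            landscape.ambiguous.append(match)
            continue
        uniqueness = "unique" if len(modified) == 1 else "shared_consistent"
        involved_refs = {c.entry.ref_id for c in modified}
        compartments = {refs[r].compartment for r in involved_refs}
        for position, species in label_sets[0]:
            landscape.add(
                position,
                species,
                match_id,
                involved_refs,
                compartments,
                uniqueness,
            )
    return landscape
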