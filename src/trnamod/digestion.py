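"""In-silico RNase A and RNase T1 digestion with configurable blocking.

RNase T1 cleaves 3' of guanosine (and, by default, of unlabeled
inosine); 2'-O-methylation (Gm) and base methylation of G (m^1^G, m^2^G,
m^2,2^G, m^7^G, wyosine derivatives) block it, as does the cyanoethyl
adduct on inosine.  RNase A cleaves 3' of pyrimidines, including Ψ and
base-modified pyrimidines, and is blocked by 2'-O-methylation (Um, Cm,
cmnm^5^Um) and optionally by dihydrouridine.  Products carry 5'-OH and
3'-linear phosphate (the convention under which the fragment masses of
cyanoethylated tRNA digests reproduce); a cyclic-phosphate variant is
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem import ModificationRegistry, default_registry, normalize_name
from .modseq import ModifiedResidue, ModifiedSequence

__all__ = ["CleavageRule", "Fragment", "digest", "default_rules"]


@dataclass(frozen=True)
class CleavageRule:
    """Cleavage specificity of one endoribonuclease.

    ``blocked_species`` holds normalized species names that never cleave;
    ``ce_blocks`` adds cyanoethylation as a blocking event (RNase T1 on
    inosine).
    """

    enzyme: str
    registry: ModificationRegistry = field(compare=False)
    blocked_species: frozenset[str] = frozenset()
    cleave_inosine: bool = True
    ce_blocks: bool = True
    product_three_prime: str = "p"

    def cleaves_after(self, residue: ModifiedResidue) -> bool:
        species = normalize_name(residue.species)
        if species in self.blocked_species:
            return False
        if residue.ce_labeled and self.ce_blocks:
            return False
        entry = self.registry[residue.species]
        if self.enzyme == "RNaseT1":
            if species == "I":
                return self.cleave_inosine
            return entry.is_guanosine_like
        if self.enzyme == "RNaseA":
            return entry.is_pyrimidine_like
        raise ValueError(f"unknown enzyme {self.enzyme!r}")

    def without_blocking(self, species: str) -> "CleavageRule":
        blocked = self.blocked_species - {normalize_name(species)}
        return CleavageRule(
            self.enzyme,
            self.registry,
            blocked,
            self.cleave_inosine,
            self.ce_blocks,
            self.product_three_prime,
        )


@dataclass(frozen=True)
class Fragment:
    """A digestion product with 1-based inclusive parent coordinates."""

    sequence: ModifiedSequence
    parent_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("fragment coordinates inconsistent with its length")


def default_rules(
    registry: ModificationRegistry | None = None,
    cleave_inosine: bool = True,
    block_dihydrouridine: bool = False,
    product_three_prime: str = "p",
) -> tuple[CleavageRule, CleavageRule]:
    """The default (RNase A, RNase T1) rule pair.

    Blocked sets are read off the registry flags so that a user-registered
    species participates automatically.  Ψ cyanoethylation does not block
    RNase A by default; inosine cyanoethylation blocks RNase T1.
    """
    registry = registry if registry is not None else default_registry()
    blocked_a = {normalize_name(m.short_name) for m in registry if m.blocks_rnase_a}
    if block_dihydrouridine:
        blocked_a.add("D")
    blocked_t1 = {normalize_name(m.short_name) for m in registry if m.blocks_rnase_t1}
    rnase_a = CleavageRule(
        "RNaseA",
        registry,
        frozenset(blocked_a),
        cleave_inosine=cleave_inosine,
        ce_blocks=False,
        product_three_prime=product_three_prime,
    )
    rnase_t1 = CleavageRule(
        "RNaseT1",
        registry,
        frozenset(blocked_t1),
        cleave_inosine=cleave_inosine,
        ce_blocks=True,
        product_three_prime=product_three_prime,
    )
    return rnase_a, rnase_t1


def digest(
    parent: ModifiedSequence,
    rule: CleavageRule,
    parent_id: str = "",
    missed_cleavages: int = 0,
) -> list[Fragment]:
    """Complete digestion of ``parent``; optionally include missed-cleavage unions.

    With ``missed_cleavages = 0`` the maximal-cleavage fragments tile the
    parent in 5'->3' order.  Internal products get 5'-OH and the rule's 3'
    terminus; the first and last fragments inherit the parent termini.
    With ``k`` missed cleavages, all unions of up to ``k + 1`` adjacent
    fragments are additionally returned, sorted by (start, end).
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    n = len(parent)
    cut_after = [rule.cleaves_after(parent.residues[i]) for i in range(n)]
    bounds: list[tuple[int, int]] = []
    start = 1
    for i in range(1, n + 1):
        if i == n or cut_after[i - 1]:
            bounds.append((start, i))
            start = i + 1
    def build(s: int, e: int) -> Fragment:
        five = parent.five_prime if s == 1 else "OH"
        three = parent.three_prime if e == n else rule.product_three_prime
        return Fragment(parent.subsequence(s, e, five, three), parent_id, s, e)

    fragments = [build(s, e) for s, e in bounds]
    if missed_cleavages:
        for span in range(2, missed_cleavages + 2):
            for i in range(len(bounds) - span + 1):
                fragments.append(build(bounds[i][0], bounds[i + span - 1][1]))
        fragments.sort(key=lambda f: (f.start, f.end))
    return fragments
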