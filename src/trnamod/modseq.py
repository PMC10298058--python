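"""Bracket notation for modified oligonucleotides.

The notation used in RNA-MS fragment tables: an optional leading ``p``
(5'-monophosphate), one token per residue — a bare base letter or a
bracketed modification name, optionally suffixed ``-CE`` for a
cyanoethylated residue — and a terminator ``p`` (3'-linear phosphate),
``>p`` (2',3'-cyclic phosphate) or ``OH`` (3'-hydroxyl, the default).
Examples: ``p[Ψ-CE]CCUC[I-CE]Gp``, ``CC[m^5^C][Ψ-CE]CCAOH``, ``ACGU``.

Coordinates elsewhere in the package are 1-based and inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable

from .chem import ModificationRegistry, default_registry, normalize_name

__all__ = [
    "ModifiedResidue",
    "ModifiedSequence",
    "parse_bracket_notation",
    "to_bracket_notation",
    "cyanoethylate",
]

FIVE_PRIME_STATES = ("OH", "p")
THREE_PRIME_STATES = ("OH", "p", ">p")


@dataclass(frozen=True)
class ModifiedResidue:
    """One residue: a parent base, an optional modification, and a CE flag."""

    base: str
    modification: str | None = None
    ce_labeled: bool = False

    def __post_init__(self) -> None:
        if self.base not in "ACGU":
            raise ValueError(f"base must be one of A/C/G/U, got {self.base!r}")

    @property
    def species(self) -> str:
        """The effective species name: the modification if present, else the base."""
        return self.modification if self.modification is not None else self.base


@dataclass(frozen=True)
class ModifiedSequence:
    """An oligonucleotide with explicit 5'/3' terminus chemistry."""

    residues: tuple[ModifiedResidue, ...]
    five_prime: str = "OH"
    three_prime: str = "OH"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("a sequence needs at least one residue")
        if self.five_prime not in FIVE_PRIME_STATES:
            raise ValueError(f"invalid 5' terminus {self.five_prime!r}")
        if self.three_prime not in THREE_PRIME_STATES:
            raise ValueError(f"invalid 3' terminus {self.three_prime!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def unmodified_string(self) -> str:
        """The plain base string, modifications stripped (I reads as A)."""
        return "".join(r.base for r in self.residues)

    def ce_count(self) -> int:
        return sum(r.ce_labeled for r in self.residues)

    def subsequence(
        self, start: int, end: int, five_prime: str, three_prime: str
    ) -> "ModifiedSequence":
        """1-based inclusive slice with explicit termini."""
        if not (1 <= start <= end <= len(self)):
            raise ValueError(f"invalid slice [{start}, {end}] of length {len(self)}")
        return ModifiedSequence(self.residues[start - 1 : end], five_prime, three_prime)


_TOKEN = re.compile(r"\[([^\]]+)\]|([ACGUI])")


def _registry_or_default(registry: ModificationRegistry | None) -> ModificationRegistry:
    return registry if registry is not None else default_registry()


def parse_bracket_notation(
    text: str, registry: ModificationRegistry | None = None
) -> ModifiedSequence:
    """Parse bracket notation into a :class:`ModifiedSequence`.

    A bare ``I`` in the body is accepted as sugar for ``[I]`` (inosine is
    modelled as a modification on parent base A).  Caret-free names
    (``m1G``) and the ASCII alias ``Y`` for Ψ are normalized on input.
    """
    registry = _registry_or_default(registry)
    text = text.strip()
    five_prime = "OH"
    three_prime = "OH"
    if text.startswith("p"):
        five_prime = "p"
        text = text[1:]
    if text.endswith("OH"):
        text = text[:-2]
    elif text.endswith(">p"):
        three_prime = ">p"
        text = text[:-2]
    elif text.endswith("p"):
        three_prime = "p"
        text = text[:-1]
    residues: list[ModifiedResidue] = []
    pos = 0
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"cannot parse {text!r} at position {pos}")
        bracket, bare = match.groups()
        if bare is not None:
            if bare == "I":
                residues.append(ModifiedResidue("A", "I"))
            else:
                residues.append(ModifiedResidue(bare))
        else:
            name = bracket
            ce = False
            if name.endswith("-CE"):
                ce = True
                name = name[:-3]
            entry = registry[name]  # raises KeyError naming the species
            if ce and not entry.ce_reactive:
                raise ValueError(
                    f"species {entry.short_name!r} is not cyanoethylation-reactive"
                )
            if entry.canonical:
                residues.append(ModifiedResidue(entry.short_name))
            else:
                residues.append(
                    ModifiedResidue(entry.parent_base, entry.short_name, ce_labeled=ce)
                )
        pos = match.end()
    if pos != len(text):
        raise ValueError(f"cannot parse {text!r} at position {pos}")
    if not residues:
        raise ValueError("empty sequence")
    return ModifiedSequence(tuple(residues), five_prime, three_prime)


def to_bracket_notation(seq: ModifiedSequence) -> str:
    """Canonical rendering; ``parse(render(s)) == s``.

    The 3'-hydroxyl terminus renders explicitly as ``OH`` (the style used
    for intact tRNA 3'-CCA ends).
    """
    parts: list[str] = ["p"] if seq.five_prime == "p" else []
    for residue in seq.residues:
        if residue.modification is None:
            parts.append(residue.base)
        else:
            suffix = "-CE" if residue.ce_labeled else ""
            parts.append(f"[{residue.modification}{suffix}]")
    parts.append({"OH": "OH", "p": "p", ">p": ">p"}[seq.three_prime])
    return "".join(parts)


def cyanoethylate(
    seq: ModifiedSequence,
    targets: Iterable[str] = ("Ψ", "I"),
    registry: ModificationRegistry | None = None,
) -> ModifiedSequence:
    """Label every residue whose species is in ``targets`` with a CE adduct.

    Models complete acrylonitrile derivatization (the reaction is driven
    to completion before digestion); idempotent, termini unchanged.
    """
    registry = _registry_or_default(registry)
    target_names = set()
    for name in targets:
        entry = registry[name]
        if not entry.ce_reactive:
            raise ValueError(f"species {entry.short_name!r} is not cyanoethylation-reactive")
        target_names.add(normalize_name(entry.short_name))
    residues = tuple(
        replace(r, ce_labeled=True)
        if normalize_name(r.species) in target_names
        else r
        for r in seq.residues
    )
    return replace(seq, residues=residues)
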