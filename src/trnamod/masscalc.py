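"""Neutral masses, charge-state m/z, and CID product-ion series.

An oligonucleotide's neutral monoisotopic mass is the sum of its
nucleoside-3'-monophosphate residue masses minus one water per internal
phosphodiester, adjusted for the termini (+HPO3 for a 5'-monophosphate,
-HPO3 for a 3'-hydroxyl, -H2O for a 2',3'-cyclic phosphate) and +C3H3N
per cyanoethylated residue.  The only charge carrier is the proton:
negative-mode m/z = (M - z*1.0072765)/z.

CID product ions follow the dominant nucleic-acid series: for a break at
phosphodiester i, c_i is the 5' prefix ending in 3'-phosphate, d_i the
prefix ending in 3'-OH, y_j the 3' suffix starting 5'-OH, and w_j the
suffix starting 5'-phosphate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .chem import (
    CYANOETHYL,
    PHOSPHATE_HPO3,
    PROTON_MASS,
    WATER,
    ModificationRegistry,
    default_registry,
)
from .modseq import ModifiedResidue, ModifiedSequence

__all__ = [
    "oligo_neutral_mass",
    "oligo_mz",
    "mz_from_neutral",
    "neutral_from_mz",
    "nucleoside_mz",
    "ppm_error",
    "ProductIon",
    "cid_products",
]

PRODUCT_SERIES = ("c", "d", "y", "w")


def _registry_or_default(registry: ModificationRegistry | None) -> ModificationRegistry:
    return registry if registry is not None else default_registry()


def residue_phosphate_mass(
    residue: ModifiedResidue, registry: ModificationRegistry | None = None
) -> float:
    """Mass of the residue as a nucleoside-3'-monophosphate, CE included."""
    registry = _registry_or_default(registry)
    mass = registry[residue.species].monoisotopic_mass + PHOSPHATE_HPO3
    if residue.ce_labeled:
        mass += CYANOETHYL
    return mass


def oligo_neutral_mass(
    seq: ModifiedSequence, registry: ModificationRegistry | None = None
) -> float:
    registry = _registry_or_default(registry)
    mass = sum(residue_phosphate_mass(r, registry) for r in seq.residues)
    mass -= (len(seq) - 1) * WATER
    if seq.five_prime == "p":
        mass += PHOSPHATE_HPO3
    if seq.three_prime == "OH":
        mass -= PHOSPHATE_HPO3
    elif seq.three_prime == ">p":
        mass -= WATER
    return mass


def mz_from_neutral(neutral_mass: float, z: int, polarity: str = "negative") -> float:
    if z == 0:
        raise ValueError("charge must be non-zero")
    z = abs(int(z))
    if polarity == "negative":
        return (neutral_mass - z * PROTON_MASS) / z
    if polarity == "positive":
        return (neutral_mass + z * PROTON_MASS) / z
    raise ValueError(f"polarity must be 'positive' or 'negative', got {polarity!r}")


def neutral_from_mz(mz: float, z: int, polarity: str = "negative") -> float:
    z = abs(int(z))
    if polarity == "negative":
        return mz * z + z * PROTON_MASS
    return mz * z - z * PROTON_MASS


def oligo_mz(
    seq: ModifiedSequence,
    z: int,
    polarity: str = "negative",
    registry: ModificationRegistry | None = None,
) -> float:
    return mz_from_neutral(oligo_neutral_mass(seq, registry), z, polarity)


def nucleoside_mz(
    short_name: str,
    registry: ModificationRegistry | None = None,
    polarity: str = "positive",
) -> float:
    """Protonated (or deprotonated) m/z of a free nucleoside at z = 1."""
    registry = _registry_or_default(registry)
    entry = registry[short_name]
    if polarity == "positive" and not entry.esi_positive:
        raise ValueError(
            f"{entry.short_name!r} is not observable in positive ESI "
            "(negatively charged species)"
        )
    return mz_from_neutral(entry.monoisotopic_mass, 1, polarity)


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative error in parts per million, computed on m/z."""
    return 1e6 * (observed_mz - theoretical_mz) / theoretical_mz


@dataclass(frozen=True)
class ProductIon:
    series: str
    index: int  # residues counted from the respective terminus
    neutral_mass: float
    charge: int
    mz: float


def cid_products(
    seq: ModifiedSequence,
    z_range: Iterable[int] = (1, 2),
    registry: ModificationRegistry | None = None,
    series: Sequence[str] = PRODUCT_SERIES,
) -> list[ProductIon]:
    """Deprotonated c/d/y/w fragment ions for every internal phosphodiester.

    Modification and CE masses ride with their residue, so positional
    isomers yield distinct ladders.  Neutral complementarity:
    c_i + y_(n-i) = precursor + H2O.
    """
    if len(seq) < 2:
        raise ValueError("CID products require at least 2 residues")
    registry = _registry_or_default(registry)
    masses = [residue_phosphate_mass(r, registry) for r in seq.residues]
    n = len(masses)
    five_adj = PHOSPHATE_HPO3 if seq.five_prime == "p" else 0.0
    if seq.three_prime == "OH":
        three_adj = -PHOSPHATE_HPO3
    elif seq.three_prime == ">p":
        three_adj = -WATER
    else:
        three_adj = 0.0
    ions: list[ProductIon] = []
    prefix = 0.0
    total = sum(masses)
    for i in range(1, n):
        prefix += masses[i - 1]
        c_i = prefix - (i - 1) * WATER + five_adj
        suffix = total - prefix
        j = n - i
        y_j = suffix - (j - 1) * WATER + three_adj
        neutral = {"c": c_i, "d": c_i - PHOSPHATE_HPO3, "y": y_j, "w": y_j + PHOSPHATE_HPO3}
        for name in series:
            for z in z_range:
                ions.append(
                    ProductIon(
                        series=name,
                        index=i if name in ("c", "d") else j,
                        neutral_mass=neutral[name],
                        charge=z,
                        mz=mz_from_neutral(neutral[name], z, "negative"),
                    )
                )
    return ions
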