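"""Elemental-formula arithmetic and the modified-nucleoside registry.

Monoisotopic element masses come from the NIST table shipped with
:mod:`pyteomics` (most-abundant-isotope masses, >=9 decimal places).
The registry stores full nucleoside formulas; mass deltas (methylation
+CH2, cyanoethylation +C3H3N, ...) are obtained by formula subtraction
rather than being hard-coded, so any registered species is
automatically mass-enabled downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from pyteomics.mass import nist_mass

__all__ = [
    "ElementalFormula",
    "Modification",
    "ModificationRegistry",
    "monoisotopic_mass",
    "default_registry",
    "PROTON_MASS",
    "WATER",
    "PHOSPHATE_HPO3",
    "CYANOETHYL",
]

#: Mass of the charge-carrying proton (pure (de)protonation, no adduct cations).
PROTON_MASS = 1.0072765

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _element_mass(symbol: str) -> float:
    try:
        return nist_mass[symbol][0][0]
    except KeyError:
        raise ValueError(f"unknown element symbol: {symbol!r}") from None


@dataclass(frozen=True)
class ElementalFormula(Mapping[str, int]):
    """An immutable element -> count mapping with element-wise arithmetic.

    Counts are non-negative integers; an absent element is equivalent to
    count zero.  Subtraction that would drive any count below zero is an
    error.
    """

    counts: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        cleaned: dict[str, int] = {}
        for symbol, n in self.counts:
            if n < 0 or n != int(n):
                raise ValueError(f"negative or non-integer count for {symbol}: {n}")
            if n:
                cleaned[symbol] = cleaned.get(symbol, 0) + int(n)
        object.__setattr__(self, "counts", tuple(sorted(cleaned.items())))

    # -- construction -------------------------------------------------
    @classmethod
    def from_dict(cls, mapping: Mapping[str, int]) -> "ElementalFormula":
        return cls(tuple(mapping.items()))

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``"C10H13N5O4"``."""
        text = text.strip()
        if not text:
            return cls()
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            symbol, digits = match.groups()
            _element_mass(symbol)  # validate early
            counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        return cls.from_dict(counts)

    # -- mapping protocol ---------------------------------------------
    def __getitem__(self, symbol: str) -> int:
        return dict(self.counts).get(symbol, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(s for s, _ in self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for symbol, n in other.counts:
            merged[symbol] = merged.get(symbol, 0) + n
        return ElementalFormula.from_dict(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for symbol, n in other.counts:
            merged[symbol] = merged.get(symbol, 0) - n
            if merged[symbol] < 0:
                raise ValueError(
                    f"subtraction drives element {symbol} below zero"
                )
        return ElementalFormula.from_dict(merged)

    def hill_string(self) -> str:
        """Render in Hill order (C first, H second, others alphabetical)."""
        d = dict(self.counts)
        parts: list[str] = []
        for symbol in ["C", "H"] + sorted(k for k in d if k not in ("C", "H")):
            if d.get(symbol):
                n = d[symbol]
                parts.append(symbol + (str(n) if n != 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill_string()


def monoisotopic_mass(formula: ElementalFormula | Mapping[str, int] | str) -> float:
    """Monoisotopic mass in Da: sum of count x most-abundant-isotope mass."""
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    return sum(_element_mass(symbol) * n for symbol, n in formula.items())


WATER = monoisotopic_mass("H2O")
PHOSPHATE_HPO3 = monoisotopic_mass("HPO3")
#: Cyanoethyl adduct added by acrylonitrile derivatization of Psi and inosine.
CYANOETHYL = monoisotopic_mass("C3H3N")

_ALIASES = {"Y": "Ψ"}  # ASCII alias for the pseudouridine symbol


def normalize_name(name: str) -> str:
    """Normalize a species name: strip caret markup and map ASCII aliases.

    ``"m^1^G"`` and ``"m1G"`` normalize identically; a bare ``"Y"`` is the
    ASCII alias of the pseudouridine symbol.
    """
    name = name.strip()
    name = _ALIASES.get(name, name)
    return name.replace("^", "")


@dataclass(frozen=True)
class Modification:
    """A registry entry for a (possibly modified) nucleoside.

    ``formula`` is the neutral free-nucleoside composition.  The cleavage
    flags drive the default RNase rules; ``esi_positive`` is False for
    species such as Ar(p) that carry a negative charge and are not seen
    in the positive-ESI nucleoside analysis.
    """

    short_name: str
    parent_base: str
    formula: ElementalFormula
    is_pyrimidine_like: bool = False
    is_guanosine_like: bool = False
    ce_reactive: bool = False
    blocks_rnase_a: bool = False
    blocks_rnase_t1: bool = False
    esi_positive: bool = True
    canonical: bool = False
    known_positions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.parent_base not in "ACGU":
            raise ValueError(f"parent base must be one of A/C/G/U, got {self.parent_base!r}")
        if self.monoisotopic_mass <= 0:
            raise ValueError(
                f"modification {self.short_name!r} must have a strictly positive mass"
            )

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self.formula)

    @property
    def mz_positive(self) -> float:
        """Protonated [M+H]+ m/z of the free nucleoside."""
        return self.monoisotopic_mass + PROTON_MASS


class ModificationRegistry:
    """Lookup table of modifications keyed by normalized short name."""

    def __init__(self, modifications: Iterable[Modification] = ()) -> None:
        self._entries: dict[str, Modification] = {}
        for mod in modifications:
            self.register(mod)

    def register(self, modification: Modification, overwrite: bool = False) -> None:
        key = normalize_name(modification.short_name)
        if key in self._entries and not overwrite:
            raise ValueError(
                f"modification {modification.short_name!r} already registered"
            )
        self._entries[key] = modification

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self._entries

    def __getitem__(self, name: str) -> Modification:
        key = normalize_name(name)
        try:
            return self._entries[key]
        except KeyError:
            raise KeyError(f"unknown modification: {name!r}") from None

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[Modification]:
        return iter(self._entries.values())

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.short_name for m in self._entries.values())

    def isomer_group(self, mz: float, tol_ppm: float = 10.0) -> set[str]:
        """All species whose [M+H]+ lies within ``tol_ppm`` of the query m/z.

        Species invisible to positive ESI are excluded; the query must be
        positive.
        """
        if mz <= 0:
            raise ValueError("query m/z must be positive")
        if tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")
        group = set()
        for mod in self:
            if not mod.esi_positive:
                continue
            if abs(mod.mz_positive - mz) / mz * 1e6 <= tol_ppm:
                group.add(mod.short_name)
        return group

    def ce_reactive_names(self) -> frozenset[str]:
        return frozenset(m.short_name for m in self if m.ce_reactive)

    # -- serialization -------------------------------------------------
    _COLUMNS = (
        "short_name",
        "parent_base",
        "formula",
        "pyrimidine_like",
        "guanosine_like",
        "ce_reactive",
        "blocks_rnase_a",
        "blocks_rnase_t1",
        "esi_positive",
        "canonical",
        "known_positions",
    )

    @classmethod
    def from_table(cls, path_or_lines: Path | str | Iterable[str]) -> "ModificationRegistry":
        if isinstance(path_or_lines, (str, Path)):
            lines = Path(path_or_lines).read_text(encoding="utf-8").splitlines()
        else:
            lines = list(path_or_lines)
        registry = cls()
        header: list[str] | None = None
        for line in lines:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = set(cls._COLUMNS) - set(header)
                if missing:
                    raise ValueError(f"registry table missing columns: {sorted(missing)}")
                continue
            row = dict(zip(header, fields))
            positions = tuple(
                p for p in row["known_positions"].split(",") if p and p != "-"
            )
            registry.register(
                Modification(
                    short_name=row["short_name"],
                    parent_base=row["parent_base"],
                    formula=ElementalFormula.parse(row["formula"]),
                    is_pyrimidine_like=row["pyrimidine_like"] == "1",
                    is_guanosine_like=row["guanosine_like"] == "1",
                    ce_reactive=row["ce_reactive"] == "1",
                    blocks_rnase_a=row["blocks_rnase_a"] == "1",
                    blocks_rnase_t1=row["blocks_rnase_t1"] == "1",
                    esi_positive=row["esi_positive"] == "1",
                    canonical=row["canonical"] == "1",
                    known_positions=positions,
                )
            )
        return registry

    def to_table(self, path: Path | str) -> None:
        rows = ["\t".join(self._COLUMNS)]
        for m in self:
            rows.append(
                "\t".join(
                    [
                        m.short_name,
                        m.parent_base,
                        m.formula.hill_string(),
                        "1" if m.is_pyrimidine_like else "0",
                        "1" if m.is_guanosine_like else "0",
                        "1" if m.ce_reactive else "0",
                        "1" if m.blocks_rnase_a else "0",
                        "1" if m.blocks_rnase_t1 else "0",
                        "1" if m.esi_positive else "0",
                        "1" if m.canonical else "0",
                        ",".join(m.known_positions) or "-",
                    ]
                )
            )
        Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


@lru_cache(maxsize=1)
def default_registry() -> ModificationRegistry:
    """The packaged registry of coconut-tRNA nucleosides and modifications."""
    table = resources.files("trnamod").joinpath("data/modifications.tsv")
    return ModificationRegistry.from_table(table.read_text(encoding="utf-8").splitlines())
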