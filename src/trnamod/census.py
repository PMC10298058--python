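"""MS1 nucleoside census: match positive-mode peaks to the registry.

Free nucleosides released by complete enzymatic digestion are observed
as [M+H]+ ions.  Several modifications are exact-mass isomers (2'-O- vs
base methylation), so a peak is reported against its whole isomer group;
distinguishing members needs retention-time standards, which are carried
only as an opaque annotation here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .chem import ModificationRegistry, default_registry
from .masscalc import ppm_error

__all__ = ["CensusEntry", "census", "write_census"]


@dataclass(frozen=True)
class CensusEntry:
    """One matched MS1 peak with its isomer group."""

    mz: float
    group: tuple[str, ...]
    ppm: tuple[float, ...]
    unmodified: bool
    intensity: float | None = None
    confirmed_by_standard: bool | None = None

    def __post_init__(self) -> None:
        if not self.group:
            raise ValueError("a census entry needs a non-empty isomer group")


def census(
    ms1_peaks: Iterable[tuple[float, float | None] | float],
    registry: ModificationRegistry | None = None,
    tol_ppm: float = 10.0,
    annotations: dict[float, bool] | None = None,
) -> tuple[list[CensusEntry], list[float]]:
    """Match positive-mode z=+1 peaks against the registry at ``tol_ppm``.

    Peaks are (m/z, intensity) pairs or bare m/z values.  Returns the
    matched entries and the residual list of unmatched m/z values.  The
    four canonical nucleosides match but are flagged ``unmodified``.
    """
    registry = registry if registry is not None else default_registry()
    annotations = annotations or {}
    entries: list[CensusEntry] = []
    residual: list[float] = []
    for peak in ms1_peaks:
        if isinstance(peak, (tuple, list)):
            mz, intensity = float(peak[0]), peak[1]
        else:
            mz, intensity = float(peak), None
        if mz <= 0:
            raise ValueError(f"non-positive m/z in peak list: {mz}")
        group = sorted(registry.isomer_group(mz, tol_ppm))
        if not group:
            residual.append(mz)
            continue
        entries.append(
            CensusEntry(
                mz=mz,
                group=tuple(group),
                ppm=tuple(ppm_error(mz, registry[name].mz_positive) for name in group),
                unmodified=all(registry[name].canonical for name in group),
                intensity=None if intensity is None else float(intensity),
                confirmed_by_standard=annotations.get(mz),
            )
        )
    return entries, residual


def write_census(
    entries: Iterable[CensusEntry], residual: Iterable[float], path: str | Path
) -> None:
    rows = [
        {
            "mz": e.mz,
            "isomer_group": ";".join(e.group),
            "ppm": ";".join(f"{p:.2f}" for p in e.ppm),
            "unmodified": int(e.unmodified),
            "intensity": e.intensity,
            "confirmed_by_standard": e.confirmed_by_standard,
        }
        for e in entries
    ]
    frame = pd.DataFrame(
        rows,
        columns=["mz", "isomer_group", "ppm", "unmodified", "intensity", "confirmed_by_standard"],
    )
    with open(path, "w", encoding="utf-8") as handle:
        frame.to_csv(handle, sep="\t", index=False)
        for mz in residual:
            handle.write(f"# residual\t{mz}\n")
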