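"""Expression screen: FPKM->TPM conversion and a per-gene Pearson correlation
of modifying-enzyme expression against a salinity time course.

The design follows a two-variety salt-stress experiment (varieties BD
and XS sampled at 0 h, 4 h, 6 d and 10 d after 200 mM NaCl): per gene
and per variety, the Pearson r of TPM against a numeric encoding of the
timepoints, with a two-sided t test on n-2 degrees of freedom and a raw
p < alpha cutoff (no multiple-testing correction by default, as in the
original screen; Benjamini-Hochberg is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TIMEPOINTS",
    "VARIETIES",
    "ExpressionMatrix",
    "CorrelationResult",
    "fpkm_to_tpm",
    "pearson_screen",
    "read_expression",
    "write_results",
]

TIMEPOINTS = ("0h", "4h", "6d", "10d")
VARIETIES = ("BD", "XS")

#: Numeric covariates for the time course: ordered-rank (default) or hours.
TIME_ENCODINGS: dict[str, dict[str, float]] = {
    "rank": {"0h": 0.0, "4h": 1.0, "6d": 2.0, "10d": 3.0},
    "hours": {"0h": 0.0, "4h": 4.0, "6d": 144.0, "10d": 240.0},
}


@dataclass
class ExpressionMatrix:
    """Genes x samples abundances with variety/timepoint sample metadata."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    metadata: pd.DataFrame  # index: sample ids, columns: variety, timepoint
    unit: str = "FPKM"

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.unit not in ("FPKM", "TPM"):
            raise ValueError(f"unit must be FPKM or TPM, got {self.unit!r}")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        bad_tp = set(self.metadata["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def samples_of(self, variety: str) -> list[str]:
        meta = self.metadata.loc[list(self.values.columns)]
        return list(meta.index[meta["variety"] == variety])


def fpkm_to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-sample renormalization: TPM_g = FPKM_g / sum(FPKM) * 1e6.

    Idempotent on TPM input (renormalizes to column sums of one million).
    """
    sums = matrix.values.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    values = matrix.values.div(sums, axis=1) * 1e6
    return ExpressionMatrix(values, matrix.metadata, unit="TPM")


@dataclass(frozen=True)
class CorrelationResult:
    gene: str
    variety: str
    r: float
    p: float
    significant: bool
    direction: str  # "positive" / "negative" / "undefined"
    degenerate: bool = False  # |r| = 1 or zero variance


def _covariate(
    metadata: pd.DataFrame, samples: list[str], time_encoding: str | Mapping[str, float]
) -> np.ndarray:
    if isinstance(time_encoding, str):
        try:
            encoding = TIME_ENCODINGS[time_encoding]
        except KeyError:
            raise ValueError(
                f"unknown time encoding {time_encoding!r}; use one of {sorted(TIME_ENCODINGS)}"
            ) from None
    else:
        encoding = dict(time_encoding)
    values = []
    for sample in samples:
        tp = metadata.loc[sample, "timepoint"]
        value = encoding[tp]
        if not np.isfinite(float(value)):
            raise ValueError(f"non-numeric covariate for timepoint {tp!r}")
        values.append(float(value))
    return np.array(values)


def pearson_screen(
    matrix: ExpressionMatrix,
    time_encoding: str | Mapping[str, float] = "rank",
    alpha: float = 0.05,
    pooled: bool = False,
    benjamini_hochberg: bool = False,
) -> list[CorrelationResult]:
    """Per-gene, per-variety Pearson correlation of TPM against time.

    FPKM input is converted to TPM first.  p is the two-sided tail of
    t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.  Genes with
    zero variance are flagged undefined and never significant; |r| = 1
    gives a degenerate (underflowed) p, flagged as such.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if matrix.unit == "FPKM":
        matrix = fpkm_to_tpm(matrix)
    groups: list[tuple[str, list[str]]]
    if pooled:
        groups = [("pooled", list(matrix.values.columns))]
    else:
        groups = [(v, matrix.samples_of(v)) for v in VARIETIES if matrix.samples_of(v)]
    results: list[CorrelationResult] = []
    for variety, samples in groups:
        n = len(samples)
        if n < 3:
            raise ValueError(f"need >= 3 samples per variety, {variety} has {n}")
        t_cov = _covariate(matrix.metadata, samples, time_encoding)
        data = matrix.values[samples].to_numpy(dtype=float)
        tc = t_cov - t_cov.mean()
        xc = data - data.mean(axis=1, keepdims=True)
        sx = np.sqrt((xc**2).sum(axis=1))
        st = np.sqrt((tc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc @ tc) / (sx * st)
        r = np.clip(r, -1.0, 1.0)
        df = n - 2
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = r * np.sqrt(df / (1.0 - r**2))
        degenerate = np.abs(r) >= 1.0 - 1e-12
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
        p = np.where(degenerate, np.nextafter(0.0, 1.0), p)
        undefined = sx == 0
        if benjamini_hochberg:
            from statsmodels.stats.multitest import multipletests

            usable = ~undefined
            adjusted = np.full_like(p, np.nan)
            if usable.any():
                adjusted[usable] = multipletests(p[usable], method="fdr_bh")[1]
            p = adjusted
        for gene, r_g, p_g, und, deg in zip(matrix.genes, r, p, undefined, degenerate):
            if und:
                results.append(
                    CorrelationResult(gene, variety, float("nan"), 1.0, False, "undefined", True)
                )
                continue
            significant = bool(p_g < alpha)
            results.append(
                CorrelationResult(
                    gene,
                    variety,
                    float(r_g),
                    float(min(max(p_g, np.nextafter(0.0, 1.0)), 1.0)),
                    significant,
                    "positive" if r_g > 0 else "negative",
                    degenerate=bool(deg),
                )
            )
    return results


def screen_candidates(
    matrix: ExpressionMatrix,
    candidates: list[str],
    time_encoding: str | Mapping[str, float] = "rank",
    alpha: float = 0.05,
    **kwargs,
) -> list[CorrelationResult]:
    """TPM-normalize over the whole matrix, then screen the candidate slice.

    Normalizing before slicing keeps per-sample totals anchored to the
    full transcriptome; renormalizing a small candidate panel on its own
    would distort every gene's trend through compositional closure.
    """
    if matrix.unit == "FPKM":
        matrix = fpkm_to_tpm(matrix)
    missing = [g for g in candidates if g not in matrix.values.index]
    if missing:
        raise ValueError(f"candidate genes absent from matrix: {missing}")
    subset = ExpressionMatrix(matrix.values.loc[candidates], matrix.metadata, unit="TPM")
    return pearson_screen(subset, time_encoding=time_encoding, alpha=alpha, **kwargs)


def read_expression(
    values_path: str | Path, metadata_path: str | Path, unit: str = "FPKM"
) -> ExpressionMatrix:
    """Read genes-in-rows delimited expression plus a sample-metadata sidecar."""
    values = pd.read_csv(values_path, sep="\t", index_col=0, comment="#")
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0, comment="#")
    return ExpressionMatrix(values, metadata, unit=unit)


def write_results(results: list[CorrelationResult], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "variety": r.variety,
                "r": r.r,
                "p": r.p,
                "significant": int(r.significant),
                "direction": r.direction,
                "degenerate": int(r.degenerate),
            }
            for r in results
        ]
    )
    frame.to_csv(path, sep="\t", index=False)
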