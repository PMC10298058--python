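"""Seeded generators for benchmark inputs: tRNA-like reference pools,
planted modifications, noisy peak lists, and salt-stress expression matrices.

Two reference styles are provided.  ``"uniform"`` draws fully random
sequences (uniform base composition, lengths uniform in range, at least
one G per 15 nt so RNase T1 digestion fragments them) and is what the
digestion/matching property tests run on.  ``"trna"`` (the default for
end-to-end benchmarks) emulates the structure of a real tRNA pool that
unique-fragment mapping relies on: a 76-residue cloverleaf-like scaffold
with conserved positions (G18/G19, the T-loop G53-U54-U55-C56, A58, the
3'-CCA), isoacceptor families sharing most of their sequence, a
variable-loop insertion of 0-14 residues (labelled e1, e2, ... as in
canonical tRNA numbering), and otherwise uniform-random bases.  Every
generator is a pure function of (parameters, seed), with independent
per-purpose random streams so that e.g. adding decoys does not perturb
the fragment noise draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import ModificationRegistry, default_registry
from .digestion import CleavageRule, default_rules, digest
from .mapper import Peak, TRnaReference
from .masscalc import mz_from_neutral, oligo_neutral_mass
from .modseq import ModifiedSequence, to_bracket_notation
from .saltcorr import ExpressionMatrix, TIMEPOINTS, VARIETIES

__all__ = [
    "PlantedSite",
    "GroundTruth",
    "PlantingProfile",
    "generate_reference_set",
    "plant_modifications",
    "simulate_peaklist",
    "simulate_expression",
]

_AMINO_ACIDS = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)

#: Conserved scaffold residues (canonical position -> base) for the tRNA style.
_CONSERVED = {
    8: "U", 14: "A", 18: "G", 19: "G", 21: "A", 32: "C", 33: "U",
    53: "G", 54: "U", 55: "U", 56: "C", 57: "G", 58: "A", 59: "U", 61: "C",
    74: "C", 75: "C", 76: "A",
}
_SCAFFOLD_LENGTH = 76
_VARIABLE_LOOP_AFTER = 45  # insertions sit between canonical 45 and 46


def _enforce_g_density(bases: list[str], protected: set[int], rng: np.random.Generator) -> None:
    """Guarantee >= 1 G per 15-residue stretch (indices are 0-based)."""
    n = len(bases)
    windows = [(w, w + 15) for w in range(0, n - 14, 15)]
    if n % 15 and n >= 15:
        windows.append((n - 15, n))
    for lo, hi in windows:
        window = range(lo, hi)
        if not any(bases[i] == "G" for i in window):
            candidates = [i for i in window if i not in protected]
            bases[int(rng.choice(candidates))] = "G"


def generate_reference_set(
    n: int,
    length_range: tuple[int, int] = (70, 90),
    seed: int = 0,
    style: str = "trna",
) -> list[TRnaReference]:
    """Generate ``n`` reference sequences, deterministic under ``seed``.

    ``style="uniform"``: independent uniform-composition sequences with
    lengths uniform in ``length_range``.  ``style="trna"``: scaffolded
    isoacceptor families with canonical position maps (see module
    docstring); lengths vary through the variable loop.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    if style == "uniform":
        refs = []
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            bases = list(rng.choice(list("ACGU"), size=length))
            _enforce_g_density(bases, set(), rng)
            aa = _AMINO_ACIDS[i % len(_AMINO_ACIDS)]
            anticodon = "".join(rng.choice(list("ACGU"), size=3))
            refs.append(TRnaReference(f"{aa}{i + 1}-{anticodon}", "".join(bases)))
        return refs
    if style != "trna":
        raise ValueError(f"unknown style {style!r}")
    if lo > _SCAFFOLD_LENGTH:
        raise ValueError("tRNA-style references need length_range[0] <= 76")
    max_insert = min(14, hi - _SCAFFOLD_LENGTH)
    if max_insert < 0:
        raise ValueError("tRNA-style references need length_range[1] >= 76")

    refs: list[TRnaReference] = []
    family_aas = list(rng.permutation(_AMINO_ACIDS))
    family = 0
    protected = set(i - 1 for i in _CONSERVED)
    while len(refs) < n:
        aa = family_aas[family % len(family_aas)]
        family += 1
        anticodon = "".join(rng.choice(list("ACGU"), size=3))
        master = [str(rng.choice(list("ACGU"))) for _ in range(_SCAFFOLD_LENGTH)]
        for pos, base in _CONSERVED.items():
            master[pos - 1] = base
        master[33:36] = list(anticodon)
        # position 37 is a purine and position 60 a pyrimidine in
        # essentially all tRNAs; both choices are family-level
        master[36] = str(rng.choice(["A", "G"]))
        master[59] = str(rng.choice(["C", "U"]))
        family_protected = protected | {33, 34, 35, 36, 59}
        _enforce_g_density(master, family_protected, rng)
        size = min(int(rng.integers(1, 4)), n - len(refs))
        for member in range(1, size + 1):
            bases = list(master)
            if member > 1:
                mutable = [i for i in range(_SCAFFOLD_LENGTH) if i not in family_protected]
                for i in rng.choice(mutable, size=int(rng.integers(1, 4)), replace=False):
                    bases[int(i)] = str(
                        rng.choice([b for b in "ACGU" if b != bases[int(i)]])
                    )
                _enforce_g_density(bases, family_protected, rng)
            insert = int(rng.integers(0, max_insert + 1))
            loop = [str(rng.choice(list("ACGU"))) for _ in range(insert)]
            full = bases[:_VARIABLE_LOOP_AFTER] + loop + bases[_VARIABLE_LOOP_AFTER:]
            position_map = {}
            for raw in range(1, len(full) + 1):
                if raw <= _VARIABLE_LOOP_AFTER:
                    position_map[raw] = str(raw)
                elif raw <= _VARIABLE_LOOP_AFTER + insert:
                    position_map[raw] = f"e{raw - _VARIABLE_LOOP_AFTER}"
                else:
                    position_map[raw] = str(raw - insert)
            refs.append(
                TRnaReference(
                    f"{aa}{member}-{anticodon}",
                    "".join(full),
                    position_map=tuple(sorted(position_map.items())),
                )
            )
    return refs


@dataclass(frozen=True)
class PlantedSite:
    """One planted modification: where it sits and what it is."""

    ref_id: str
    position: int  # raw 1-based coordinate
    label: str  # canonical position label
    species: str
    ce_labeled: bool = False


@dataclass(frozen=True)
class GroundTruth:
    references: tuple[TRnaReference, ...]
    sites: tuple[PlantedSite, ...]

    def __post_init__(self) -> None:
        by_id = {r.id: r for r in self.references}
        for site in self.sites:
            ref = by_id[site.ref_id]
            if not 1 <= site.position <= len(ref):
                raise ValueError(
                    f"site {site} outside reference of length {len(ref)}"
                )

    def sites_of(self, ref_id: str) -> list[PlantedSite]:
        return [s for s in self.sites if s.ref_id == ref_id]

    def modified_sequence(self, ref_id: str) -> ModifiedSequence:
        ref = {r.id: r for r in self.references}[ref_id]
        planted = {s.position: (s.species, s.ce_labeled) for s in self.sites_of(ref_id)}
        return ref.to_modseq(planted)

    def site_triples(self) -> set[tuple[str, str, str]]:
        """(ref id, position label, species) for recovery accounting."""
        return {(s.ref_id, s.label, s.species) for s in self.sites}


@dataclass(frozen=True)
class PlantingProfile:
    """Per-position planting probabilities and base-compatible species pools.

    The default concentrates on the anticodon loop (positions 34 and 37
    are the most frequently modified tRNA sites) with additional mass at
    the conserved T-loop sites 55/58 and the core positions 9/26/46.
    """

    site_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "34": 0.9, "37": 0.9, "32": 0.3, "38": 0.3,
            "55": 0.4, "58": 0.4, "9": 0.2, "26": 0.2, "46": 0.2,
        }
    )
    species_by_base: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "A": ("I", "m^1^A"),
            "U": ("Ψ",),
            "C": ("m^5^C",),
            "G": ("m^1^G", "m^2,2^G"),
        }
    )


_MAX_CO_POSITIONING = 3  # densest co-positioning arity per mapped fragment


def _family_key(ref_id: str) -> str:
    """Isoacceptor family key: strip the member index ('His2-UAC' -> 'His-UAC')."""
    head, _, anticodon = ref_id.partition("-")
    return head.rstrip("0123456789") + "-" + anticodon


def _cap_fragment_density(
    master: TRnaReference,
    chosen: list[tuple[str, str]],
    rule: CleavageRule,
    ce: bool,
    registry: ModificationRegistry,
    cap: int,
) -> list[tuple[str, str]]:
    """Drop late-drawn sites until no digestion fragment carries more than ``cap``.

    Blocking modifications fuse fragments, so the partition is recomputed
    after every drop (removing a blocker can only split fragments and
    lower the density).
    """
    chosen = list(chosen)
    label_to_raw = {master.label(i): i for i in range(1, len(master) + 1)}
    while True:
        planted = {}
        for label, species in chosen:
            raw = label_to_raw.get(label)
            if raw is not None and master.sequence[raw - 1] == registry[species].parent_base:
                planted[raw] = (species, ce and registry[species].ce_reactive)
        fragments = digest(master.to_modseq(planted), rule)
        worst = None
        for frag in fragments:
            inside = [
                (label, species)
                for label, species in chosen
                if label_to_raw.get(label) is not None
                and frag.start <= label_to_raw[label] <= frag.end
                and label_to_raw[label] in planted
            ]
            if len(inside) > cap:
                worst = inside
                break
        if worst is None:
            return chosen
        # drop the last-drawn site of the overfull fragment
        for label, species in reversed(chosen):
            if (label, species) in worst:
                chosen.remove((label, species))
                break


def plant_modifications(
    references: Sequence[TRnaReference],
    profile: PlantingProfile | None = None,
    seed: int = 0,
    ce: bool = True,
    registry: ModificationRegistry | None = None,
    rule: CleavageRule | None = None,
) -> GroundTruth:
    """Sample planted modification sites according to ``profile``.

    Sites are drawn once per isoacceptor family and applied to every
    member (modification patterns are conserved within a family: the
    same enzymes target the same positions), skipping members whose base
    at the site is incompatible with the drawn species.  The planted
    density is capped at three sites per digestion fragment of the
    family master (under ``rule``, default RNase T1), the densest
    co-positioning a mapped fragment is expected to carry.  Ψ/I sites
    are CE-labelled when ``ce`` is on; an unregistered or
    base-incompatible species in the profile is an error.
    """
    registry = registry if registry is not None else default_registry()
    profile = profile or PlantingProfile()
    if rule is None:
        _, rule = default_rules(registry)
    for base, names in profile.species_by_base.items():
        for name in names:
            entry = registry[name]  # raises for unregistered species
            if entry.parent_base != base:
                raise ValueError(
                    f"species {name!r} has parent base {entry.parent_base}, "
                    f"cannot be planted on {base}"
                )
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    families: dict[str, list[TRnaReference]] = {}
    for ref in references:
        families.setdefault(_family_key(ref.id), []).append(ref)
    sites: list[PlantedSite] = []
    for members in families.values():
        chosen: list[tuple[str, str]] = []  # (label, species) in draw order
        master = members[0]
        label_to_raw_master = {master.label(i): i for i in range(1, len(master) + 1)}
        for label in sorted(profile.site_probs, key=lambda l: rng.random()):
            prob = profile.site_probs[label]
            raw = label_to_raw_master.get(label)
            if raw is None or rng.random() >= prob:
                continue
            base = master.sequence[raw - 1]
            pool = profile.species_by_base.get(base, ())
            if not pool:
                continue
            chosen.append((label, str(rng.choice(list(pool)))))
        for ref in members:
            # member mutations can fuse fragments, so the density cap is
            # checked against each member's own digest
            member_chosen = _cap_fragment_density(
                ref, chosen, rule, ce, registry, _MAX_CO_POSITIONING
            )
            label_to_raw = {ref.label(i): i for i in range(1, len(ref) + 1)}
            for label, species in member_chosen:
                raw = label_to_raw.get(label)
                if raw is None:
                    continue
                entry = registry[species]
                if ref.sequence[raw - 1] != entry.parent_base:
                    continue  # member mutated at this site
                sites.append(
                    PlantedSite(ref.id, raw, label, entry.short_name, ce and entry.ce_reactive)
                )
    return GroundTruth(tuple(references), tuple(sites))


def simulate_peaklist(
    truth: GroundTruth,
    rule: CleavageRule,
    ce: bool = True,
    ppm_sigma: float = 2.0,
    dropout: float = 0.1,
    decoy_rate: float = 0.2,
    seed: int = 0,
    charges: Sequence[int] = (1, 2, 3),
    ms2_fraction: float = 1.0,
    replicates: int = 1,
    registry: ModificationRegistry | None = None,
) -> tuple[list[Peak], pd.DataFrame]:
    """Digest the modified pool and emit a noisy peak list plus a truth table.

    Per replicate injection, each digestion fragment is observed at one
    random charge with Gaussian ppm mass error, or dropped at the dropout
    rate; observed fragments emit idealized c/y MS2 ladders (z = 1) for a
    configurable fraction of precursors.  Uniform-random decoy peaks are
    added over the observed m/z range at ``decoy_rate`` (relative to the
    theoretical fragment count).  The truth table labels every peak, so
    mapper precision/recall against the planted truth is exactly
    computable.
    """
    if not 0 <= dropout < 1 or not 0 <= decoy_rate < 1:
        raise ValueError("rates must lie in [0, 1)")
    if ppm_sigma < 0:
        raise ValueError("ppm_sigma must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    registry = registry if registry is not None else default_registry()
    streams = np.random.SeedSequence(seed).spawn(4)
    rng_noise = np.random.default_rng(streams[0])
    rng_dropout = np.random.default_rng(streams[1])
    rng_charge = np.random.default_rng(streams[2])
    rng_decoy = np.random.default_rng(streams[3])

    from .masscalc import cid_products  # local import to avoid cycle at module load

    peaks: list[Peak] = []
    records: list[dict] = []
    fragments = []
    for ref in truth.references:
        seq = truth.modified_sequence(ref.id)
        if not ce:
            seq = ModifiedSequence(
                tuple(r.__class__(r.base, r.modification, False) for r in seq.residues),
                seq.five_prime,
                seq.three_prime,
            )
        fragments.extend(digest(seq, rule, parent_id=ref.id))
    for replicate in range(1, replicates + 1):
        for frag in fragments:
            neutral = oligo_neutral_mass(frag.sequence, registry)
            if rng_dropout.random() < dropout:
                continue
            z = int(rng_charge.choice(list(charges)))
            theo_mz = mz_from_neutral(neutral, z, "negative")
            obs_mz = theo_mz * (1.0 + rng_noise.normal(0.0, ppm_sigma) * 1e-6)
            peaks.append(Peak(obs_mz, z, intensity=1.0, level="MS1"))
            records.append(
                {
                    "kind": "fragment",
                    "ref_id": frag.parent_id,
                    "start": frag.start,
                    "end": frag.end,
                    "fragment": to_bracket_notation(frag.sequence),
                    "z": z,
                    "theoretical_mz": theo_mz,
                    "observed_mz": obs_mz,
                    "replicate": replicate,
                }
            )
            if len(frag.sequence) >= 2 and rng_dropout.random() < ms2_fraction:
                for ion in cid_products(frag.sequence, (1,), registry, series=("c", "y")):
                    ion_mz = ion.mz * (1.0 + rng_noise.normal(0.0, ppm_sigma) * 1e-6)
                    peaks.append(
                        Peak(ion_mz, 1, level="MS2", precursor_mz=obs_mz)
                    )
    if peaks:
        ms1_mzs = [p.mz for p in peaks if p.level == "MS1"]
        lo_mz, hi_mz = min(ms1_mzs), max(ms1_mzs)
        n_decoys = int(round(decoy_rate * len(fragments) * replicates))
        for _ in range(n_decoys):
            mz = float(rng_decoy.uniform(lo_mz, hi_mz))
            z = int(rng_decoy.choice(list(charges)))
            peaks.append(Peak(mz, z, intensity=1.0, level="MS1"))
            records.append(
                {
                    "kind": "decoy",
                    "ref_id": "",
                    "start": 0,
                    "end": 0,
                    "fragment": "",
                    "z": z,
                    "theoretical_mz": np.nan,
                    "observed_mz": mz,
                    "replicate": 0,
                }
            )
    table = pd.DataFrame(
        records,
        columns=[
            "kind", "ref_id", "start", "end", "fragment",
            "z", "theoretical_mz", "observed_mz", "replicate",
        ],
    )
    return peaks, table


def simulate_expression(
    n_genes: int = 66,
    planted_positive: str | None = "g001",
    noise_sd: float = 0.05,
    seed: int = 0,
    n_background: int = 200,
) -> tuple[ExpressionMatrix, dict]:
    """An FPKM matrix over 2 varieties x 4 timepoints with planted trends.

    The planted candidate gene rises linearly over the time course in
    both varieties; every other candidate declines (emulating the broad
    downregulation of modifying enzymes under salinity stress with a
    single positively responding outlier).  ``n_background`` stable,
    highly expressed genes are included so that per-sample totals — and
    therefore TPM normalization — are dominated by the unchanging bulk
    of the transcriptome rather than by the candidate genes themselves
    (screening candidates in isolation would otherwise distort their
    trends through compositional closure).  ``noise_sd`` is the standard
    deviation of multiplicative log-normal noise.  With
    ``planted_positive=None`` a trend-free null matrix is generated
    (constant mean, additive Gaussian noise, no background) for
    calibration of the significance cutoff.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    genes = [f"g{i + 1:03d}" for i in range(n_genes)]
    samples = [f"{v}_{t}" for v in VARIETIES for t in TIMEPOINTS]
    metadata = pd.DataFrame(
        {
            "variety": [s.split("_")[0] for s in samples],
            "timepoint": [s.split("_", 1)[1] for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    streams = np.random.SeedSequence(seed).spawn(2)
    rng_base = np.random.default_rng(streams[0])
    rng_noise = np.random.default_rng(streams[1])
    if planted_positive is None:
        values = 100.0 + rng_noise.normal(0.0, 10.0, size=(n_genes, len(samples)))
        values = np.clip(values, 0.0, None)
        matrix = ExpressionMatrix(
            pd.DataFrame(values, index=genes, columns=samples), metadata, unit="FPKM"
        )
        return matrix, {"planted": None, "candidates": genes, "direction": {}}
    if planted_positive not in genes:
        raise ValueError(f"planted gene {planted_positive!r} not among generated ids")
    background = [f"bg{i + 1:03d}" for i in range(n_background)]
    base = rng_base.lognormal(mean=3.0, sigma=1.0, size=n_genes)
    bg_base = rng_base.lognormal(mean=5.0, sigma=0.5, size=n_background)
    t_index = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    all_genes = genes + background
    values = np.empty((len(all_genes), len(samples)))
    for g, gene in enumerate(all_genes):
        if g < n_genes:
            slope = 1.0 if gene == planted_positive else -0.6
            level = base[g]
        else:
            slope = 0.0
            level = bg_base[g - n_genes]
        for s, sample in enumerate(samples):
            t = t_index[metadata.loc[sample, "timepoint"]]
            trend = level * (1.0 + slope * t / 3.0)
            noise = np.exp(rng_noise.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
            values[g, s] = trend * noise
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=all_genes, columns=samples), metadata, unit="FPKM"
    )
    direction = {g: ("positive" if g == planted_positive else "negative") for g in genes}
    return matrix, {"planted": planted_positive, "candidates": genes, "direction": direction}
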