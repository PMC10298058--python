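# Methods

## Mass conventions

All masses are monoisotopic, computed from elemental formulas with the
most-abundant-isotope masses of the NIST table shipped with pyteomics
(H 1.00782503207, C 12, N 14.0030740048, O 15.9949146196, P 30.97376163,
S 31.97207100). The registry stores the full neutral formula of each free
nucleoside; every derived quantity (residue masses, methylation and
cyanoethylation deltas) comes from formula arithmetic, so a
user-registered species is automatically mass-enabled everywhere.

The only charge carrier is the proton, 1.0072765 Da: negative-mode
*m/z* = (M − z·1.0072765)/z, positive-mode *m/z* = (M + z·1.0072765)/z.
No adduct cations are modelled. An oligonucleotide's neutral mass is

    M = Σ residue(nucleoside-3′-monophosphate) − (n−1)·18.010565
        + 79.966331 if 5′-monophosphate
        − 79.966331 if 3′-hydroxyl
        − 18.010565 if 2′,3′-cyclic phosphate
        + 53.026549 per cyanoethylated residue

Digestion products default to the 3′-linear-phosphate convention; the
cyclic form (−18.010565 Da) is retained as an option. ppm error is
computed on *m/z*, 1e6·|obs − theo|/theo, matching instrument-software
convention; the default matching tolerance is 10 ppm throughout.

The registry's theoretical [M+H]+ values sit systematically ~1–2 ppm
below the values printed in the survey this pipeline re-implements
(presumably instrument-calibrated readouts); the package reports
theoretical values and matches at 10 ppm rather than reproducing that
offset. The shipped fragment fixture flags the handful of published
fragment rows whose printed *m/z* is irreconcilable with their printed
composition (>10 ppm; the patterns are consistent with +1 Da isotopolog
readouts, charge-state misprints, and copy errors between adjacent rows);
tests pin those rows as discrepant instead of matching them.

## Sequence notation

Modified oligonucleotides are written in bracket notation: an optional
leading `p` (5′-monophosphate), one token per residue (`A`/`C`/`G`/`U` or
`[name]`, with `-CE` marking a cyanoethylated residue), and a terminator
`p`, `>p`, or `OH` (default hydroxyl; the canonical rendering writes `OH`
explicitly). Inosine is modelled as modification `I` on parent base A;
the bare letter `I` is accepted as input sugar. Caret markup is
normalized (`m^1^G` ≡ `m1G`) and `Y` is accepted as an ASCII alias for Ψ
on input only. Coordinates are 1-based and inclusive.

Cyanoethylation models the acrylonitrile reaction as complete (the
protocol drives it to completion at 70 °C before digestion): every Ψ/I
residue is labelled, the operation is idempotent, and only Ψ and I are
reactive by default — whether U acquires partial label in practice is
not modelled.

## Digestion rules

RNase T1 cleaves 3′ of guanosine and, by default, of unlabeled inosine;
it is blocked by 2′-O-methylation (Gm, Im), by base methylation of G
(m^1^G, m^2^G, m^2,2^G, m^7^G, and the wyosine pathway species), and by
the cyanoethyl adduct on inosine. RNase A cleaves 3′ of pyrimidines —
C, U, Ψ, and base-modified pyrimidines — and is blocked by
2′-O-methylation (Um, Cm, cmnm^5^Um) and, optionally, dihydrouridine.
Blocked sets are read from registry flags and are user-configurable;
published fragment tables are not fully consistent about whether T1 can
cleave after m^1^G (one fragment ends in `[m^1^G]p`), so no default can
satisfy every printed row and the default keeps methylated G uncleavable.

Digestion is complete (0 missed cleavages) by default; with k missed
cleavages all unions of ≤ k+1 adjacent fragments are additionally
produced. Products carry 5′-OH and the rule's 3′ terminus; the first and
last fragments inherit the parent termini (mature tRNA: 5′-monophosphate,
3′-CCA-OH). Two invariants hold by construction and are property-tested:
fragments tile the parent exactly, and the summed fragment masses equal
the parent mass plus one water per internal cut.

## Fragment index and hypothesis enumeration

The mapper is theoretical-first. For each reference, the unmodified
sequence is digested into unit fragments; candidate intervals are unions
of up to k+1 adjacent units (k = 3 by default, the densest co-positioning
observed in mapped fragments). Modification assignments of ≤ k species
drawn from per-base allowed sets are enumerated under a
cleavage-consistency constraint: no internal residue of a hypothesized
fragment may be cleavable under the rule (an internal G must carry a
blocking modification; an internal unlabeled I is rejected), and the
3′-terminal residue must remain cleavable unless the fragment ends at the
parent 3′ end. Missed cleavages therefore arise exactly where blocking
modifications are hypothesized. With the CE flag on, hypothesized
CE-reactive species carry the adduct. Entries are indexed by neutral
mass and queried by ppm window; charges 1–4 are supported at match time
by converting the observed peak to neutral mass.

The default allowed sets contain every registered modification grouped by
parent base; because enumeration is combinatorial in fragment length and
set size, practical runs restrict the sets to the species under study
(the CLI exposes `--mods`).

## Matching, localization, landscape

MS1 peaks are matched per peak (so decoys never perturb other peaks'
results); candidates are ordered by |ppm|, then fewer modifications
(parsimony), then placement. MS2 localization scores each candidate by
the number of theoretical c/d/y/w ions (z = 1, 2) matched within
tolerance among the ladder peaks linked to the precursor, and retains the
maximal scorers. A match has MS2 support when (i) all retained candidates
share one identical modified sequence — isoacceptors sharing a fragment
are one placement pattern — (ii) the winner matches at least
max(2, (n−1)/2) ions for an n-mer (a single coincidental ion across a
10 ppm window must not count as confirmation), and (iii) at least one
matched ion discriminates the winner from sequence-distinct alternatives,
when any existed.

The landscape aggregates matches whose retained candidates all assert the
same set of (position label, species) pairs and that have MS2 support
(configurable). Since the index is hypothesis-complete over the allowed
sets, the candidate set is the operative ambiguity measure: one candidate
is a unique placement, several agreeing candidates are the
shared-consistent isoacceptor case, and disagreeing candidates are
surfaced in an ambiguity report rather than decided. The string-based
`classify_uniqueness` operation (count occurrences of the fragment's
unmodified residue string over all references; multiple occurrences are
consistent only if every positioned modification maps to one identical
label everywhere) is provided and oracle-tested, but landscape inclusion
deliberately keys on the candidate set: a raw substring occurrence that
cannot form a viable digestion product at the observed mass should not
veto an otherwise consistent placement.

Position labels default to raw 1-based coordinates; references may carry
a position map to canonical tRNA numbering (insertions labelled e1, e2,
…), which the synthetic generator uses for its variable loop. No
cloverleaf aligner is included.

## Nucleoside census

Positive-mode z = +1 peaks are matched to the registry's [M+H]+ values at
10 ppm and reported against their whole exact-mass isomer group —
2′-O-methyl vs base-methyl isomers (Um/m^5^U, Cm/m^5^C/m^3^C,
m^1^G/m^2^G/m^7^G/Gm, m^1^A/m^6^A/Am) are never reported singly from MS1
alone, since distinguishing them requires retention-time standards, which
the package carries only as an opaque annotation. Ar(p), a negatively
charged nucleotide species, is flagged as unobservable in positive ESI
and excluded from census matching. Canonical nucleosides match but are
flagged unmodified.

## Salt-stress correlation screen

TPM conversion is per-sample renormalization to one million. The screen
computes, per gene and per variety (BD and XS analyzed separately; pooled
mode behind a flag), the Pearson r of TPM against a numeric time
covariate, with the two-sided p-value of t = r·√((n−2)/(1−r²)) on n−2
degrees of freedom and a raw p < α cutoff (α = 0.05; Benjamini–Hochberg
available but off by default, matching the original raw-cutoff design).
The timepoint covariate defaults to rank encoding (0 h→0, 4 h→1, 6 d→2,
10 d→3) with an hour encoding (0/4/144/240) behind a flag — the ordered
conditions, not the literal hours, are what the screen is designed
around. Zero-variance genes are flagged undefined and never significant;
|r| ≈ 1 (within 1e-12) yields a degenerate underflowed p, flagged as
such, with p clamped into (0, 1].

A compositional caveat drives one design choice: renormalizing a small
candidate panel by itself forces the trends to cancel (if every candidate
declines at the same rate, their panel-TPM is exactly flat). TPM must be
computed over the full matrix and the candidate rows screened afterwards;
`screen_candidates` encodes that order, and the synthetic expression
generator includes a stable highly-expressed background compartment (200
genes by default) so that per-sample totals behave like a real
transcriptome in which the candidate enzymes are a negligible fraction.

## Synthetic data

All generators are pure functions of (parameters, seed) with independent
per-purpose random streams (noise, dropout, charge, decoys), so changing
the decoy rate does not perturb the fragment noise draws.

Two reference styles exist. `uniform` draws fully random sequences
(uniform composition, lengths uniform in 70–90 nt, ≥1 G per 15-nt stretch
so T1 digestion fragments them); it is the right substrate for the
digestion and occurrence-oracle property tests precisely because it has
no structure. `trna` (the benchmark default) emulates what unique-fragment
mapping actually relies on in a real tRNA pool: a 76-residue scaffold
with conserved positions (U8, A14, G18/G19, A21, C32/U33, the T-loop
G53-U54-U55-C56-G57-A58-U59, a pyrimidine at 60, C61, CCA 74–76, a purine
at 37), isoacceptor families sharing most of their sequence with a few
point differences, a variable-loop insertion of 0–14 residues between
positions 45 and 46 carried in the position map as e-labels, and
uniform-random bases elsewhere. Under fully uniform pools, essentially
every fragment of ≤4 nt recurs somewhere else and honest mapping
collapses to ambiguity; the structured pool represents the conditions the
method was designed for.

Modification planting draws sites per isoacceptor family (the same
enzymes modify the same positions across a family; independent
per-member draws would create same-mass same-family isomer pairs that no
instrument could separate), concentrated on the anticodon loop (34 and 37
are the most frequently modified tRNA positions; the default profile also
covers 9, 26, 32, 38, 46, 55, 58), with parent-base compatibility
enforced and Ψ/I sites CE-labelled when the run is derivatized. Planted
density is capped at three sites per digestion fragment of each member
(recomputed as blockers fuse fragments): denser fragments fall outside
the k = 3 hypothesis space the mapper enumerates, so the benchmark
measures recovery of the identifiable landscape.

Peak-list simulation digests the modified pool and emits, per replicate
injection, each fragment at one random charge ∈ {1, 2, 3} with Gaussian
ppm error (σ = 2 ppm default), dropping fragments at the dropout rate
(0.1), adding uniform-random decoy peaks over the observed *m/z* range at
the decoy rate (0.2 of the theoretical fragment count), and attaching
idealized c/y ladders (z = 1, same ppm noise) to a configurable fraction
of observed precursors (1.0 by default). Truth tables label every peak,
so mapper precision and recall are exactly computable.

What the generators do **not** emulate — and what passing benchmarks
therefore do not demonstrate about real data: chromatography and
retention time, isotope envelopes and intensity structure, chimeric MS2
spectra from co-eluting isobars, partial digestion and partial
derivatization, sequence polymorphism against the reference set, and
modification stoichiometry.

## Recovery benchmark

The end-to-end benchmark mirrors the standard two-digest study design:
the cyanoethylated pool cut with RNase T1 and the natural pool cut with
RNase A, each observed in duplicate injections with independent per-peak
detection, matched at 10 ppm with the planting profile's species as the
hypothesis sets (mass-silent hypotheses, i.e. underivatized Ψ, are
excluded from the natural run), localized with MS2, and combined. Scoring
is strict: a planted (reference, position, species) triple counts as
recovered only if a landscape-contributing match places that species at
that label in that reference, and a false position is any landscape
(label, species) pair never planted anywhere in the pool. The shipped
configuration runs pools of 5 references over 20 seeds; measured across
five independent 20-seed blocks, aggregate recall is 0.91–0.95 with zero
false positions. The residual misses are almost entirely short fragments
(2–4 nt) whose string recurs at inconsistent positions — a real
limitation of RNase fingerprint mapping, reported honestly as ambiguity.

## Numerical and degenerate-input choices

- Proton 1.0072765 Da; water 18.010565; HPO3 79.966331; cyanoethyl
  53.026549 (all derived from the element table, quoted here rounded).
- Formula subtraction below zero, empty sequences, non-positive masses,
  unknown species/elements, z = 0, and all-zero expression samples raise
  errors naming the offending item.
- Candidate ordering ties (equal ppm, equal modification count) break
  lexicographically on placement and are surfaced, never silently
  dropped; an uncleavable parent digests to itself.
- Hypothesis enumeration skips intervals whose forced blocking sites
  already exceed k.
- The fragment fixture's consistency flags were frozen from the 10 ppm
  criterion applied to the printed values.

## Known limitations

- Landscape quality is bounded by fragment uniqueness; heavily shared
  short fragments are unmappable by construction and land in the
  ambiguity report.
- No FDR estimation: decoys in the simulator exist to stress matching,
  not to calibrate error rates.
- a−B (base-loss) CID ions are not modelled; localization uses c/d/y/w
  only.
- Isomer groups from MS1 are irreducible without retention-time
  standards; the census never resolves them.
- The mapper assumes the reference sequences are exact; polymorphisms
  masquerade as mass shifts.
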