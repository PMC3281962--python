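# Methods

## Problem setting

Covalent staining of proteins with the reactive anthraquinone dye
Uniblue A attaches the dye to lysine ε-amino groups through vinyl-sulfone
addition. For downstream protein identification by LC-MS/MS this has four
consequences that any search pipeline must model:

1. every derivatized residue gains a fixed mass: +484.039891 Da
   monoisotopic, +484.5016 Da average;
2. trypsin no longer recognizes a derivatized lysine, so cleavage at that
   residue is abolished ("cleavage blocking");
3. the tag's sulfonate group removes one protonation site, lowering the
   electrospray charge state by one per tag;
4. fragment spectra change asymmetrically: all N-terminal (a/b) ions at or
   beyond the tagged residue shift by the full tag mass, C-terminal (y)
   ions are untouched, and the N-terminal series gains intensity
   (chemically assisted fragmentation).

This package implements the full desk-scale pipeline around that model:
modification-aware digestion, fragment prediction, spectrum annotation,
site localization, target-decoy search with q-values, and a generative
spectrum simulator so that the entire pipeline is testable without any
external data.

## Mass arithmetic

Residue, water, CO, NH3 and proton masses come from the standard tables in
`pyteomics.mass`. A modform (peptide + site→modification map) has neutral
mass `Σ residues + H2O + Σ deltas`; additivity is exact by construction and
is property-tested against an independently typed residue table. The
canonical tag delta is 484.039891 Da — the machine-readable value used in
the modification registry — and comparisons against the 4-decimal figure
484.0399 use rounding. Three nearly identical published values of this
constant exist (484.0399, 484.039891, 484.039893); a tolerance of 1e-3 Da
covers all of them. Carbamidomethyl (+57.021464, fixed on C) and
deamidation (+0.984016, variable on N/Q) use standard community values.

No elemental composition is stored for the dye adduct (only mass deltas are
published); isotope envelopes are therefore out of scope.

## Digestion and cleavage blocking

Trypsin cleaves after K/R, not before P (OMSSA-style default). Chemically
blocked sites are removed from the cleavage pattern before missed-cleavage
expansion, and **blocked sites do not count toward the missed-cleavage
budget**: the miss is chemical, not enzymatic. At the database-index level
this is enforced per modform: candidate peptides are generated over the
unblocked pattern with up to `max_missed + max_variable` internal sites,
and a modform is kept only if the number of internal sites *not* occupied
by a cleavage-blocking modification is within the missed-cleavage limit. A
peptide spanning an internal unmodified lysine therefore costs a miss,
while the same span with the lysine tagged does not.

Variable-modification enumeration emits every subset of eligible sites of
size ≤ `max_variable` (default 3 per peptide), with fixed modifications
applied everywhere eligible and at most one modification per position.
N-terminal methionine clipping and semi-tryptic peptides are not modeled.

## Fragment model, localization, paired comparison

Ladders use the standard CID definitions (b = N-terminal residue sum +
proton; y = C-terminal residue sum + water + proton; a = b − CO; optional
NH3/H2O losses; multiply charged ions via `(M + zH)/z`). The default
series is {b, y} with fragment charge capped at precursor charge − 1
(floor 1), appropriate for ion-trap CID. Peak matching is nearest-peak
with an absolute Da tolerance (default 0.8 Da, the trap default); ppm
matching is deliberately not offered since the model targets trap data.

The precursor charge heuristic is `max(1, 1 + #R + #unmodified K)`:
arginines and free lysines protonate, tagged lysines do not. Histidine is
deliberately ignored — the simplest model consistent with the charge-
reduction mechanism, and it reproduces the 3+/2+ native/tagged pair of the
worked example peptide KVPQVSTPTLVEVSR.

Site localization scores each candidate single-site modform by the number
of matched *site-determining* ions — fragments whose m/z differs between
candidate placements — and returns the argmax, with ties resolved to the
lowest position and flagged ambiguous. This is the simplest defensible
scheme; no probability is attached to the localization. Note that a
restricted scan window can remove all site-determining ions between two
adjacent candidate sites, in which case the ambiguity flag is the correct
output; the round-trip recovery tests therefore use an unrestricted
window, while scan-window truncation is exercised separately.

The paired-spectrum comparison reports, per ion series, matched-ion counts
and per-index theoretical m/z differences between a tagged and a native
form of the same sequence (mirror-plot-ready), flagging series shifted by
more than the fragment tolerance.

## Database and search

Decoys are full-sequence reversals with the `decoy_` id prefix,
concatenated after the targets — exactly the classic strategy; full
reversal (rather than cleavage-site-preserving pseudo-reversal) is used
deliberately, accepting that tryptic-terminus composition differs between
target and decoy. I and L are distinct residues of equal mass. Records
containing non-standard codes (B, Z, X, U) are retained but their affected
peptides are excluded from the index.

Scoring: with `n` peaks over an observed m/z span `R`, the chance that one
of `N` theoretical ions lands within tolerance `t` of some peak is ≈
`2tn/R`, so the random match count is approximately Poisson with
`λ = 2tnN/R` and the PSM p-value is the upper tail `P(X ≥ k)`. The
E-value multiplies by the number of candidates in the precursor window
(±2.0 Da on the neutral mass, charge-aware; uncharged spectra try 2+ and
3+). Ties break on higher match count, then **fewer modification sites**,
then lexicographic modform. The parsimony step matters in practice: at
0.8 Da tolerance a spurious deamidation (+0.984 Da) on a multiply charged
precursor shifts most fragment m/z by less than the tolerance and ties the
unmodified form exactly; preferring the simpler explanation resolves the
tie correctly.

The Poisson score and direct target-decoy q-values
(`q = running min of #decoy / max(1, #target)` down the E-value ranking)
are deliberate native replacements for an external search engine and
mixture-model rescoring; the package's substance is the modification
handling, which is scorer-agnostic. Calibration is conservative rather
than exactly uniform: the match count is discrete, and ladder ions falling
outside the recorded peak range can never match. Both effects inflate
p-values (the safe direction for FDR control); the Monte-Carlo calibration
test asserts two-sided agreement in the decision-relevant tail (k ≥ 4) and
one-sided conservatism elsewhere, and the decoy-null test asserts
super-uniformity.

## Simulator

The simulator is the package's study-condition generator, not a test
helper: 50 random proteins of 60–120 residues (uniform residue usage),
per-lysine labeling probability 0.3 (a realistic partial-labeling rate:
roughly the fraction observed for a lysine-rich serum albumin), trypsin
with ≤2 missed cleavages and blocking at labeled lysines, minimum peptide
length 5, scan range 200–1400 m/z, m/z jitter sd 0.1 Da (ion-trap-like
relative to the 0.8 Da tolerance), 10 uniform noise peaks at lower-quartile
signal intensity, and 3× a/b-intensity enhancement for tagged peptides —
a qualitative encoding of chemically assisted fragmentation, explicitly
not a fitted value. Precursor charges follow the charge heuristic;
carbamidomethylation is applied to every cysteine (the wet protocol
alkylates before digestion). One spectrum per sampled modform; no
chimeras, retention times, or isotope envelopes. Everything derives from a
single integer seed, and file outputs are byte-identical per seed.

What the simulator does *not* emulate — correlated chemical noise, real
intensity distributions, co-eluting precursors, deamidation actually
occurring in samples, instrument-specific low-mass cutoff physics — bounds
what passing benchmarks show: they validate the pipeline's logic and
calibration under the stated generative model, not instrument performance.

## Benchmarks and problem sizes

The standard identification benchmark is 50 proteins / 200 spectra / one
CPU (seconds to a few minutes per run); the FDR-control check pools 20
seeded replicates at 20 proteins / 100 spectra; score calibration uses
10,000 Monte-Carlo spectra. The noise-free self-identification check runs
the search with `max_variable = 6` so that the search space contains every
generated modform (the generator can label four or more lysines on one
long peptide; a search capped at 3 variable sites cannot represent such a
peptide, which is a representability limit, not a scoring failure). The
noisy benchmark keeps the default cap of 3.

Parameter recovery is partial by design and stated as such: a labeled
lysine can never appear as a tryptic C-terminus, so the per-lysine label
rate estimated from confident identifications is biased low at high
labeling rates; the recovery test asserts monotonicity and ±0.15 accuracy
at p_label = 0.5 rather than unbiasedness.

## Numerical and interface choices

* Modification positions are 1-based everywhere user-visible; protein
  spans are 0-based half-open internally.
* The OMSSA `usermods.xml` dialect carries only id, name, the two mass
  deltas and target residues. Reading resolves entries matching the
  built-in registry (by OMSSA id, name, mass, residues) back to the
  registry entry, recovering the cleavage-blocking flag and PSI-MOD
  accession the dialect cannot express; unknown entries default to
  variable mode without blocking.
* p-values are floored at the smallest positive float so E-value ordering
  never collapses at underflow; E-values are capped at 1e6 but no
  candidate is ever discarded before validation.
* Degenerate inputs: empty proteins digest to nothing; zero-length
  fragments from adjacent cleavage sites are dropped; spectra without
  PEPMASS are skipped with a warning; an empty spectrum cannot be scored;
  a modform whose entire ladder falls outside the scan window yields an
  empty spectrum with a warning.

## Known limitations

No protein-level inference or grouping; no mzML/mzXML ingest (MGF only);
no intensity-aware scoring; no isotope envelopes; localization confidence
is a count, not a calibrated probability; the decoy construction inherits
the terminus-composition mismatch of full reversal.
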