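# Methods

This note documents the models, defaults and numerical choices behind
`cysredox`, and what the synthetic world does and does not establish.

## Redox dynamics classification

Replicate-level % reversible oxidation is averaged per (site, condition);
the s.e.m. is sd(ddof=1)/√n. Δ oxidation is the range of condition means,
max − min, which is equivalent to the maximum over all pairwise
condition-mean differences (the test suite asserts this equivalence against
an exhaustive pairwise oracle). The dynamic call uses a **strict**
inequality at the threshold (default 10 percentage points): Δ = 10.0 is
stable. Design choices where the convention was genuinely open:

* Classification operates on condition means, not replicate-level pairs.
* Sites observed in fewer than two conditions are *unclassifiable*, not
  stable — absence of contrast is not evidence of stability. The number of
  observed conditions is carried in the output for filtering.
* Missing conditions are dropped, never imputed.
* Rank ties in top-k family tables break lexicographically by site id, so
  reports are deterministic.

## Ortholog residue mapping

Pairwise global alignment (Gotoh affine-gap dynamic programming) replaces a
multiple-sequence alignment of two sequences; for a pair, the optimal
pairwise alignment is the principled equivalent and is testable against a
brute-force enumeration oracle. Defaults: BLOSUM62, gap open 10, gap
extend 1 (a gap of length L costs 10 + 1·(L−1), matching Bio.Align's
convention, against which scores are cross-checked). Co-optimal alignments
are resolved by a fixed traceback preference — residue–residue column, then
gap in the second sequence, then gap in the first — making output
deterministic; this tie-break is a stated choice, not an inference about
how any upstream analysis resolved ambiguity. Residue numbering is 1-based
from the initiator methionine (UniProt convention). Conservation requires
cysteine on **both** sides of an aligned column.

## Functional annotation

Domain intervals are 1-based and inclusive at both ends (Pfam residue
coordinates). All covering domains are reported; no primary domain is
chosen. Family labels are the union over class tables
(kinase/phosphatase/transcription factor/metabolic enzyme), with `other`
when none match; structure identifiers are opaque strings attached by a
pure join. Compendium summary fractions are exact integer ratios; rounding
happens only at report formatting. Duplicate join keys raise — records are
never silently de-duplicated — and the record count always equals the
conserved-cysteine count entering annotation.

## Engagement scoring

R = S/N(DMSO)/S/N(treated) uses mean-of-arms S/N per site per dose; the
median of all pairwise replicate R values is reported alongside (which of
the two an upstream analysis used is not specified anywhere authoritative;
mean-of-arms is the default here). % modification = 100·(1 − 1/R) is the
standard competition-chemoproteomics conversion, making R = 2 ⇔ 50%
occupancy; negative values (treated above DMSO, i.e. noise) clamp to 0
because occupancy is physically in [0, 1]. When one cysteine is quantified
on several peptides, S/N is summed per (site, channel) before ratioing,
preserving total reporter signal. The reproducibility rule — a hit needs
≥ `min_pair_fraction` (default 0.75) of pairwise R values above
`r_threshold` (default 2) — is an explicit operationalization of
"reproducibly engaged above 50%"; both knobs are parameters. Under the
null (occupancy 0, 20% CV multiplicative noise) the pairwise log-ratio has
σ ≈ 0.28, so P(R > 2) ≈ 0.7% per pair and the ≥75%-of-pairs rule yields a
per-site false-positive rate far below 1% (asserted on 10,000 null sites).

## Biochemical assays

**4PL fitting.** Parameterized on log10(dose) for conditioning; bounded
`scipy.optimize.least_squares` with a fixed initialization (bottom/top from
response extrema, EC50 from the dose nearest the half-range response,
hill = 1) makes fits deterministic. Hill is bounded to [0.05, 10], log-EC50
to the data range ± 2 decades. Non-convergence raises with diagnostics;
there are no silent defaults. The bottom may be pinned (e.g. at 1.0 on a
fold-change scale); both constrained and free fits are supported. Fits are
validated two ways: exact recovery (1e−6 relative) on noise-free curves for
hill ∈ [0.5, 3] and EC50 across three decades, and objective agreement
within 1% against a dense grid-search oracle that is linear-least-squares
in (bottom, top) at each (EC50, hill) grid point.

**DiFMU rates.** The standard curve is a linear fit (rejected below
R² = 0.98 or non-increasing); the kinetic rate is the least-squares slope
of fluorescence vs time over the first 10 minutes by default (the window is
a parameter — no authoritative window is specified), divided by the curve
slope; 1 pmol DiFMU ≡ 1 pmol phosphate.

**Intact-MS stoichiometry** is fraction-of-total: 100·Σ(≥1 adduct)/Σ(all).
A literal ratio to the *unlabeled* species alone would diverge for complete
labeling, which is inconsistent with a 100%-stoichiometry reading; the
fraction-of-total interpretation is recorded as a deliberate one.
Multi-adduct species count as engaged and are also reported separately.

**FP binding.** mP is normalized to the stated reference condition, fitted
with the 4PL (saturation rises with protein; competition falls with
competitor, yielding IC50). "No change on pre-incubation" is
operationalized as a residual-bootstrap 95% interval of the IC50 ratio
covering 1 — no numeric criterion exists upstream, so this is the package's
own.

**ELISA** standards are fitted with a rising 4PL and unknowns recovered by
inverse evaluation, intrapolation only: signals outside the standards'
range are flagged, never extrapolated. **ΔΔCt** is
2^−(ΔCt_sample − ΔCt_calibrator) with ΔCt = Ct_gene − Ct_reference; it is
invariant to global Ct shifts and row order. **Phagocytosis** is net
background-corrected fluorescence relative to the vehicle control, ×100.

## The synthetic world

Defaults encode the emulated study design: 20 conditions (10 tissues × 2
ages), 5 replicates, 6% dynamic fraction, activation 4PL with EC50 36.4 μM
and top (Vmax) 14.2 pmol min⁻¹ (bottom 1.0, hill 1 — the latter two are
package choices; no hill or baseline is authoritative), engagement
occupancy d^h/(d^h + K^h) with K = 8 μM, h = 1.5 so that occupancy exceeds
0.5 across 10–20 μM, S/N base 100 with lognormal site effects.

* Replicate oxidation noise is Gaussian with SD 2.0 percentage points
  (no authoritative per-tissue value exists; 2.0 is a realistic replicate
  SD for percent-oxidation measurements), clipped to [0, 100]. Planted
  dynamic sites have true Δ ≥ threshold + 3·SD and stable sites
  ≤ threshold − 3·SD, so classification on the synthetic world is
  essentially noise-free by construction: a green classifier test
  establishes correctness of the max−min logic and threshold convention,
  **not** performance on borderline real-world sites.
* Ortholog pairs mutate a mouse sequence at substitution rate ≤ 0.1 and
  indel rate ≤ 0.02 (lengths 1–5); rates beyond those bounds, or realized
  identity below 40%, are rejected as unidentifiable. The generator tracks
  the exact residue correspondence, so mapping recovery is measurable. Real
  orthologs differ in ways the generator does not emulate (domain-level
  rearrangements, isoform mismatches, low-complexity regions).
* Engagement noise is multiplicative lognormal with unit mean (ratio-scale
  MS intensities); treated S/N is floored at 0.1% of baseline so S/N stays
  positive even at complete occupancy.
* The activation dose grid is 10 log-spaced points from EC50/30 to
  EC50·30 — a series reaching ~97% of plateau at hill 1, as a practitioner
  would design; with 4 replicates at 2% CV, refitted EC50 and Vmax recover
  within 10% at any seed (empirically ≤ 7.6% over 60 seeds).
* Intact-MS tables use a synthetic ~67.6 kDa base mass and 421.5 Da adduct
  mass; only intensity ratios matter downstream.

Determinism: every generator derives its RNG stream from (seed, stage tag),
so outputs are byte-identical across runs and independent of call order;
the pipeline manifest records SHA-256 digests of every artifact as the
determinism contract.

## Known limitations

* No peptide-spectrum matching, reporter-ion extraction, isotope correction
  or search-engine FDR — the S/N table is the entry point.
* No spectral deconvolution — the intact-MS entry point is the deconvoluted
  species table.
* The pairwise aligner handles exactly two sequences; no isoform selection
  beyond identifier matching, and many-to-many pairings are rejected rather
  than resolved.
* Cross-tissue statistics beyond the max−min definition (e.g. moderated
  tests) are out of scope, as are structural or docking analyses; structure
  IDs are carried but never interpreted.
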