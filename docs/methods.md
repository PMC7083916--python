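# Methods

## The problem

Heparan sulfate (HS) is a linear, unbranched glycosaminoglycan of
alternating uronic acid and glucosamine residues. Its sequence
information is carried by substituents — N-acetyl vs N-sulfo
glucosamine, O-sulfates at C2 (uronic acid) and C3/C6 (glucosamine) —
and by the C5 epimerization of the uronic acid (GlcA vs IdoA). Mass
spectrometry alone cannot read this code completely: GlcA and IdoA are
isobaric, and so are many sulfation isomers (3S vs 6S). Ion mobility
adds the missing dimension: the rotationally averaged collision cross
section (CCS, in Å²) of an ion in helium is shape-sensitive and
separates many of these isomers.

`simms2` implements a shotgun sequencing strategy on top of this: an
unknown saccharide is fragmented, the CCS of each glycosidic fragment
is measured, and each fragment is matched — by mass *and* CCS — against
a library of fragments from fully defined standards. Because a matching
fragment transfers its known residue sequence to the unknown's prefix
or suffix, overlapping matches from several standards can tile the
whole chain.

## Sequence and mass model

Sequences are ordered non-reducing end (NRE) → reducing end (RE), in
the field's shorthand (`dUA-GlcNS-IdoA2S-GlcNS3S`). Residue
compositions are the in-chain (dehydrated) forms — HexA C6H8O6,
ΔHexA C6H6O5, HexNAc C8H13NO5, HexN C6H11NO4, plus one SO3 per sulfate
— so a neutral molecule is Σ(residues) + H2O + (tag − H). Reducing-end
tags are monovalent aglycones replacing the anomeric hydroxyl hydrogen:
R1 aminopentyl (C5H12N), R2 methoxyphenyl-type (C7H7O), R3
p-nitrophenyl (C6H4NO2); the R1/R3 formulas follow from the named
chemistry and are configurable, since only R2's formula is fixed by its
source. Negative-mode ions are [M − zH]^z− with the proton at
1.00727646688 u. Masses come from the NIST monoisotopic table via
pyteomics.

Validation rules: residues strictly alternate uronic/GlcN; the
lyase-signature ΔHexA (`dUA`) is only legal at the NRE; 2S only on
uronic residues, 3S/6S only on GlcN. Synthetic standards that start
with a glucosamine are accepted behind an explicit
`allow_leading_glcn` flag so accidental reversals still fail loudly.
Free-amine GlcN is representable but excluded from default candidate
enumeration (no such standard exists in the packaged library).

## Fragmentation

Glycosidic fragments use Domon–Costello nomenclature with the
residue-sum convention: B_i = Σ(first i residues), C_i = B_i + H2O,
Y_j = Σ(last j residues) + H2O + tag, Z_j = Y_j − H2O. This makes the
complementarity identity B_i + Y_{n−i} = M exact (asserted to 1e-6 Da),
which is the internal cross-check used instead of any external table.
For untagged chains the full-length B_n (precursor minus the anomeric
hydroxyl as water) is also generated — that is the ion reported as
"B4" for untagged tetrasaccharide standards. Sulfate losses are
modelled as neutral-loss satellites (default at most one), flagged so
that downstream logic can treat them as corroborating-only evidence.
Cross-ring A/X fragments and intensity prediction are out of scope;
collision energies are metadata.

## Mobility physics

The measurement chain is the stepped-field drift-tube method in helium:

1. each arrival-time distribution (ATD) is centroided with a Gaussian
   fit (joint multi-Gaussian fit when more than one maximum exceeds a
   5% prominence threshold; conformers are reported in centroid order
   and tracked across voltages by area rank);
2. arrival times are regressed on reciprocal drift voltage — the slope
   is L²/K and the intercept the field-free dead time t0;
3. K is reduced to standard density, K0 = K·(P/760)·(273.15/T), and
   converted by the Mason–Schamp equation

   Ω = (3ze/16N0) · sqrt(2π/(μ kB T)) · 1/K0,

   with μ the ion–He reduced mass and CODATA constants.

Instrument geometry is a parameter set (`InstrumentConfig`); the
defaults L = 0.2505 m, T = 300 K, P = 3.5 Torr are plausible fixture
values for a linear drift tube, not measured constants, and every
result is conditioned on the config used. The synthetic generator
inverts the same chain (CCS → K → centroids → sampled Gaussian ATDs),
so simulate→fit→convert is an exact identity at zero noise; timing
noise is a relative Gaussian perturbation of each centroid. The default
ATD width model is a constant apparent resolving power of 55 (t/FWHM),
a hook that can be replaced by a diffusion-limited model.

Resolving-power arithmetic uses FWHM-based Rp = t/FWHM and
peak-to-peak resolution on base widths w_b = 4σ = (4/2.3548)·FWHM,
i.e. Rpp = 2Δt/(w_b1+w_b2). Hence Rp = (4/2.3548)·Rpp/δ for a relative
CCS difference δ, and the plate number N = (t/σ)² = (2.3548·Rp)².
For δ = 2% and Rpp = 0.75 this gives Rp = 63.7 (≈64) and N = 22,500 —
the base-width convention is chosen because it reproduces both numbers
simultaneously. Replicate CCS values are summarized as the mean with
the maximum relative deviation from the mean.

## Reference library

The packaged registry holds the 36 defined standards (#1–#36) and the
two natural hexasaccharides #HS1/#HS2, with every precursor and
fragment CCS printed in the main text of the originating study, stored
as printed (integer Å²). Structures or values reported only in
supplementary tables are deliberately absent — roster rows without a
sequence, standards without CCS entries — rather than guessed. Where
the source does not state the charge state of a printed CCS, the
charge is stored as unspecified and matched permissively. Libraries
round-trip byte-stably through a fixed CSV schema
(`standard_id,sequence,ion,charge,ccs_A2,provenance`) and a JSON
mirror; merging is conflict-checked on the (standard, ion, charge) key.

## Sequencer

Pipeline: precursor mass → bounded integer decomposition into residue/
acetyl/sulfate/tag counts (all solutions within the ppm window, 10 ppm
default) → exhaustive candidate enumeration → evidence matching →
coverage scoring and verdict.

Enumeration expands every placement of N-acetyl groups and O-sulfates
over their legal positions and every saturated uronic to both epimers;
a candidate cap (default 100,000) aborts pathological inputs with an
explicit error. When a disaccharide-composition table is supplied
(the standard orthogonal experiment), candidates are the orderings of
those units instead: the unit carrying the unsaturated uronic sits at
the NRE when the intact composition demands it, units with unresolved
epimers (`dUA-`/`UA-` prefix) expand to both GlcA and IdoA when placed
interior, and units with analyst-resolved epimers (`GlcA-`/`IdoA-`)
are interior-only, since epimer identity at a lyase-opened NRE is
unknowable. Epimer resolution at sites no CCS evidence reaches must
come from such orthogonal input; without it the package reports the
ambiguity rather than picking a side.

Matching requires four independent agreements: the observation's m/z
matches a theoretical fragment of the candidate (ppm window); a library
entry of the same series/index/loss matches in neutral mass; the CCS
agrees within max(2 Å², 0.5%) — the absolute floor reflecting the
integer precision of printed values, the relative part the replicate
scatter of the method; and the library fragment agrees
residue-for-residue (epimers included) with the candidate's
prefix/suffix, which is what licenses transferring the standard's
sequence to the unknown. Sulfate-loss satellites match but never cover
a site on their own.

A matched B_i/C_i confirms residues 1..i and covers cleavage sites
1..i; Y_j/Z_j cover sites n−j..n−1; a matched precursor CCS identifies
the whole structure. Candidates are ranked lexicographically by
(covered sites, distinct matched observations) — the second key is
needed because a wrong candidate can tile all sites with a strict
subset of the evidence while leaving observations unexplained. The
verdict is `unambiguous` only when a single candidate strictly leads
this ranking, `ambiguous` (with the full tied set and flagged epimer
positions) on any tie — two epimer variants that no evidence separates
always tie, by construction — and `insufficient` when nothing matched.
There is no tie-breaking heuristic. Reports are deterministic and
byte-identical for identical inputs.

## Synthetic data

The fixture generator emulates the study conditions: eight drift
voltages from 50–120 V, singly charged fragment ions in negative mode,
CCS values taken from library entries (or, for closed-loop tests,
synthetic values drawn reproducibly from a smooth ~mass^(2/3) size
trend plus a structure-keyed jitter so isomers stay distinct), timing
noise at the 0.1–0.2% level and CCS noise up to ~0.5%, matching the
reported replicate scatter. What it does not emulate: real conformer
multiplicity, intensity patterns, charge-state distributions, in-source
sulfate loss, or any systematic relation between structure and CCS —
so passing closed-loop tests demonstrates the correctness of the
bookkeeping and the matching logic, not the chemical realism of
synthetic CCS values. Problem sizes in the test-suite sweeps (dp 2–8,
candidate sets up to ~10^4) were chosen to exercise every code path
while keeping the default suite fast.

## Numerical choices and limitations

- ATD fits are initialized from detected maxima and half-prominence
  widths, with positivity bounds; non-convergence and flat traces are
  reported as errors, never silently dropped.
- Duplicate drift voltages are collapsed by averaging with a warning;
  a non-positive arrival-time slope is an error (unphysical mobility).
- CCS values are never re-precisioned: printed integers stay integers.
- Equal-CCS isomers are a real phenomenon; when library values within
  tolerance support several candidates the verdict stays ambiguous.
  Larger libraries, not looser tolerances, are the remedy.
- Traveling-wave/trapped/cyclic IMS calibration, vendor raw files,
  intact-chain multi-digest assembly and CCS prediction from 3D
  structure are out of scope.
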