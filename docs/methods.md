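# Methods

## The dereplication problem

The Mediterranean sponge *Crambe crambe* accumulates guanidine alkaloids in
two families: crambescins (sub-families A, B, C with bicyclic, spiro and
monocyclic guanidine cores) and the pentacyclic crambescidins.  Crambescins
form homologous series: each member carries an upper alkyl chain with
(n + 2) methylene units and a lower guanidinoalkyl chain with (m + 2)
units, so an LC-MS/MS run of the extract contains dozens of compounds that
differ only by CH2 increments and by how a fixed formula mass is split
between the two chains.  Dereplication — identifying these analogues from
spectral evidence without isolating them — therefore needs three things:
exact-mass arithmetic that is honest about charge states, a parametric
library of the homologue grid, and fragmentation rules that can tell two
homologues of identical formula apart.  This package implements that
procedure and a minimal molecular-networking stage, and ships a synthetic
forward model so every stage can be tested end to end.

## Mass conventions

All reported numbers use a four-decimal mass table: M_H = 1.0078, M_C = 12,
M_N = 14.0031, M_O = 15.9949 Da ("reported" preset).  A full-precision
"precise" table is available but the reported mass errors only regenerate
under the four-decimal table, so it is the default everywhere.  Protonation
adds exactly M_H per charge; the electron mass is ignored.  Hence

* neutral mass: `Mw = m/z * z − z * M_H`
* neutral-scale error: `1e6 * (Mw_exp − Mw_theor) / Mw_theor`
* fragment-ion error: `1e6 * (mz_obs − mz_theor) / (z * mz_theor)`

The fragment convention references the error to the **full cation mass**.
For z = 1 it is the ordinary ppm on m/z; for z = 2 it is half of that.
This is the only convention that reproduces every reported fragment error
(e.g. 127.0863 observed for [C12H22N4O2]2+, theoretical 127.0869, is
−2.36 ppm on the 254.17 Da cation, not −4.7 ppm on m/z); it was validated
against six independent reported values before the main build.

Reported values round half-away-from-zero: masses and m/z to 4 decimals,
ppm to 2.  RDBE is `C − H/2 + N/2 + 1` (oxygen contributes nothing).

## Scaffold library

With `k = 14 + m + n` for chain-parameterized families and `k = 26 + m` for
the fixed-upper-chain families, the neutral formulas are

| family      | formula            | RDBE |
|-------------|--------------------|------|
| A           | C_k H_(2k−4) N6O2  | 6    |
| didehydro A | C_k H_(2k−6) N6O2  | 7    |
| A3          | C_k H_(2k−12) N6O2 | 10   |
| B, C        | C_k H_(2k−2) N6O3  | 5    |
| B3, C3      | C_k H_(2k−10) N6O3 | 9    |

These coefficients regenerate all 38 annotated homologue formulas of the
reference table exactly.  Diagnostic fragments are linear element-count
functions of (m, n), stored in a human-editable YAML config
(`data/crambe_scaffolds.yaml`) together with enumeration ranges
(m ∈ [2, 8], n ∈ [2, 12] by default), the closed crambescidin list and the
marker ions.  The main rules:

* **A family** — methylenediamine loss `[M+2H−CH2N2]2+`; further
  alkyl-chain loss `C(n+3)H(2n+6)` giving `[C(m+10)H(2m+18)N4O2]2+` (reads
  out m, and with it n); guanidinoalkyl chain `[C(m+3)H(2m+10)N3O]+` and
  its water loss; a provisional ester-cleavage ion `[C(n+10)H(2n+14)NO]+`
  generalized from two observations (lowest weight).
* **A3** — as A with the alkyl loss fixed at C15H22 (202 Da nominal,
  locating the four extra unsaturations on the upper chain), plus a
  constant core ion `[C23H34N3O2]+` at 384.2643.
* **B family** — the retro-Diels–Alder pair `[C(n+5)H(2n+12)N3]+` /
  `[C(m+9)H(2m+16)N3O3]+` (element-conserving: they sum to the precursor
  dication), CH2N2 loss from the upper RDA ion, the spiroaminal ring ion
  `[C6H7O2]+`, and the guanidinoalkyl ions.
* **C family** — the doubly charged C-diagnostic
  `[C(m+10)H(2m+17)N3O3]2+` plus the guanidinoalkyl ions.  B3/C3 reuse the
  B/C rules with the upper-chain ions 8 H lighter (fixed unsaturated
  chain), matching the observed 274.2275/232.2046 pair.

Singly charged analogues of the CH2N2-loss ions are included at low weight
so spectra triggered on [M+H]+ instead of [M+2H]2+ still match (m/z-based
matching makes this the whole of the dual-charge-interpretation handling).

Crambescidins have no homologue rule and form a closed list (800, 816,
830, 834, 841, 857, 875, the crambescidin acid C22H33N3O4, crambescins 253
and 281, and three small guanidine-related formulas).  Names take the
**integer part** of the monoisotopic mass: rounding to nearest would call
crambescidin 800 (monoisotopic 800.6120) "801" and 875 (875.6411) "876",
while truncation reproduces every published name.

## Annotation procedure

For each feature, all library candidates within ±5 ppm of the neutral mass
are enumerated and scored by the summed diagnostic weights of their
matched MS2 ions (family-discriminating ions weigh 1.0–1.5; water losses
0.5; provisional ions 0.25), tie-broken by |precursor ppm| and then by
fewer unmatched rules; ordering is fully deterministic.  Candidates with
no fragment evidence are retained but flagged `formula_only`.

Fragment matching uses 5 ppm on the full cation mass with a 0.002 Da
absolute floor below m/z 400: four-decimal printed m/z values alone are
±4 ppm at m/z 127, so a pure ppm rule would reject genuinely printed ions.
Above m/z 400 the 5 ppm rule is strict.

**B vs C isobars.**  B and C homologues of the same (m, n) share a formula
and are never merged.  The C core (two conjugated double bonds) undergoes
the retro-Diels–Alder cleavage less readily than the spiro B core, so C
spectra show an intense C-diagnostic dication and only weak RDA ions.
The discriminator computes `r = I_C / (I_C + I_B)` with I_C the
C-diagnostic intensity and I_B the summed RDA-pair intensity, and calls C
when r ≥ θ (default θ = 0.5 — the midpoint; the source evidence is only
qualitative "intense" vs "significantly lower", and under the generator's
intensity profiles the ratio is bimodal around ~0.7 vs ~0.0, so the call
is insensitive to θ over a wide range).  When neither diagnostic is
present the annotation is reported as "B or C", never silently one of
them.

**Crambescidins** require a closed-list formula match plus at least two of
the three marker ions (guanidine core 264.1709, its dehydration product
246.1602, pyrrolinium 70.0655); otherwise the feature falls back to
"guanidine-related compound (formula)".

**Isomer labels.**  A3 candidates sharing a formula and detected as
exactly two features are labelled cis (earlier eluting) and trans (later)
by expected relative polarity; groups of any other size stay unlabelled
(with a warning for >2) because polarity only orders a pair.

## Spectra I/O and feature assembly

MGF is read and written through pyteomics.  mzML is read-only through a
small in-package parser (lxml + base64/zlib decoding of the peak arrays,
handling the ~10 controlled-vocabulary terms the pipeline needs:
ms level, centroid/profile, scan start time, selected-ion m/z and charge,
array encodings); profile-mode data are rejected with an explicit message.
Feature assembly is deliberately simplified — centroids grouped within
5 ppm and contiguous retention time (gap ≤ 0.1 min), apex = maximum
intensity, isotope satellites folded in by searching +1.003355/z steps
(tolerance 0.01 Da, adequate at ~70k resolution) — because feature finding
is upstream plumbing here, not the method under study.  Charge is
`round(1/median spacing)` for z ∈ {1, 2, 3}, ties toward lower z;
inconsistent envelopes leave the feature flagged, not dropped.  MS2 scans
attach to the nearest feature within 0.02 Da and 0.2 min (the precursor
tolerance is a stated workflow value; the retention-time window is this
package's default).  QC checks the spiked yohimbine and reserpine [M+H]+
ions (355.2015 / 609.2801) at ≤5 ppm and reports, never raises.

## Molecular networking

The modified cosine takes square-root, L2-normalised intensities; peaks
match directly or shifted by the precursor m/z difference; the one-to-one
pairing maximising the summed weight products is solved exactly as a
linear assignment problem (scipy), not greedily, and a property test holds
it equal to brute-force enumeration on small spectra.  Edges require
cosine ≥ 0.7 and ≥ 6 matched peaks (standard feature-based molecular
networking thresholds); top-K pruning is available but off by default.
Components are labelled and node attributes (annotation, subfamily,
side-chain type) can be overlaid for GraphML export.

A caution established while building the package: on a *full* homologue
grid, modified cosine chains CH2 homologues — a (m, n) → (m+1, n+1) step
shifts the precursor by exactly one CH2, so all m-dependent singly charged
ions match shifted and whole families merge into single components.
Because the side-chain type labels partition the grid by (m, n), such
components necessarily mix labels, and with only rule-derived ions in the
spectra (6–8 peaks), cross-family type clusters cannot reach the 6
matched-peak threshold at all.  Clustering of extract data by side-chain
type is therefore a property of which compounds a real extract contains
and of the many minor ions real HCD spectra share, not something the
diagnostic rule set alone reproduces; the networking example prints the
measured grid purity rather than asserting the extract behaviour.

## Synthetic data generator

The generator is the forward model of the rule set.  Per planted compound
it emits the protonated precursor at its theoretical m/z, an isotope
envelope with 1.003355/z spacing and a Poisson-shaped intensity pattern,
and an MS2 spectrum containing the family's diagnostic ions under a family
intensity profile plus a residual precursor peak (30% — HCD spectra of
multiply charged precursors retain it).  Qualitative intensity statements
are encoded as ratio bounds: C-family spectra draw the C-diagnostic at
60–100% of base with B-type ions leaking in at 5–25%; B-family spectra
draw the RDA pair at 70–100%/40–80% with no C-diagnostic.  Mass jitter is
a truncated Gaussian (σ = bound/3, hard-truncated at ±bound, default
bound 3 ppm), a calibrated-Orbitrap error model that keeps every planted
ion within the annotation tolerance by construction.  Decoy peaks are
uniform over m/z 60..precursor and rejected inside twice the matching
tolerance around true ions so the planted truth stays well defined; an
adversarial mode instead drops half the decoys within ±1.5 mDa of true
ions to probe false-annotation behaviour.  All randomness flows through
one seeded generator; a fixed seed gives byte-identical runs, and the
manifest TSV records every planted truth.

The "extract-like" manifest plants all 53 reference-table compounds plus
the two internal standards at their reported retention times and charge
states.  What the generator does **not** emulate: chromatographic peak
shapes, adducts and in-source fragments, isotope fine structure, chimeric
MS2 spectra from co-isolation, and the long tail of minor fragment ions in
real HCD spectra.  Passing round-trip tests therefore demonstrate the
internal consistency of the rules and the annotator, not performance on
instrument data — the known chimeric peaks in the reference table (three
of 132 printed fragments) are exactly the kind of artefact the generator
does not produce.

## Problem sizes and numerical choices

The stochastic recovery check uses 200 seeded extract-like runs (7,600
planted crambescins, 3,600 B/C calls) at 3 ppm jitter and 10 decoys per
spectrum; the brute-force cosine oracle runs 1,000 random ≤8-peak spectrum
pairs; the grid network covers all 329 (subfamily, m, n) points.  These
sizes keep the full suite and the acceptance script each under a minute on
one core while leaving the statistical checks well-powered.  Degenerate
inputs are defined, not special-cased: empty spectra score (0, 0) in the
cosine; an empty annotation set yields a header-only report; subtraction
of formulas below zero, non-positive tolerances and empty manifests raise.

## Known limitations

* Elements beyond C/H/N/O are accepted by the formula engine but no
  scaffold uses them; adducts other than protonation are out of scope.
* The A-family ester-cleavage ion and the A3 core ion are generalized from
  few observations and are flagged provisional in the library config.
* Feature assembly is not a chromatographic deconvolution; heavily
  overlapping traces of identical m/z merge or split by the retention-gap
  rule alone.
* The networking stage reproduces the similarity measure and thresholds,
  not extract-scale network statistics (those depend on real feature
  extraction and spectral richness, as discussed above).
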