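# Methods

## The measurement model

AAPL reads out spatial proximity chemically: an antibody carrying an
Fe(III) chelate binds its antigen, hydroxyl radicals generated from H₂O₂
oxidize side chains within the reaction radius, and label-free MS
quantifies each peptidoform. The package's two primitive quantities are
ratios of peptidoform intensities:

* **site degree of oxidation** — per tryptic peptide and condition,
  `I_ox(p) / (I_unmod + Σ_q I_ox(q))` for each oxidized residue position
  *p*. When the denominator is zero the peptide contributes nothing.
* **extent of protein oxidation (EPO)** — per protein and condition, the
  summed oxidized intensity over the summed total intensity. EPO is a
  weighted mean of per-peptide oxidized fractions, hence always in [0, 1].
  Zero total intensity yields an undefined-EPO sentinel (NaN) that is
  excluded downstream and logged.

Replicate handling: intensities are **summed across replicates** for all
point estimates (degree, EPO, spectral counts); EPO is separately computed
per replicate for significance testing only. The input format does not
distinguish charge states or other peptidoform duplicates — all rows of
the same (peptide, modification) pair are merged, and when missed-cleavage
variants cover the same residue the maximum degree is kept so each site
has one value per condition.

Cross-condition quantities:

* **normalized EPO** — each protein's EPO divided by its maximum across
  conditions, so the optimal condition reads 1 (all-zero proteins stay 0).
* **EPO fold change** — treatment EPO over the mean control EPO, floored
  at ε = 10⁻⁴ to avoid division by zero; floored denominators set an
  `fc_capped` flag rather than disappearing.
* **significance** — one-sided Welch t-test of the treatment replicate
  EPOs against the pooled control replicates, Benjamini–Hochberg corrected
  across proteins. Proteins with fewer than two replicate values per side,
  or zero variance on both sides, get NaN sentinels. Note that under a
  global null the BH-adjusted q-values reject essentially nothing (that is
  the point of FDR control); the raw p-values are the quantity whose
  sub-0.05 fraction sits near the nominal 5%.
* **condition clustering** — conditions × proteins EPO matrix (undefined →
  0), correlation distance, average linkage. Conditions enter in sorted id
  order, which makes equal-distance merges deterministic; constant rows
  would produce undefined correlations and are treated as distance 1.

## The AAPL score

The score adapts the AP-MS topological score to oxidation data. The matrix
entry is `v(p, c) = oxidized spectral count × EPO` — the two available
protein-level oxidation readouts, one counting-based and one
abundance-based; their product rewards proteins that are high on both. The
transform is `score = v · ln(v / E)` with the independence expectation
`E = row_sum × col_sum / grand_total` and `0 · ln(0/E) := 0`. Scores are
positive exactly where the observed signal exceeds the expectation,
permute with rows, and scale linearly with the matrix — so the absolute
thresholds 0 and 1 presume data of comparable depth. A `rescale_total`
option normalizes the grand total for cross-dataset comparability
(off by default, to keep the printed thresholds meaningful as-is), and a
`mode` switch offers `spc_only` and `tops_times_epo` compositions since
the exact published combination of the two readouts is not printed in full.
The per-protein AAPL score is the TopS value read at the selected
(optimal) treatment condition; every other condition — controls and
suboptimal treatments — shapes the expectation.

All-zero matrix rows are dropped before the transform (logged); those
proteins are unscored and sit outside the classified universe.

## Classification conventions

The published thresholds are quoted as "above", which this package reads
strictly; range endpoints are resolved as follows and are configurable:

| call | rule |
|---|---|
| L1 | score > 1 |
| L2 | 0 < score ≤ 1 **and** EPO FC > 1.5 |
| T1 | direct bait edge, combined score > 0.7 |
| T2 | direct bait edge, 0.4 ≤ score ≤ 0.7 |
| T3 | no qualifying bait edge, but an edge (≥ 0.4) to a T1/T2 protein |
| T4 | every remaining scored protein |

The bait is excluded from its own interactor list; proteins without a
defined fold change cannot be L2. The universe for typing (including the
T3 adjacency rule) is the set of scored oxidized proteins. Score-bin
summaries use (1, ∞), (0, 1], (−∞, 0], assigning score 0 to the lowest
bin. Cross-reactivity is reported by looking up an off-target antigen in
another antibody's result table and flagging it if it would classify
L1/L2 there.

## Network assembly

A single-bait graph holds the bait, all L1/L2 interactors, and scored
non-interactor ("grey") proteins that connect to the bait or to an
interactor through a known-interaction edge; edges among grey nodes are
kept only when both endpoints are already in the graph. Edge style encodes
the weaker endpoint's STRING type (solid for bait/T1/T2, dashed for T3,
backslash for T4); opacity bands follow STRING's conventional confidence
tiers 0.4 / 0.7 / 0.9. Node fill is exported as the numeric EPO FC, not a
color — rendering belongs to the consumer (a linear white→red ramp over
FC 1–5 reproduces the usual look). Merged graphs union nodes and edges,
keep the maximum score on duplicate edges, and carry both baits' level and
FC attributes on shared nodes.

## Glycan typing

Compositions are counts of (Hex, HexNAc, Fuc, NeuAc). The five-type rule
formalizes standard N-glycan nomenclature, with the decision order giving
the mixed fucosyl-sialyl class precedence:

1. **HM** if HexNAc ≤ 2, Hex ≥ 4, no Fuc, no NeuAc (unsubstituted
   high-mannose core, Hex4–9HexNAc2);
2. else **FS** if Fuc ≥ 1 and NeuAc ≥ 1;
3. else **F** if Fuc ≥ 1; else **S** if NeuAc ≥ 1; else **CH**.

Per-protein percentages are intensity-weighted by default (count weighting
available) and sum to 100. The inhibitor comparison contrasts EPO under
the optimal labeling condition against kifunensine and sialyltransferase-
inhibitor co-treatments; an interactor is flagged *decreased* when its
EPO ratio to control falls below 1 − δ with δ = 0.2 — the published
observations are qualitative, so δ is an explicit, configurable default.

## The synthetic generator

The generator emulates the complete experiment so every downstream stage
is testable against ground truth:

* **proteome** — random sequences (120–360 residues) from rounded human
  amino-acid frequencies; tryptic digestion (cleave after K/R, not before
  P, up to a configurable number of missed cleavages) with a 6–50 residue
  detectability window.
* **oxidation** — each residue's expected mono-oxidation stoichiometry is
  `p_background × residue_weight × enrichment(protein, condition)`.
  Residue weights follow hydroxyl-radical reactivity (M 5, C 3, W 3, Y 2,
  F 1, H 1, all others 0.1); `p_background = 0.003` puts background
  stoichiometry at ≈1.5% on methionine and ≈0.03% on unreactive residues,
  typical of footprinting background. Enrichment is 8× for the bait and
  its 10 proximal partners, 1 for background proteins and in all control
  conditions. Realized stoichiometry is `Binomial(n_copies, π)/n_copies`
  with `n_copies = 50`, so its mean is exactly π while small peptide pools
  show zero-oxidation dropout.
* **condition series** — treatment conditions carry a relative labeling
  efficiency (M1–M6 = 0.25, 0.40, 0.30, 0.60, 1.00, 0.80) scaling the
  proximity-dependent excess, emulating the probe-optimization screen in
  which one condition is optimal. This grading is what gives the score its
  contrast: were all treatments equally efficient, the row/column
  expectation would absorb the enrichment entirely.
* **intensities and counts** — one lognormal base intensity per peptide
  (log-mean 14 ≈ 1.2 M counts, log-sd 1) with 0.2 log-sd replicate noise,
  split exactly between the unmodified and oxidized forms (intensity is
  conserved by construction); spectral counts are Poisson with mean
  10⁻⁵ × intensity, giving ≈12 spectra for an average unmodified peptide.
* **known-interaction edges** — a configurable fraction (default 0.5) of
  the truly proximal proteins receive a direct bait edge with combined
  score uniform in [0.4, 1.0], reflecting the partial overlap between
  proximity labeling and literature-derived interaction databases; decoy
  edges connect random background pairs.
* **perturbations** — per-condition, per-protein enrichment overrides let
  a condition weaken specific interactions, used to emulate
  glycosylation-inhibitor experiments where sialylation-dependent
  interactors lose their proximity signal.

What the generator does **not** emulate: MS acquisition (spectra,
retention time, missing values from data-dependent sampling),
search-engine identification error, shared peptides between proteins,
di-oxidation and other modification chemistries, antibody binding
kinetics, or any geometric notion of distance beyond the three proximity
classes. Passing tests therefore demonstrate that the statistical pipeline
recovers a proximity-dependent oxidation signal of realistic magnitude and
noise — not that it is robust to identification artifacts in real
searches.

## Problem sizes and numerical choices

The reference experiment is 200 proteins with 10 proximal partners, nine
conditions, three replicates (≈160 k table rows); recovery metrics average
five seeded replicates, and the null calibration uses 1,000 proteins.
These sizes make every property measurable with stable statistics while a
full run stays in the tens of seconds. Other conventions: all residue
coordinates are 1-based inclusive; tables are tab-separated with headers
and are validated hard (malformed rows are errors, not warnings; rows with
zero intensity and zero spectral count are dropped with a logged count);
STRING scores are normalized to [0, 1] on input whichever dialect arrives;
ties in the glycan dominant-type ranking break alphabetically; natural
logarithm throughout the score transform.

## Known limitations

* The exact published composition of spectral counts and EPO inside the
  interaction score is not fully printed; the default here is the product
  rule, with the alternatives behind a switch.
* Score thresholds inherit TopS's linear scaling with data depth; applying
  the 0/1 cutoffs to datasets of very different depth requires the
  rescaling option.
* The q-value column answers the FDR question, not the per-protein
  type-I-error question; see the note under significance.
* The generator's proximity model is class-based; graded distance decay
  within the labeled neighborhood is not represented.
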