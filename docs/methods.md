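# Methods

## Data model and validation

A mutation record carries a 4-character structure identifier, chain, author
residue number, wild-type and mutant amino acid (20-letter alphabet),
wild-type Tm (°C), ΔTm = Tm(mutant) − Tm(wild type) (°C), and optionally pH,
measurement technique (CD, DSC, FL, Abs, activity, other), and the three
structural features. Rows failing invariants (self-substitution, |ΔTm| ≥
20 °C, pH outside (0, 14), unparseable numerics) are quarantined with their
reasons in a validation report rather than silently dropped, so any
exclusion is reconstructible. The input-table schema (TSV, documented column
names, a column-mapping dialect for foreign layouts) is defined by this
package.

Stability categories use a ±2 °C band: ΔTm < −2 destabilizing, ΔTm > +2
stabilizing, otherwise neutral. The boundary |ΔTm| = 2 is classified neutral
(closed neutral band): the colored categories are defined by strict
inequalities, so the symmetric closure is the least surprising choice.
Substitution-matrix cells report the mean ΔTm for cells with at least 3
entries by default (sample, n−1, standard deviation, requiring at least 2);
"at least 3" versus "more than 3" is genuinely ambiguous in the literature
this mirrors, so the threshold is configurable and neither reading is
asserted as canonical. Equal-count binning assigns sorted entries to bins
whose sizes differ by at most one; Tm histograms use 1 °C left-closed bins.

## Structural features

* **RSA** = ACC / maxACC(aa), clamped to [0, 1] with a clamp counter.
  ACC values are consumed from classic fixed-column DSSP output; the
  denominator is a theoretical maximum-ASA table (Tien et al.-style values),
  swappable via `MaxAccTable`. No in-house accessibility computation from
  coordinates is attempted.
* **Mean B-factor** averages the B-factors of exactly the residue's C, N and
  O atoms; S, H and other elements are excluded. Backbone atoms are included
  by default; a sidechain-only mode exists because the literature is
  inconsistent about which atom set is meant, and the two modes differ
  mainly for small residues.
* **Secondary structure** simplifies DSSP's eight classes to a ternary code:
  B, E, S → −1; H, G, I → +1; T, blank and anything else → 0. Note that S
  (bend) deliberately groups with the sheet-like class; this matches the
  convention the package reproduces, not DSSP's own taxonomy.

PDB parsing goes through Bio.PDB (first model, heteroatoms excluded).
Alternate locations keep the highest-occupancy conformer, ties broken by
altloc identifier order; author numbering is preserved verbatim. Annotation
never alters ΔTm, Tm or entry count; unmatched residues and wild-type /
structure sequence disagreements are flagged per entry and the entry is
retained unannotated.

## Featurization and normalization

The 19-slot input vector is: 8 wild-type descriptor values, 8 descriptor
deltas (mutant − wild type), RSA, mean B-factor, ss code. The default
8-scale property table (Kyte–Doolittle hydrophobicity; Zamyatnin side-chain
volume, Å³; Grantham polarity; formal charge at neutral pH with Asp/Glu −1,
Lys/Arg +1, His 0; side-chain H-bond donor+acceptor count, this package's
convention; Vihinen normalized flexibility; Pace–Scholtz helix propensity,
kcal/mol; Chou–Fasman sheet propensity) ships as a TSV config, so any
alternative scale set — including a different 16-number layout — can be
swapped in without code change. The "8 wild-type values + 8 deltas = 16"
layout is this package's reading of a wild-type-plus-change featurization;
equivalence with any particular published scale set is not claimed.

Normalization is z-scoring with statistics estimated on the training split
(after mock-WT augmentation, per replicate) and reused verbatim for
validation, test and grid inputs. The ss slot and the two charge-coded slots
(wild-type charge ∈ {−1,0,+1}, charge delta ∈ {−2..+2}) are passed through.
A constant training slot gets SD 1 and a degeneracy flag rather than an
error, so tiny fixtures train.

## Baseline network and training protocol

Architecture: 19 inputs → 64 rectified hidden units → 1 linear output;
loss is mean-square error in °C². The optimizer is Adam (β₁ 0.9, β₂ 0.999,
ε 1e−8) with learning rate 1e−3, minibatch 64, seeded shuffling, at most
2000 epochs, early stopping after 50 epochs without validation improvement,
restoring the best-validation-epoch weights. Hidden activation, optimizer
settings, patience and batch size are config-exposed choices of this
package. The implementation is plain numpy, which keeps a fixed seed
byte-for-byte reproducible on one CPU.

Protocol: the dataset is extended with 15 mock wild-type rows per protein
(wild type → wild type at a sampled annotated residue, ΔTm = 0), split
60/30/10 by a seeded shuffle (floor for train and validation, remainder to
test), and trained once per split across replicates (default 20). The final
model is chosen by best validation RMSE with ties broken by split seed — a
deterministic, order-invariant replacement for manual model picking.
Evaluation reports RMSE, Pearson r (flagged undefined under zero variance)
and |error|-band shares [0,1), [1,4], (5,∞), [10,∞); the last two bands
overlap and the (4,5] gap is uncovered by construction, reproducing the
reporting convention this package mirrors rather than a clean partition.

The symmetry experiment trains, per seed, one network on the forward
train/validation parts and one on those parts doubled with reversed
mutations (wt/mut swapped, ΔTm negated, wild-type features copied — the
mutant structure is not modeled), evaluating both on the same forward test
part, and reports per-seed RMSEs, their medians over 5 seeds, and the
prediction asymmetry statistic mean |pred(a→b) + pred(b→a)|.

## Prediction grid and per-substitution models

The grid fixes the enumeration order (substitution block, then ss
ascending, RSA ascending, B ascending) so exports are diffable; raw feature
values are passed through the model's stored normalizer at query time. Grid
size invariants: 462 rows per substitution, 175,560 for all 380.

Per-substitution models are OLS of ΔTm on (RSA, B, ss) with intercept,
refused below 10 entries (4-parameter fits on fewer points are judged
unstable) and on rank-deficient designs. The ss code enters as the numeric
−1/0/+1 value. The two Val→Ala reference equations are transcribed fixtures
with immutable parameters; the symbolic form has a pole at RSA = 0.89/8.58 ≈
0.1037, where evaluation returns NaN (flagged undefined) rather than
±infinity. The symbolic-regression search engine itself is out of scope.

The web-app export writes one JSON document per observed substitution
(experimental entries with stability-category colors, plus that
substitution's grid predictions) and an index; a schema validator ships with
the package.

## Synthetic data generator

The generator emulates the composition of curated ΔTm collections; defaults
are: 1626 entries over 90 proteins; protein sampling weights 0.28 / 0.13 /
0.08 for the three dominant families and uniform for the rest; per-ordered-
substitution linear baselines with intercept c0 = shift − |N(0, scale)|
(shift 1.8 °C, scale 5.5 °C), RSA slope −0.9·c0 (the effect decays toward
zero at exposed sites), B slope ~ N(0, 0.02 °C/Å²), ss slope ~ N(0, 0.8 °C);
observation noise N(0, 2 °C); 5% outliers with magnitude uniform in
4–15 °C and random sign, standing in for structure-specific contributions;
RSA from a buried/exposed mixture (55% N(0.05, 0.05), 45% N(0.5, 0.2),
clipped to [0,1]); B from Gamma(4, 7.5) (mean 30 Å²); ss categorical
(0.25 / 0.35 / 0.40 for −1/0/+1); pH and technique from the published
marginal shares. Entries with |ΔTm| ≥ 20 °C are resampled by default
(clipping would distort the noise model); a drop mode exists. The skew
defaults were set once so the destabilizing/stabilizing fractions at
defaults land near the published 47% / 11.8% marginals.

Ground truth (realized coefficients, per-entry baseline, noise, outlier
flags and deviations, seed) is returned alongside the dataset, enabling
recovery tests: per-substitution OLS on well-sampled substitutions recovers
the generating coefficients within 3 standard errors at 2 °C noise, and the
network trained on noise-free data reproduces the generative RSA dependence
in rank order.

What the generator does **not** emulate: the joint empirical distribution of
(RSA, B, ss) in real structures, residue-level spatial correlation within a
protein, any relation between substitution identity and feature distribution,
or genuinely structure-specific (rather than random additive) outliers.
Passing recovery tests therefore demonstrates correctness of the pipeline's
estimators under the stated generative model, not predictive accuracy on
real proteins. Toy structure fixtures are geometric placeholder peptides
(valid PDB text plus matching classic-format DSSP text with integer ACC
values), sufficient for parser and feature tests only.

## Numerical choices and problem sizes

Feature values in synthetic tables are rounded at draw time (RSA to 4
decimals, B to 2, ΔTm to 4) so the emitted table reproduces the ground-truth
baseline exactly. OLS uses `numpy.linalg.lstsq`; tests cross-check against
an explicit normal-equations solver. Equation evaluation near the symbolic
pole uses a 1e−9 guard. Test-suite problem sizes (600-entry shared synthetic
dataset; 200–2000-entry generated sets; 5-seed symmetry medians; 300–2000
epoch budgets) were chosen so the full suite runs in seconds on one CPU
while leaving the statistical assertions comfortably powered.

## Known limitations

* The package's featurization matches the published 19-input layout and
  count, but the exact identity of published descriptor scales is not
  recoverable; headline accuracies from the literature (e.g. ~3.2 °C test
  RMSE on the real curated dataset) are reproducible in character, not
  asserted numerically, without the real data and structures.
* mmCIF input, the full DSSP hydrogen-bond algorithm, ΔΔG handling,
  hyperparameter search and GPU training are out of scope.
* The unregularized network can wiggle slightly between training points;
  predictions off the training manifold should be read as baselines, not
  case-level estimates — which is precisely the package's thesis about
  structure-specific deviations.
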