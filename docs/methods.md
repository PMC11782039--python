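# Methods

This note documents the models, parameter choices and numerical
conventions of plasmapipe, and what the synthetic experiments do and do
not establish.

## Cohort model

The simulator emulates a three-group plasma study: controls (CNTR, 24
samples) and two disease groups (KD 25, KC 26), with 650 proteins.
Protein baselines are log-normal, log₁₀ mean 6.0 and sd 0.8, spanning
roughly four orders of magnitude, as plasma does. Each cell adds
within-group scatter of sd 0.12 log₁₀. That value is calibrated to the
significance scale the study design implies: a 1.5-fold group
difference at ~25 samples/group reaching BH-adjusted p ≈ 10⁻⁴ requires
within-group sd of roughly 0.1–0.15 log₁₀; at sd 0.3 such effects would
be undetectable at those p-levels. Per-sample loading offsets default
to zero because the emulated quantitation tables are per-injection
calibrated concentrations; a nonzero loading sd induces a cohort-wide
correlated shift between groups that no per-protein test can be
calibrated against (imputation experiments construct loading variation
explicitly, sd 0.15).

Injected effects multiply one protein's values in one group by |fc|
(divide for negative fc), applied after all random draws — so a design
re-generated with the same seed has identical baselines with and
without effects, and experiments can target effects at quantifiable
(abundant) proteins, as the study's DEP candidates are abundant
acute-phase proteins.

Missingness mixes a MCAR floor (default 5%) with a logistic
left-censoring term centred at log₁₀ intensity 4.8 with slope 2 per
log₁₀ — low-abundance cells vanish preferentially, the signature of
label-free plasma data. With slope 0 the censoring term is off
entirely (the raw logistic would otherwise contribute ½ at any
intensity). The paper-facing defaults are conventions: the study
reports no missingness rates.

What the generator does **not** emulate: peptide-level interference,
retention-time drift, batch effects, non-log-normal contamination, or
correlated protein modules. Passing tests therefore establish that the
statistics are calibrated and the geometry is correct under a clean
generative model — not that the pipeline is robust to all failure
modes of real acquisitions.

## QC and imputation

* Sample filter: keep samples with **more than** 70 observed proteins
  (strict inequality; a 70-protein sample is dropped). Idempotent.
* Loading factors: per sample, the median log₁₀ intensity over anchor
  proteins. The strict anchor rule (observed in every retained sample)
  is the default; at realistic cohort sizes complete observation is
  rare, so the pipeline relaxes the anchor criterion to proteins
  observed in ≥ 90% of samples (`anchor_fraction=0.9`), with
  NaN-skipping medians. Fewer than 3 anchors is an error.
* Per protein with ≥ 3 observations: OLS of log₁₀ intensity on the
  loading factor; predictions back-transformed and flagged. Proteins
  with < 3 observations stay missing. Observed cells are never
  altered. Imputation regresses censored low values toward the
  protein's typical level, which attenuates extreme fold changes
  slightly — visible as a few-percent shrinkage in the recovery
  experiments, and a known limitation for heavily censored proteins.
* Inclusion: presence (observed + imputed) in ≥ 50% of the group's
  samples and imputed share ≤ 50% of the present values. The two
  rules are deliberately non-redundant (coverage vs imputation load).
  Boundary cases sit exactly on the ≥ / ≤ conventions.

## Differential expression

Fold change is the signed ratio of group medians (magnitude ≥ 1,
positive = elevated in the disease group; ties → +1). Medians include
imputed values, consistent with the inclusion rules counting them.
Mann–Whitney U is exact (enumeration) when min(n) ≤ 8 with no ties,
otherwise normal approximation with midranks, tie correction and
continuity correction; sides with < 3 values are untestable (NaN, not
an error). BH runs within each comparison separately. DEP selection is
strict on both thresholds: |fCh| > 1.5 **and** adjusted p < 0.05 in at
least one comparison; selected proteins are reported with both
comparisons' values, including non-significant companions.

## Multivariate segmentation

Feature gate: proteins *observed* (non-imputed) in ≥ 20 samples
overall. The matrix is log₁₀, column-standardized (population sd);
cells still missing after imputation are set to the column mean (0
after centering). PCA is a thin SVD of the centered matrix; component
sign is fixed by making the largest-magnitude loading positive.

sPLS-DA one-hot codes the classes (centered) and runs NIPALS weight
updates with soft-thresholding to the keepX largest-magnitude weights
per component, convergence at relative change < 1e-6 or 500 iterations
(non-convergence is flagged, not raised); X and Y are deflated between
components. In the dense limit this equals unpenalized PLS2 — checked
against the exact oracle (dominant left singular vector of XᵗY with
deflation). Scaling is unit-variance, matching the common default of
sPLS-DA implementations; keepX, when not given, is tuned over
{5, 10, 20, 50} by stratified 5-fold CV on balanced accuracy with a
required seed. Prediction assigns the nearest class centroid in score
space; exact ties (at 1e-12 resolution) break to the lexicographically
smaller label. Confidence ellipses are normal-theory: semi-axes
√(eigenvalue · χ²₂(level)); a singular covariance is flagged
degenerate. ROC is one-vs-rest with trapezoidal AUC.

## Structural descriptors

SASA: Shrake–Rupley with a deterministic golden-spiral point set
(960 points/atom), probe 1.4 Å, Chothia-style heavy-atom radii
(C 1.87, N 1.65, O 1.40, S 1.85, P 1.80 Å); hydrogens ignored, waters
and ligands excluded. The engine agrees with an independent
latitude–longitude quadrature within 2% and with the analytic
two-sphere formula.

Peptide mapping is exact substring search on each chain's
resolved-residue sequence, tolerating internal unresolved gaps up to
20% of peptide length (endpoints must be resolved); optional
Ile/Leu-equivalent matching is off by default; all matches are
returned, with a warning for multiple matches within a chain.

K_SASA = SASA(peptide atoms | complex) / SASA(peptide atoms | parent
chain extracted alone). The denominator keeps the peptide in its own
chain — the ratio isolates partner-induced burial. A fully buried
peptide (zero denominator) yields NaN with a warning.

Contacts: hydrogen bonds are N/O/S–N/O/S pairs at ≤ 3.5 Å (covalently
bonded pairs excluded; when hydrogens are present a D–H···A angle
≥ 120° is additionally required); hydrophobic contacts are pairs of
apolar carbons (no bonded N/O) at ≤ 5.0 Å. Both are counted between
the peptide and *all* non-peptide atoms — own-chain context included —
because restricting to partner chains only is a stricter reading the
descriptor definitions do not force.

Location class: mean K < 0.9 → In; mean K ∈ [0.9, 1.1] with minimum
heavy-atom distance to a partner chain ≤ 8 Å → Near; otherwise Out.
The In/Near boundary at 0.9 rather than 1.0 absorbs quadrature noise;
the proximity rule disambiguates K ≈ 1 peptides that graze the
interface from those far away. The surface flag marks peptides whose
isolated-chain SASA reaches 20% of a 100 Å²-per-residue reference
exposure. Aggregation over complexes reports mean ± population sd and
"in-complex/screened" structure counts.

Toy complexes: chain A is an extended CA-only trace (3.8 Å spacing,
alanine flanks around a seeded random peptide that avoids flank and
cage residue types, so matches are unique); chain B is a glycine CA
tube (1.8 Å point spacing — sealed against the 1.4 Å probe) around the
peptide span whose radius is bisected until the achieved SASA
occlusion matches the requested burial fraction within 0.02;
unreachable requests are rejected. Ideal geometry, no side chains:
adequacy is judged via SASA only, not chemistry.

## Validation experiment sizes

Chosen as the package's own desk-scale defaults: null calibration — 20
cohorts of 500 proteins, 25 samples/group, full QC + DEP path;
summarised by the median KS p over seeds (the per-seed KS p of a
calibrated caller is itself uniform, so a per-seed floor would fail a
perfect caller occasionally by construction). Effect recovery — 12
cohorts of 650 proteins with {±1.5, ±2, ±4} injected into abundant
proteins, three replicates per magnitude/sign/group; recovery is the
per-magnitude mean of recovered |fCh|; recall is measured on effects
at magnitudes ≥ 2, which sit clearly above the |fCh| > 1.5 cut (an
effect injected exactly at the cut cannot systematically appear in the
DEP table under a strict inequality). Segmentation — 20 cohorts of 300
proteins with 12 modest effects (|FC| 1.3–1.5) in abundant proteins,
the regime producing overlapping profiles with ~70–80% CV accuracy,
against a label-permutation null on the same data. Oracle equivalence
and toy structural validation are deterministic small fixtures.

## Known limitations

* The OLS imputation is a single-regressor model; it cannot recover
  censoring-induced tail values and shrinks them toward the protein
  mean.
* The literal sPLS-DA configuration of the original MixOmics runs
  (keepX, scaling variant) is not recorded in the study methods;
  defaults here are stated above and logged in run metadata.
* Structural descriptors depend on convention choices (radii, cutoffs,
  counting scope) that the source methods leave open; printed-value
  reproduction on deposited complexes therefore validates the engine
  jointly with those conventions, and requires the PDB files locally.
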