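# Methods

## Scope and data model

The package computes with *compositions*, not structures: a glycan is a
count vector over five residue classes (Hex, HexNAc, Fuc, ethyl-esterified
NeuAc = α2,6, lactonized NeuAc = α2,3). Branch isomers, linkage positions
and bisecting GlcNAc are out of scope — composition-level proxies are
documented as such wherever they stand in for structural calls (notably the
sialyl-Lewis-x proxy and the antennarity ambiguity classes). Only singly
sodiated, free-reducing-end ions are modelled; protonated or multiply
charged adducts are not.

## Mass arithmetic

Residue masses are monoisotopic and derived from elemental formulas at
run time (atomic masses via pyteomics), never hard-coded: Hex C6H10O5
(162.0528), HexNAc C8H13NO5 (203.0794), Fuc C6H10O4 (146.0579), ethyl
ester NeuAc C13H21NO8 (319.1267), lactone NeuAc C11H15NO7 (273.0849).
The sodium cation mass subtracts one electron mass from the Na atomic
mass. Isotopologue patterns are aggregated (nucleon-count) distributions of
the full sodiated elemental formula, computed by per-element polynomial
convolution with binary exponentiation and truncation; they are exact for
the aggregated distribution up to the truncation length and are verified in
the tests against an independent symbolic (sympy) polynomial expansion.

## Composition enumeration

Enumeration is exhaustive over inclusive per-residue bounds (defaults:
H 0–12, N 2–10, F 0–5, E 0–4, L 0–4), pre-tabulated and sorted by mass so a
ppm-window query is a binary search; the result is order-independent by
construction. The biosynthetic filter (on by default) requires the
chitobiose core (N ≥ 2), total sialic acids ≤ max(N − 2, 0) and F ≤ N. A
single "most probable" candidate per peak is chosen by smallest |ppm
error|, then fewest residues; the full candidate set is retained because
the trait calculus is deliberately multi-assignment.

## Synthetic spectra

The generator emulates a reflectron MALDI-TOF acquisition of a two-group
cohort with known ground truth. Choices, with rationale:

- **Replicate design**: 3 biological × 4 technical replicates per group —
  the standard cell-extract design the statistics module presumes.
- **Grid**: uniform 0.02 Da over m/z 1000–5000 (the acquisition window).
  This resolves 0.05 Da-sigma Gaussian peaks (the TOF-like default width)
  and keeps a full spectrum at ~200k points.
- **Envelopes**: every species places Gaussian peaks at its theoretical
  m/z + k·1.003355 (five isotopologues by default), with areas proportional
  to ground-truth fraction × isotopologue abundance; an optional constant
  or mass-linear ppm drift displaces all centers multiplicatively.
- **Noise**: additive white Gaussian noise (sigma 5 intensity units against
  an abundance scale of 10⁴ per unit fraction) over a slowly varying
  sinusoidal baseline (level 20), exercising background subtraction and
  S/N estimation without overwhelming minor species.
- **Replicate variability**: log-normal multiplicative factors (sigma 0.15)
  on species abundances, drawn once per *biological* replicate; technical
  replicates share them and differ only in noise draws. Sigma 0.15 puts the
  within-group biological SD of the derived-trait percentages near 2
  percentage points, matching the replicate scatter the statistics are
  designed around.
- **Seeding**: every random stream is derived from
  `SeedSequence([master_seed, group, bio, tech])`, so any single spectrum is
  reproducible in isolation and cohorts are deterministic per master seed.

The presets `ntc_like` and `knockdown_like` (19/20 species) encode a
complex-dominated control glycome (complex 46%, high-mannose 34%, hybrid
19%, paucimannosidic 1%) and a knockdown phenotype differing by programmed
trait shifts: complex +10 points, monofucosylation −8, multifucosylation
+5, α2,6-sialylation +6, with α2,3-sialylation left approximately flat.
All preset species were chosen to be univocal at 20 ppm under the default
bounds and mutually separated in mass, so recovered trait tables equal the
programmed ones in the noise-free limit; real spectra additionally contain
non-univocal signals, matrix clusters and mass-dependent resolution, none
of which the generator models — passing recovery tests therefore validate
the computation, not instrument behaviour.

## Spectrum processing

Apexes are local maxima above a robust global threshold (median + 5·MAD),
refined by 3-point parabolic interpolation (sub-0.001 Da accuracy on
noise-free Gaussians, removing the ±¼-grid-step quantization that would
otherwise dominate ppm errors). A monoisotopic "chain head" is an apex with
no apex one isotope spacing below it whose height is at least 0.3× its own —
the height condition keeps a species from being swallowed by the faint
envelope tail of a near-coincident lighter species, while true isotopologue
ratios in the working window never fall below that factor going backwards.

Internal recalibration matches calibrant glycans of unique composition to
apexes within a 50 ppm pre-tolerance (≥ 3 required) and fits the drift by
least squares on ppm residuals; the constant model is the default, the
linear-in-m/z model is available by configuration. Corrections are applied
to peak m/z values, not the raw grid.

Per signal, the background is the local median (noise: 1.4826·MAD) in a ±7
Da annulus excluding all chain windows; areas are trapezoidal integrals of
the baseline-subtracted intensity over ±0.15 Da windows at each of the
first four isotopologues. The summed envelope area is divided by the
theoretical pattern mass contained in those four isotopologues, so areas
estimate *total* species signal without a truncation bias that would
otherwise grow with mass. The isotopic QC statistic is the cosine
similarity between observed and theoretical envelope fractions over four
isotopologues — a symmetric, [0, 1]-bounded stand-in for the (undocumented)
legacy score, interpreted as "keep iff ≥ 0.95". S/N is strict (> 2), the
ppm window inclusive (≤ 20). TIC normalization runs per spectrum after QC.

## Trait calculus

Classification thresholds are configuration, not code (`TraitRules`,
YAML-serializable). Defaults: paucimannosidic = N 2, H ≤ 3, no sialic acid;
high-mannose = N 2, H 5–9, no fucose or sialic acid; N 3 with H ≥ 5 reads
hybrid, otherwise complex; N ≥ 4 is complex. H:N classes compare raw
counts. Antennarity uses A = min(N − 2, 4); compositions meeting H > 7 and
N > 6 are reported as tetra-/poly- (LacNAc-repeat territory); otherwise a
composition with H ≥ A + 2 and A ≥ 3 also receives the adjacent-lower
label, producing the di-/tri- and tri-/tetra- ambiguity groups (the rule is
not applied below three antennas: a fully galactosylated diantennary
glycan is diantennary, full stop). Aggregation sums each peak's percentage
into every group any candidate belongs to; antennarity rows use the exact
label-set semantics (singleton → pure row, adjacent pair → intermediate
row, wider unions → every contained adjacent pair, or singleton rows when
none applies). Mixed sialylation is non-exclusive with the single-linkage
rows.

## Statistics

Technical replicates are averaged (mean) within biological replicates
before any testing; with 3 extracts per group the t-tests run at 4 degrees
of freedom, and technical replicates never enter them directly (no
pseudo-replication). The default test is the classical pooled-variance
Student's t (Welch by option); no multiple-testing correction is applied by
default since per-trait significance flags are the reporting convention
(`*` p ≤ 0.05, `**` p ≤ 0.01, boundary values inclusive). The outlier
screen operates on per-spectrum normalized signal percentages (absent
signals filled with 0), mean-centered PCA, T² on the first two component
scores against the critical value p(n−1)(n+1)/(n(n−p)) · F₀.₉₅(p, n−p);
for in-sample points this is conservative (the attainable in-sample T² is
bounded by (n−1)²/n), so clean cohorts are rarely trimmed. Cross-validated
PCA quality metrics (R2X/Q2) are not reproduced.

## SILAC arithmetic

Correction precedes aggregation: each peptide ratio is divided by
(1 − p)^n before the protein median is taken (default p = 0.077). The
median runs over all quantified peptides of a protein, unique or not; the
identification filter (≥ 2 unique peptides) gates which proteins are
reported at all. Selection is strict |log2 FC| > 1 — both up- and
down-regulated proteins qualify. The module never produces p-values:
without replicates, flags are the honest output.

## Numerical and degenerate-input conventions

Empty compositions are rejected at construction; enumeration of a mass
below any valid glycan returns an empty set (not an error); a flat spectrum
integrates to area 0 with S/N 0; a noise-free peak has S/N = ∞ and passes
the gate; zero variance in both groups with equal means yields p = 1;
QC-rejected peaks keep NaN percentages and are excluded from aggregation;
all randomness flows from explicit seeds and results are
platform-independent at 1e-9 on stored intensities.

## Known limitations

- Composition-level assignment cannot separate isomers; the sLex and
  antennarity outputs are proxies and labelled as such.
- The synthetic instrument model omits matrix clusters, detector
  saturation, mass-dependent resolution and peak asymmetry.
- The cosine isotopic-fit score is a documented stand-in for an
  unspecified legacy metric; its 0.95 threshold was kept as given.
- Reference narrative values that do not survive arithmetic (a one-ulp
  rounding slip in one printed mass; one fragment-mass typo) are treated as
  printing artifacts, with the computed values used throughout.
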