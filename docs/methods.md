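# Methods

## Background and model

`dilac` implements differential isotope labelling by amino acids (DILAC): a
proteomics computation that detects metabolic producer/consumer
subpopulations of one amino acid inside an isogenic cell population, and
deconvolutes the two subpopulations' proteomes from bulk measurements.

Cells grown on fully ¹³C-labelled glucose with an unlabelled supplement of
the target amino acid (lysine throughout the defaults) incorporate heavy
residues wherever they synthesize and light residues wherever they import.
For a peptide with *n* target residues, a *homogeneous* population — every
cell importing each molecule independently with probability *P* — produces
labelling states whose abundances follow a Bernoulli/binomial law:

r_k = C(n, k) · P^k · (1 − P)^(n−k),  k = 0 … n imported sites.

*P* is estimated from observed state fractions as the mean number of
imported sites divided by *n* (for n = 2:
P = (0·producer + 1·mixed + 2·consumer)/2). Distinct producer and consumer
subpopulations instead put all mass on the fully heavy (k = 0) and fully
light (k = n) states, so the mixed states are depleted. The detection
statistic is the **depletion ratio** expected-mixed / observed-mixed; a
configurable verdict threshold (default 2.0) and an optional chi-square
goodness-of-fit (df = n − 1, requiring a user-supplied effective count m,
since fractions alone carry no sample size) make the qualitative call
reproducible. An observed mixed fraction of exactly zero is reported as an
infinite ratio with a flag, not an exception.

## Isotope mass model

Residue elemental compositions ship as a versioned plain-text table
(`data/residue_compositions.tsv`); the ¹³C−¹²C shift is fixed at
1.0033548378 Da. A `LabelScheme` names the variable target residue and the
set of fixed-labelled residues (all other standard residues by default).
Species masses are the unlabelled monoisotopic mass plus shift × labelled
carbon counts; patterns are per-site boolean vectors enumerated
lexicographically (2ⁿ states). Fragment conventions: neutral y = residues +
water, neutral b = residues; singly protonated m/z = (neutral + z·proton)/z,
ordinals 1-based (y from the C terminus). Nominal m/z (round half away from
zero) is used only for MRM-style worked examples such as free lysine
147→84 / 153→89, where the product ion is the five-carbon C₅H₁₀N⁺ cation.
Carbamidomethylation and other derivatization carbons are never labelled
(labels come from biosynthesis); modified sequences beyond stripped
sequences are out of scope.

## Peptide selection

gluC cleaves after E only (a flag adds D); trypsin after K/R with
"not before proline" suppression off by default (flag provided). At zero
missed cleavages the peptides partition the protein exactly; missed-cleavage
variants concatenate up to the configured number of consecutive segments.
Candidates keep exactly *n* target residues (default 2) and no forbidden
residues (default C, M). Proteotypicity is exact substring counting across
the FASTA (I/L treated as distinct). The geometry score,
separation/(L−1) + 1 − dist(last site, C terminus)/(L−1), is a declared
surrogate ranking — only its ordering is meaningful; measured abundance and
identification-consistency criteria require instrument data and are left to
the user as external ranking inputs.

## Labelling-state quantification

Only diagnostic fragments (covering exactly one target site) are used: their
mass is unique to one precursor labelling state and resolves the two
isobaric 1-of-2 mixed states. Fragments are ranked within each sample by
total area (average ranks on ties), ordered by mean rank across all samples
(cutoff ties broken lexicographically), and the top 3 kept per peptide.
State fractions are computed per fragment first, then averaged unweighted
across fragments, then peptides, then replicates; the s.d. is reported at
the final (replicate) level. Missing state rows default to zero area with a
warning ("drop fragment" is configurable); all-zero fragments are dropped,
and a peptide set with nothing left raises an unquantifiable error. The
precursor (MS1) level uses the same chain over the n + 1 mass states with
the mixed components inherently merged.

## Proteome deconvolution

Report rows must be proteotypic with exactly one target residue at the C
terminus and Quantity.Quality strictly above 0.7. Sample QC excludes runs
with pair counts below 0.5× the cohort median or |log2 median ratio| more
than 1.0 from the cohort median (strict inequalities; boundary samples are
kept). Pairs need exactly one heavy and one light row per
(run, sequence, charge); duplicates are dropped as ambiguous, zero/negative
quantities excluded rather than imputed. Ratios are divided by the
per-sample median and log2-transformed; precursors seen in ≥3 samples get a
two-sided one-sample t-test against 0, BH-corrected once over the whole
tested set (significant: adjusted p < 0.05; zero variance with nonzero mean
reports p = 0 with a degenerate flag). A gene is a hit iff at least one
precursor is significant, |mean of per-precursor median log2 FC| > 0.75 and
all precursor medians share one sign.

## Library relabelling

Long-format (one row per fragment, OpenSWATH-style) TSV libraries are
filtered to charge {2, 3} and length 7–30 (inclusive), each precursor
expanded into heavy- and light-target variants, all m/z recomputed from the
mass model and retention-time columns passed through unchanged. Fragments
are excluded unless they cover exactly one target site — for C-terminal-K
tryptic peptides exactly "b excluded, y kept", but the general rule also
handles internal-site peptides. Modified sequences use six-decimal
mass-delta brackets (`K[+6.020129]`), bit-stable. A scheme with no labels is
the identity on retained entries.

## Synthetic data

The generator emulates the study conditions, not instrument physics. Each
cell draws an import probability from a population model — homogeneous point
mass, two-point producer/consumer (import probability 0/1: producers build
from labelled glucose, hence site-heavy), or Beta-mixture components for
gradual transitions — and a signal weight equal to its subpopulation's
protein synthesis rate, reproducing the documented bias between label-share
and cell-count fractions. Peptide molecules label sites independently;
aggregate pattern fractions are the rate-weighted per-cell binomials,
optionally followed by a multinomial draw of observed molecules.

Transition reports emit every y/b ion from ordinal 3 to length − 2
(the common extraction range), including non-diagnostic fragments the
pipeline must ignore; fragment response factors are drawn once per fragment
(log-normal, σ = 0.5) so top-3 ranking is nontrivial, and areas get
per-row log-normal noise (default σ = 0.2). DIA reports model a
two-subpopulation colony with per-gene producer-vs-consumer log2 fold
changes applied symmetrically (×2^(fc/2) / ×2^(−fc/2)), per-run global scale
factors, a configurable fraction of low-quality rows and decoy rows
(non-proteotypic, internal-K, orphan-heavy) that must never survive the
filters. Defaults — 6 replicates, σ = 0.2 noise, a 60-gene panel (40 null,
10 at ±0.3, 10 at ±1.8) with 3 peptides each — mirror the six-colony study
design. All randomness flows from the config seed; identical configs give
byte-identical files. What the simulator does **not** emulate: chromatogram
shapes, interference, missingness correlated with abundance, retention-time
drift — so passing recovery tests demonstrate correctness of the
computation, not robustness to every property of instrument data.

## Numerical choices

- Binomial pmf evaluated from its defining product form (exact at p = 0/1
  and stable for subnormal p).
- State fractions must sum to 1 within 1e−6; profile invariants hold to
  1e−9 internally.
- Rank ties: average within samples, lexicographic at the cutoff.
- Recovery tests use n_cells 300–10⁴, 20 seeds at σ = 0.2, and the 60-gene
  DIA panel; these sizes keep every law-of-large-numbers check comfortably
  inside its stated tolerance (3 s.e., 5%, sensitivity ≥ 0.9).

## Known limitations

- Heterogeneity detection is qualitative for gradual (Beta-distributed)
  populations; no parametric mixture deconvolution is attempted.
- Subpopulation size estimates are biased by synthesis-rate differences by
  construction; the simulator exposes the bias, the estimator does not
  correct it.
- No error model beyond replicate s.d. is propagated into the verdict.
- The DIA simulator is limited to two-component populations.
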