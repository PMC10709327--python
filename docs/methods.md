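# Methods

## Candidate enumeration

A capped-peptide candidate is read directly off the precursor sequence: an
amidation site is a G[K/R]R tripeptide (glycine amide donor followed by a
dibasic convertase site), and every glutamine whose distance to the motif
glycine gives a candidate length of 2–20 residues (counting the Gln that
becomes pyroGlu, through the residue immediately preceding the glycine)
yields one candidate. All qualifying glutamines are enumerated per motif,
including glutamines inside another candidate's span — so the tachykinin
context `…PQQFFGLM·GKR…` yields both the 6-mer and the 7-mer. The length-1
candidate (a bare pGlu-NH2) is excluded as chemically degenerate; the
20-residue cap reflects the practical upper limit for reliable solid-phase
synthesis of authentic standards, which the targeted workflow requires.
Candidates containing ambiguity letters (B, Z, X, U, O) are dropped because
no unique mass can be assigned. Candidates overlapping an annotated signal
peptide are kept by default — real capped peptides can begin only a few
residues past the signal-peptide cleavage site — with an opt-in filter.
Identical core sequences arising at several positions are all retained, with
distinct coordinates and a `duplicate_core` flag, leaving deduplication to
the caller.

The predictor is verified two ways: exact equivalence with an independent
brute-force enumeration over all (Q, motif) windows on random sequences, and
exact recovery (no false positives) on synthetic proteomes whose backgrounds
are rejection-sampled to contain no unplanned candidates.

## Mass-spectrometry chemistry

Monoisotopic residue masses and the proton/water/ammonia constants are
hard-coded in `cappedpep.constants`. Modifications are additive deltas:
pyroGlu-from-Gln −17.0265491 Da, C-terminal amide −0.9840156 Da,
carbamidomethyl-Cys +57.0214637 Da (off by default in mass calculations,
available because peptidomics samples are iodoacetamide-alkylated). The two
caps sum to exactly −H₂O, so a fully capped peptide's neutral mass equals
its bare residue-mass sum; this cancellation identity, and b/y
complementarity (b_i + y_{n−i} − 2·proton = M), are asserted to 1e-6 and
1e-4 Da respectively. Only b/y series at charges 1–2 are produced, matching
triple-quadrupole practice; a/x/c/z series, isotope envelopes and average
masses are out of scope. For pGlu-FFGLM-NH2 the computed [M+H]+ is
724.3487, within 20 ppm of the extracted-ion value 724.341 that a QTOF
prints for the real peak; the theoretical value is treated as canonical.

Default MRM transition choice: with a reference MS/MS spectrum, the
theoretical b/y ion matching the tallest spectrum peak (0.5 Da window);
without one, the highest-m/z b/y ion above a 200 Da floor (low-mass
products sit in the noisy immonium region). Dipeptide-class candidates with
no fragment above the floor are flagged rather than given a transition.

## Targeted detection

MS1 tier: a feature matches when |Δm/z| ≤ 20 ppm and |ΔRT| ≤ 1 min against
the authentic standard; ties go to smaller ppm error, then larger area.
Matching is monotone in both tolerances.

MRM tier: the trace's peak height is estimated as the amplitude of a
least-squares fit of a Gaussian elution template (default width σ = 0.15
min) to the baseline-subtracted trace, maximized over apex positions in the
peak window. A raw point-wise maximum would be upward-biased by roughly two
baseline-noise sigmas at typical sampling density, which would let
noise-only traces cross small thresholds; the matched-filter amplitude is
unbiased for a true Gaussian peak and has sub-sigma noise. The noise scale
is 1.4826 × the median absolute deviation of a disjoint off-peak window
(the Gaussian-consistent robust sigma), the baseline its median. A peptide
validates when S/N > 2.5 and the fitted apex lies within ±0.2 min of the
standard's retention time. A zero noise scale yields S/N = +inf with the
validation still requiring a positive height and co-elution. Instrument
vendors define S/N in proprietary ways; only threshold behavior, not
absolute S/N values, is contractual here.

MS/MS tier: count of theoretical b/y ions with a spectrum peak within
0.5 Da; one matched daughter suffices for detection.

Quantification: OLS of area on concentration over ≥ 3 calibration levels;
back-calculated concentrations are (area − intercept)/slope, negative
values clipped to zero with a flag; non-positive slopes are an error.

## Downstream statistics

Composition: each peptide contributes its own residue-frequency vector;
groups are compared per residue with a two-sided, equal-variance two-sample
t-test (matching standard practice for such comparisons). When both groups
are constant the test is degenerate: p is reported as 1 (equal means) or 0
(different means) with a flag, avoiding an arbitrary epsilon variance.
No multiple-testing correction is applied by default; Benjamini–Hochberg is
available.

Flanking profiles: residue frequencies at offsets −k…+k around the pyroGlu
(N) or the final amidated residue (C), each column normalized over the
residues actually observed there. For the C terminus, +1 is the motif
glycine under the default precursor convention; an alternative convention
counts offsets past the G[K/R]R motif instead, since heatmaps of this kind
are ambiguous about whether "downstream" includes the motif.

Fold changes: mean_b/mean_a per peptide with a two-sided t-test; zero
denominators flag an infinite fold change; log2 fold changes are reported
alongside.

Expression matrices: replicate columns averaged per tissue; each gene row
scaled to sum 1 (relative expression), log10-transformed, then z-scored
with the sample (n−1) standard deviation; rows with non-positive values or
zero variance are flagged and excluded. Rows and columns are ordered by
complete-linkage Euclidean hierarchical clustering.

## Curve fits

Dose-response: four-parameter logistic
`bottom + (top−bottom)/(1+(ec50/dose)^hill)`, parameterized on log10(dose)
for conditioning, fitted by Levenberg–Marquardt from a deterministic grid
of (EC50, hill) starts; the best residual sum of squares wins and the
result is canonicalized so top ≥ bottom. Requires ≥ 5 dose levels spanning
≥ 2 log units. The fit is scale-equivariant: rescaling responses rescales
the asymptotes and leaves EC50/hill unchanged.

Decay: A·exp(−kt) fitted on the raw scale (so late near-zero points are
honored), initialized from a log-linear regression over the positive
observations; half-life t½ = ln 2 / k. Exact exponential data are recovered
to optimizer precision.

## Cross-species comparison

Exact conservation is string equality of core sequences. The guide tree
uses Needleman–Wunsch global alignment (match +1, mismatch 0, gap −1) with
distance 1 − matches/alignment-length, then average-linkage agglomerative
clustering, serialized as Newick. Inputs are sorted lexicographically
before clustering so reruns are bit-identical. This is a deliberately
simple grouping device, not a progressive multiple alignment: no
substitution matrix, no bootstrap, and no claim that its topology
reproduces a Clustal-style phylotree beyond grouping close homologs.

## Synthetic data: what it emulates and what it does not

`make_proteome` plants compliant (Q, motif) pairs at recorded coordinates
in rejection-sampled backgrounds guaranteed free of accidental candidates,
plus three decoy classes (Q at distance 21, GKK near-motif, ambiguous-X
core) that must never be predicted. Background composition is uniform over
the 20 residues; real proteomes are not uniform, so planted counts are
exact here in a way real data never is.

`make_ms1_and_traces` emits features at theoretical m/z with Gaussian ppm
jitter (σ = 3 ppm, so 20 ppm is a 6.7σ window), +25 ppm decoy features,
retention times uniform over 5–30 min, areas on a linear response
(1500 area units per nM) over a 0.1–100 nM log-uniform concentration
range — the span observed for circulating signaling peptides — and
Gaussian elution peaks (σ = 0.15 min, 0.01 min sampling) whose apex height
is the requested multiple of the baseline noise sigma. It does not emulate
chromatographic tailing, isotope envelopes, co-eluting interferences or
matrix effects, so passing closure tests demonstrates the detection logic,
not robustness to real-matrix artifacts.

`make_quant_experiment` draws log-normal noise (mean-corrected, so group
means are unbiased) around condition means with planted fold changes;
default recovery checks use 84-fold and 0.42-fold effects at 5% CV with
n = 3 per group, the magnitudes and group sizes typical of the perturbation
panels this workflow is applied to. `make_pharm_data` generates 4PL curves
(default EC50 0.7 nM, hill 1, 8 half-log dose levels) and decay series
(default t½ 17.1 min at 0/20/40/60 min).

All generators are `numpy.random.default_rng`-seeded and bit-reproducible.

## Problem sizes

The property suites use 1,000 random sequences (length ≤ 500) for
predictor/brute-force equivalence, 100 random peptides for the chemistry
identities, 100 simulations for noisy-fit medians, and 1,000 null
replicates (n = 50 per group) for the composition-test calibration — sizes
at which every targeted effect is measured with comfortable margin while
the whole suite runs in well under a minute per file.

## Known limitations

- The published prediction counts on the curated mouse/human secretomes can
  only be recomputed with those curated lists present under `data/`; they
  are journal supplementary files and are not redistributed.
- Vendor raw files (.d/.raw) are not parsed; detection operates on open
  delimited feature/trace tables.
- Collision energies are not optimized and retention times not predicted;
  transition lists carry structure, not acquisition tuning.
- The composition t-test treats per-peptide frequencies as approximately
  normal; for very short peptides and rare residues the test is
  conservative/discrete, which the null-calibration test bounds but does
  not eliminate.
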