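# Methods

## Scope and data model

The package analyzes two-visit (baseline and ~2-year follow-up) volume
tables for 38 hippocampal subfield regions — 19 per hemisphere, with CA1,
CA3, CA4, dentate gyrus, molecular layer, presubiculum and subiculum split
into head/body segments and parasubiculum, fimbria, HATA, hippocampal tail
and hippocampal fissure kept whole — together with MMSE scores and four
adjustment covariates (baseline age in years, sex, education band,
APOE ε4 allele count).  The canonical region roster fixes row/column order
in every table and matrix; labels render as e.g. `"CA1 head L"` and parse
back losslessly.

MRI acquisition and segmentation are out of scope: the pipeline consumes
volume tables (mm³), not images.

## Synthetic cohort generator

Real subfield tables from clinical cohorts are access-restricted, so the
generator is first-class, tested code that defines the study conditions
for every downstream stage.

**Demographics.** Age ~ N(75.1, 7.17²) years; sex ~ Bernoulli(0.3953)
(1 = female); APOE ε4 allele count ∈ {2, 1, 0} with probabilities
(0.1589, 0.4768, 0.3643); education band ∈ {≤9, 10–12, 13–16, >16 years},
encoded ordinally 0–3, with probabilities (0.0155, 0.1318, 0.4651,
0.3876).  Education is generated and adjusted for as the ordinal band, not
years, because band frequencies are what converting-cohort demographics
tables report; the smallest band has ~1.5 % mass, which would make dummy
coding unstable at n = 258.  APOE enters as allele dose 0/1/2 rather than
a carrier binary; dose is the stronger-risk coding and degrades gracefully
to carrier status if users re-code.

**Volumes.** Baseline volumes are log-normal with per-subfield means
(order-of-magnitude plausible FreeSurfer-style values, 55–550 mm³,
config-overridable — per-subfield baseline dispersions are not published
for this setting, hence a single coefficient of variation
`baseline_volume_cv = 0.15`).  Log-normality guarantees positivity.

**Atrophy.** Percentage change for subject s, subfield j:

    change[s, j] = atrophy_means[j] + loadings[j, :] · f_s + ε[s, j]

with f_s ~ N(0, I) latent factors and ε ~ N(0, noise_sd²), noise_sd = 2 %.
Default per-subfield means average exactly −6.35 % on the left and −5.47 %
on the right hemisphere, with the worst atrophy in the left fimbria
(−9.11 %), left presubiculum head (−7.99 %), left subiculum head
(−7.93 %), and CA3 body bilaterally (≈ −7 %).  The default loading matrix
has four factors: a global factor (2.2 % per SD) on every subfield, one
factor per hemisphere (1.4 %), and a block factor (2.5 %) over the
CA1–CA3–CA4–dentate gyrus axis, emulating the strongly covarying
trisynaptic-circuit block seen in subfield co-atrophy data.  The fimbria
(×0.1) and hippocampal fissure (×0.45) load only weakly on the shared
factors: the fimbria is a white-matter bundle that atrophies severely yet
stays weakly integrated in covariance networks, and the fissure is a CSF
space rather than tissue.  A configuration is rejected if any subfield's
mean change minus six change-SDs crosses −100 %, which would imply
non-positive follow-up volumes.

**Cognition.** Baseline MMSE ~ N(26.40, 1.93²), rounded and clipped to the
0–30 score range.  Percentage MMSE decline is coupled to the first
(global) atrophy factor with weight `cognition_coupling = 4` % per factor
SD, so greater atrophy co-occurs with greater cognitive decline and
subfield–cognition correlations come out positive at realistic magnitudes
(r ≈ 0.15–0.25 at n = 258).  The configured decline moments (−12.9 %,
SD 13.8 %) are targets for the **realized** bounded integer score: because
the MMSE ceiling at 30 truncates improvements, a naive normal draw with
those parameters would realize an SD of ≈ 13.34 and a mean of ≈ −13.16.
The generator therefore solves for the latent normal parameters by
deterministic moment matching (exact discrete-score moments over the
integer score grid, `scipy.optimize.root`), so that the simulated cohort's
realized decline mean/SD recover the configured values.  Follow-up MMSE is
`round(baseline · (1 + decline/100))` clipped to [0, 30].

All randomness flows through one `numpy.random.Generator` seeded once per
cohort; no global state.  Identical config + seed reproduces bit-identical
cohorts.

**What the generator does not emulate.** No attrition or missing visits,
no segmentation error or site effects, no covariate–atrophy dependence
(age, sex, APOE do not modulate atrophy rates), and Gaussian factor
structure only.  Passing tests therefore validate the *statistical
machinery* under a known truthful model; they say nothing about any real
cohort's effect sizes.

## Volumetrics

Changes use the per-subject ratio convention
`100·(follow − base)/base`; the per-subfield "mean change %" is the mean
of per-subject ratios (consistent with the per-subject change definition),
not the ratio of mean volumes — the two differ when baseline volume and
change correlate.  Paired t-tests use `t = mean(d)/(sd(d)/√n)` with the
n−1-denominator SD and two-sided p from the t distribution (df = n−1);
n < 2 or zero-variance differences raise a degenerate-input error rather
than returning a silent p = 0.  Hemispheric asymmetry is the paired t-test
of per-subject unweighted means over the 19 left vs. 19 right subfield
changes (a volume-weighted variant is available via the `weights`
argument).  Aggregate regions (whole hippocampus, whole head/body per
hemisphere) are sums of constituent *tissue* volumes computed before the
change score; the hippocampal fissure is excluded from aggregates as CSF.
Aggregates never enter the network.  P-values are uncorrected by default
(matching the per-subfield reporting convention of the field);
Benjamini–Hochberg q-values are available behind a flag.

## Partial correlation and the covariance network

`partial_correlation(x, y, Z)` residualizes both variables on [1, Z] by
least squares and correlates the residuals; significance uses
`t = r√(df/(1−r²))`, df = n − k − 2, two-sided.  With Z empty this is the
plain Pearson correlation (df = n − 2).  Exact collinearity is detected
via a relative residual-variance floor (10⁻¹⁰ of the raw SD).  The
pairwise 38×38 matrix residualizes all columns in one least-squares solve
and correlates once; exact symmetry is enforced by mirroring the upper
triangle, and the test suite verifies entry-wise agreement with looped
single-pair calls at 10⁻¹².

Thresholding retains edge (i, j) iff p_ij < α (α = 1 keeps everything);
retained weights are the **signed** partial r.  Negative edges are kept —
nothing in the construction requires removing them — and a
`positive_only` flag restricts to positive co-atrophy if desired.
Strength-based computations downstream use |r|.  Per-edge uncorrected
p < 0.05 is the default, mirroring the significance-thresholding
construction; FDR mode exists but is off by default.

## Centrality

Degree is computed on the binary connection indicator regardless of stored
weights; maximum 37 in a 38-node simple graph (no self-loops).
Betweenness uses Brandes' dependency accumulation, unnormalized, endpoints
excluded, unordered pairs counted once; all equally-short paths are
credited fractionally (g_xiy/g_xy), never one arbitrary path.  Closeness
is (N−1)/Σl on connected graphs and the Wasserman–Faust generalization
(R_i/(N−1))·(R_i/Σ_reachable l) on disconnected ones, 0 for isolated
nodes.  Path metrics run on the binarized graph by default (each edge
length 1); weighted mode uses length 1/|r| so stronger co-atrophy is a
shorter path.  Binary is the default because the degree definition is
explicitly binary and the path-metric formulas are stated in unweighted
form; every report records the mode used.

Eigenvector centrality is the principal eigenvector of the binary (or
|r|) matrix, L1-normalized (ΣE_i = 1, matching the convention in which
the column totals ≈ 1 over the roster), computed by power iteration from
a uniform start to relative tolerance 10⁻¹².  Plain power iteration fails
on bipartite graphs (λ_min = −λ_max, e.g. a star), so the iteration runs
on A + I — valid because the Perron root of a non-negative symmetric
matrix dominates |λ_min|, and any positive shift breaks the tie — and λ
is reported as the Rayleigh quotient of A itself.  Disconnected input
triggers a warning listing components; the iterate then converges to the
dominant component's Perron vector (or a symmetric mix under exact
eigenvalue ties).

Consensus hubs: for each metric the top-k nodes (descending value, ties
broken by canonical label order, boundary ties reported explicitly); the
consensus set is the intersection of the four top-k sets.  On
near-complete graphs many nodes tie at the maximum, so the tie report —
not the ranked list alone — is the meaningful output.

## Numerical and I/O choices

Tolerances: symmetry and r-diagonal checks at 10⁻¹²; power iteration
10⁻¹² with a 10⁵ iteration cap (failure raises with the achieved
residual); brute-force oracle agreement asserted at 10⁻⁸ or better.
Weighted shortest-path tie detection uses exact float equality —
continuous random weights cannot produce accidental ties, and binary mode
(where ties are common) uses integer arithmetic.  CSV/TSV artifacts are
UTF-8, "." decimals, header mandatory, floats at 12 significant digits;
matrices are labeled on both axes; the manifest stores artifact paths
relative to the output directory so same-seed runs are byte-identical
wherever they land.  The run manifest (config, seed, version) suffices to
reproduce a run exactly.

Problem sizes used by the test suite — 500 oracle graphs of ≤ 8 nodes,
200-seed null calibrations at n = 258, 100-seed hub recovery, one
20 000-subject fidelity simulation — were chosen so the whole suite
completes in well under a minute per heavy check while keeping
Monte-Carlo error far below the asserted bounds.

## Known limitations

* The generator's co-atrophy is linear-Gaussian; heavy-tailed or nonlinear
  co-atrophy would require a different factor model.
* Covariates are generated independently of atrophy, so covariate
  adjustment in the default simulation removes essentially nothing; the
  adjustment machinery is instead validated by affine-invariance and
  planted-effect tests.
* The partial-correlation network is thresholded per-edge without
  multiplicity correction by default; with 703 tests this admits ~35
  false edges under the null at α = 0.05 (the FDR flag addresses this).
* No graphical-lasso-style sparsification, no bootstrap edge stability,
  no additional graph metrics (clustering, modularity), and no mixed
  models for more than two visits.
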