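# Methods

## The model

For an ordered amino-acid pair (x, y) the first-passage distribution
P_xy(L) is the probability that, starting from an occurrence of x, the
first occurrence of y in the scan direction lies exactly L residues away
(adjacent residues are L = 1).  Scanning toward the carboxyl terminus
(increasing sequence index) is direction C; toward the amino terminus is
direction N.  Passages are confined to single protein chains; an anchor
whose chain ends before any y appears is *censored* and kept in the
bookkeeping so that counts + censored = anchors for every pair.
Self-pairs follow the same rule — the anchor never counts as its own
target.

If residues were independent and identically distributed, P_xy(L) would
be geometric in L with success probability f_y, the proteome frequency
of the target: P(L) = f_y (1 − f_y)^(L−1), i.e. exponential decay with
decay constant λ_geo = −ln(1 − f_y), independent of the anchor x.  Real
proteomes are close to this regime, which motivates the empirical
background model: for each (x, y, direction) the log of the first-passage
count is fitted as a straight line in L, giving a fitted decay constant
λ_xy.  Correlated pairs show up as isolated separations whose observed
count deviates from that background.

The deviation statistic at separation L is

    q = ln(observed count / background-expected count),

the log amplitude of a peak above (or dip below) the background — a
signal-to-noise measure that is invariant under rescaling all counts
(normalization moves only the fit intercept).  Its z-score divides q by a
noise scale, and |z| ≥ 3 within one organism's proteome calls a peak.
Peaks recurring at the same (pair, L) in at least `min_genomes` organisms
of a study set are summarized across the study, and their per-organism
amplitudes are correlated with optimal growth temperature (OGT).

## Fitting choices

- **Window.** The fit uses L in [2, 49].  Above ~50 residues counts are
  dominated by finite-chain noise; L = 1 is excluded by default because
  nearest-neighbour composition effects are the strongest deviation from
  the smooth background.  Both bounds are configurable.
- **Raw counts, natural logs.** The fit regresses ln(count) on L.
  Zero-count bins are excluded rather than pseudocounted (ln 0 is
  undefined, and exclusion is unbiased at moderate counts).  All logs in
  the package are natural.
- **One sigma-clipping pass.** After a first OLS fit, bins deviating by
  more than `clip_sigma` (default 3) residual SDs are dropped and the fit
  is redone.  This keeps genuine peaks — the thing being searched for —
  from biasing their own background.  A fit needs at least 3 usable
  bins; otherwise the pair is flagged invalid and skipped downstream.
- **Residual SD.** `resid_sd` is sqrt(RSS / (n − 2)) on the retained
  bins, i.e. the regression residual SD with the two fitted parameters
  accounted for.
- **Peaks below the window** (e.g. L = 2, 3) are scored against the
  extrapolated fitted line, so short-range peaks are measured relative to
  the background established at larger separations.
- **Mean first-passage length** uses the discrete closed form
  ⟨L⟩ = 1 / (1 − e^(−λ)) — the mean of the geometric law whose per-step
  success probability is 1 − e^(−λ) — rather than the continuous 1/λ,
  because L is integer-valued.  It is undefined (flagged) when λ ≤ 0.

## Noise scale for z

The default noise scale is the fit's residual SD of log-counts
(`noise = "fit"`): the peak threshold is then literally "three standard
deviations from the exponential background".  Because Poisson noise on a
log scale is heteroscedastic — sd(ln N) ≈ 1/√N grows toward the
low-count end of the window — a single residual SD understates the tail
noise of low-count bins, and the |z| ≥ 3 call rate on null data is
around 9 per 1000 bins instead of the nominal 2.7.  The alternative
`noise = "poisson"` uses 1/√(observed) per bin and is calibrated to the
normal tail (measured ≈ 2.3 per 1000).  The default is kept because the
cross-organism recurrence filter (≥ 25 organisms at the same pair and
separation) removes non-reproducible calls regardless of the per-organism
rate; single-organism peak lists should be read with the Poisson scale in
mind.

## Statistics

- **Pearson correlations** carry a two-sided p-value from the Student's-t
  transform t = r√((n−2)/(1−r²)) with n − 2 df (scipy's `pearsonr`).
- **Spearman correlations** use mid-ranks on ties and a permutation
  p-value: exact enumeration of all n! permutations for n ≤ 8, otherwise
  a seeded Monte-Carlo with p = (1 + hits)/(1 + n_perm), n_perm = 10⁵ by
  default.  The asymptotic Spearman p is used nowhere.
- **Kruskal-Wallis** tests whether mean first-passage lengths group by
  the target amino acid (they should — λ is y-determined) and by the
  anchor (they should not).  Degenerate all-identical input returns
  H = 0, p = 1.  Each organism is tested separately; organisms are never
  pooled into one test.
- **Bonferroni cutoff** for the per-pair log-linearity screen is
  −ln(α / n_tests); with α = 0.05 over a 76-organism × 400-pair design it
  is 13.318.
- **Mean-length-vs-OGT sign convention:** a target that becomes more
  abundant at high OGT is reached faster, so its ⟨L⟩–OGT Spearman
  correlation is negative.

## Cross-organism aggregation

A peak summary records, per (pair, direction, sign), the modal
significant separation across organisms (majority vote, ties toward the
smaller L) and the number of organisms significant there.  The mean
amplitude q̄ averages, by default, over **all** organisms with a defined
q at that (pair, L) (`qbar_scope = "all"`); restricting to the organisms
where the peak is individually significant is the `"significant"`
option.  The `compare` CLI subcommand, which rebuilds summaries from peak
TSVs containing only significant calls, necessarily uses the latter.

## Synthetic study sets

The generator emulates exactly the statistical structure the pipeline
detects, and nothing else:

- Chains drawn iid from a 20-letter composition (default: typical
  proteome composition, ~1.4% cysteine to ~9.7% leucine).  Protein
  lengths are geometric with mean 350 residues and a floor of 30, the
  typical protein scale, so chain-end censoring is exercised.
- An optional linear OGT trend on chosen residue frequencies
  (renormalized, floored at 10⁻⁵), emulating composition shifts across
  habitats.
- Planted lag correlations: scanning each chain left to right, every
  occurrence of x overwrites the residue at i + Δ with y with probability
  ε.  The overwrite construction (rather than a Markov chain) localizes
  the correlation at exactly lag Δ, giving a clean single-peak ground
  truth whose expected amplitude is computable by a direct recount.
  Later overwrites win; overwrites that create new anchors (self-pairs)
  are themselves scanned.
- Study sets space pseudo-OGTs evenly over a range (default 5–100 °C)
  and evaluate effect strengths per organism's OGT; per-organism seeds
  are spawned from the study seed, so everything is reproducible.

What the generator does **not** emulate: codon usage, protein families
and domain repeats, phylogenetic covariance between organisms, and
secondary-structure periodicity.  Passing tests on synthetic data
therefore demonstrate the estimator's correctness and calibration, not
the biological claims one might draw from real proteomes.

### Finite chain length

Chain-end censoring thins the set of anchors that could still produce a
passage of length L, multiplying the expected counts by a slowly
decaying factor and inflating the fitted λ by roughly 1/(mean chain
length).  With 350-residue proteins this adds ≈ 0.003 per residue — a
few percent for common targets but ~15% of λ_geo for a 2%-frequency
target.  It is a property of the data (finite genes), not an estimator
bug; the closed-form agreement checks in the test-suite and acceptance
script therefore use 5000-residue chains, where the effect is well under
the tolerance, and real-data decay-length ratios for rare targets should
be interpreted with this bias in mind.

## Problem sizes

The simulation scales used by the tests and the acceptance script were
chosen as the smallest at which each estimate is stable: closed-form λ
agreement on one 10⁶-residue proteome; null calibration on 20 replicates
of 40 organisms × ~36 k residues; planted-effect recovery on 8 organisms
× ~700 k residues (large enough that the planted z dominates low-count
tail fluctuations); planted-trend recovery on 20 replicates of 40
organisms × ~88 k residues.

## Known limitations

- The fit-SD z is anti-conservative for low-count bins (see above).
- λ estimates for pairs involving rare anchors (W, C) are noisy in small
  proteomes; fits with fewer than 3 nonzero bins are flagged invalid.
- The background fit assumes a single exponential; stretched or
  multi-exponential decay (plausible in small, noisy genomes) is out of
  scope.
- Cross-organism correlations are not corrected for phylogenetic
  relatedness.
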