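# fpscan — first-passage statistics of proteome primary sequences

`fpscan` analyzes amino-acid correlations in protein primary sequences
through **first-passage distributions**: for every ordered pair (x, y),
the probability P_xy(L) that the first occurrence of amino acid y lies
exactly L residues away from an occurrence of x, scanning toward either
the N- or the C-terminus within single protein chains.

Across a proteome the log of P_xy(L) is very nearly linear in L — an
exponential background e^(−λ_xy L) whose decay constant depends on the
target y and barely on the anchor x.  Under fully independent residues
the background is the geometric law f_y (1 − f_y)^(L−1) with
λ_geo = −ln(1 − f_y).  `fpscan` fits the empirical background per pair
(OLS on log-counts over L ∈ [2, 49] with one sigma-clipping pass), then
scores every separation by the log amplitude above background,

    q = ln(observed / expected),   z = q / sd,

and calls peaks at |z| ≥ 3 within one organism.  Peaks that recur at the
same (pair, L) in many organisms of a study set are summarized, and
their per-organism amplitudes are correlated with optimal growth
temperature (OGT): Pearson r with a Student's-t p-value and Spearman ρ
with a seeded permutation p-value (exact enumeration for n ≤ 8).  The
approach targets the kind of environmentally dependent, discontiguous
correlations seen in thermophile proteomes — e.g. cysteine enrichment
three residues after a cysteine, or glutamic acid two residues after
leucine — without assuming residue independence in the background.

The package is aimed at comparative genomics / protein-evolution work:
it takes one protein multi-FASTA per organism plus a TSV of organism
metadata (id, name, OGT in °C, FASTA path), and also ships a synthetic
proteome generator (iid backgrounds, OGT-dependent compositions, planted
lag correlations) so the whole pipeline is testable end to end without
any sequence downloads.

## Worked example

Generate a synthetic 8-organism study in which a planted C→C correlation
at lag 3 grows linearly with pseudo-OGT (strength ε = 0.02 + 0.003·OGT),
then scan it:

```
fpscan synth --n-organisms 8 --ogt 5:100 --effect C,C,3,linear:0.02:0.003 \
       --n-proteins 300 --mean-length 350 --seed 17 --out-dir study
fpscan scan --metadata study/metadata.tsv --out-dir results \
       --min-genomes 6 --seed 17 --n-perm 20000
```

`results/pair_summary.tsv` then contains (both scan directions see the
same self-pair peak):

```
pair  x  y  direction  n_genomes  L  q_bar    sign
CC    C  C  C          7          3  2.60638  over
CC    C  C  N          7          3  2.60638  over
```

— the planted pair, significant in 7 of 8 organisms at separation L = 3,
with mean log amplitude q̄ ≈ 2.6 (a ~13-fold excess of first passages
over the exponential background).  `results/ogt_correlations.tsv` shows
the planted temperature dependence of the amplitude:

```
x  y  direction  L  sign  pearson_r  pearson_p    spearman_rho  spearman_p   n
C  C  C          3  over  0.946296   0.000371789  1             4.96032e-05  8
C  C  N          3  over  0.946296   0.000371789  1             4.96032e-05  8
```

i.e. q rises with OGT (r = 0.946, permutation Spearman p ≈ 5·10⁻⁵).
Per-organism TSVs (`<id>_counts.tsv`, `<id>_background.tsv`,
`<id>_peaks.tsv`) hold the raw first-passage counts, the fitted
backgrounds (λ, residual SD, linearity p-value, geometric-null ratio,
mean first-passage length), and the significant calls.  `fpscan plot`
renders log-count-vs-L figures with the fitted background overlaid and
OGT-vs-q scatters for every retained pair.

The same machinery is available as a library:

```python
from fpscan import (SyntheticSpec, PlantedEffect, generate_proteome,
                    count_first_passages, fit_background, score_deviation)

p = generate_proteome(SyntheticSpec(n_proteins=400, seed=13,
                                    planted_effects=[PlantedEffect("C", "C", 3, 0.3)]))
t = count_first_passages(p, "C", "C", "C")
call = score_deviation(t, fit_background(t), L=3)
print(round(call.q, 2), round(call.z, 1))   # 3.4 13.8
```

See `docs/methods.md` for the model, the fitting and noise-scale
choices, and what the synthetic generator does and does not emulate.

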