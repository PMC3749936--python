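# Methods

## Model

The package scores each protein-coding gene for intolerance to standing
functional variation. Per gene, X counts all qualifying coding
site-alleles in a cohort variant table (any effect class, any frequency)
and Y counts the common functional subset — missense, nonsense
(stop-gained/lost) and splice acceptor/donor site-alleles with minor
allele frequency strictly above ρ. X acts as a gene-specific proxy for
neutral mutational opportunity (length × mutability × coverage); the
genome-wide ordinary least squares fit of Y on X gives the expected
amount of common functional variation for that opportunity, and the
studentized residual is the score S. Negative S means common functional
alleles are under-represented in the gene, which is most naturally read
as purifying selection; positive S can reflect relaxed constraint or
frequency-promoting selection. The score is intentionally agnostic about
which force is at work.

Assumptions worth keeping in mind:

- A single genome-wide linear relationship between Y and X. The fit is
  unweighted (no statement of heteroscedasticity structure beyond the
  leverage correction built into studentization).
- Effect annotations, PolyPhen-2 predictions, allele frequencies and
  filter statuses are consumed as given, never recomputed.
- Only single-nucleotide substitutions count; indels are excluded as
  less reliably called.
- One record per site-allele: a multi-allelic site contributes one X
  (and possibly Y) count per alternate allele.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| ρ (`rho`) | 0.1 | percent MAF | common/rare threshold for Y; strictly `MAF > ρ` |
| `population` | ALL | — | which MAF column drives Y (combined, EA, AA) |
| `mode` | standard | — | `pp2` relabels benign-predicted missense as non-functional |
| `min_depth` | 10 | fold coverage | per-site mean depth for a site to count |
| `min_fraction` | 0.70 | fraction | covered share of the footprint for assessability |
| `splice_pad` | 2 | bp | exon widening so splice-site annotations fall inside |
| `studentization` | internal | — | `external` recomputes σ̂ excluding each gene |
| hot zone | x ≥ 0.95, y ≤ 0.25 | score / percentile÷100 | both boundaries inclusive |
| quartile p₀ | 0.38 | probability | intolerant-quartile share of covered bases; recomputable per dataset |

Studentization defaults to the internal form rᵢ/(σ̂√(1−hᵢᵢ)): it is the
standard leverage-aware scaling, matching the rationale that genes of
different burden have different residual variability. The external
(jackknife) form is available via configuration; the two are
rank-near-equivalent on exome-scale fits.

Percentiles use average-rank ties and ascend in S, so the minimum score
maps to the minimum percentile (100/N for a unique minimum). Group
summaries map a list's *mean score value* onto the empirical CDF of all
scored genes, not the mean of member percentiles — these differ whenever
the score distribution is skewed.

## Coordinates and file boundaries

Internally all intervals are 0-based half-open. BED stays 0-based;
EVS-style variant tables and VCF convert from/to 1-based at the reader/
writer. Splice pads are ordinary region sites and are therefore subject
to the coverage requirement like any other site (the alternative —
exempting pads — is not offered). A gene symbol mapping to several
chromosomes is rejected rather than silently merged, since a silent
union would corrupt both the footprint size and the tallies.

## Synthetic data: what it emulates, what it does not

`synthetic_data.simulate_exome` generates the statistical structure the
score assumes and nothing more: log-normal coding lengths (median
~1.4 kb, σ_log = 0.6 — the scale of real CCDS genes), Poisson variant
counts at 0.02 sites per coding base (roughly one variant site per 50 bp,
the density a ~6500-exome cohort shows), 70% functional effect
annotations (the observed missense+truncating : synonymous mix), and a
two-component MAF mixture in which 25% of sites are common at ρ = 0.1%.
Intolerant genes (10% of genes by default) have the common-probability
of their functional sites multiplied by `suppression` (default 0.2).
MAFs are *not* drawn from a realistic site-frequency spectrum, there is
no linkage, no mutation-rate heterogeneity beyond length, and subpopulation
MAFs are jittered copies of the combined value. A green recovery test
therefore establishes that the pipeline turns suppressed common
functional variation into low percentiles — not that any particular AUC
would be achieved on real cohorts, where annotation error, coverage
structure and selection regimes are richer.

`simulate_trios` plants, with `causal_hit_rate` (default 1.0 — one
causal event per affected proband, the single-causal-de-novo model the
hot-zone analysis targets), a damaging mutation (missense with
PolyPhen-2 ≥ 0.95, otherwise gene-disrupting) in a truth-intolerant gene
on top of background de novos drawn ∝ covered gene length with bimodal
background PolyPhen-2 scores.

## Numerical choices and degenerate inputs

- OLS is computed in closed form (centered sums); leverages as
  1/n + (xᵢ−x̄)²/Sxx. Tests pin both against an explicit hat-matrix
  oracle at 1e−10 and against statsmodels' influence measures.
- A zero-residual (perfectly collinear) fit raises a degenerate-fit
  error at studentization rather than emitting ±∞ scores; leverage 1
  raises an undefined-score error naming the gene.
- Genes with zero qualifying variants stay in the regression with
  X = Y = 0; dropping them would bias the fit toward high-burden genes.
- Logistic association under perfect separation returns a flagged result
  with a signed infinite slope instead of crashing.
- Mann-Whitney uses the exact null below 25 total observations when
  tie-free, otherwise the tie-corrected normal approximation with
  continuity correction.
- ROC ties take half weight (midrank convention); the DeLong variance
  uses the standard structural-components estimator, and its CI is
  clipped to [0, 1].
- Fisher's exact odds ratio is the sample cross-product estimate; a zero
  margin yields an `inf` flag with the p-value still defined.
- The exact binomial p is two-tailed in the minimum-likelihood sense
  (sum of outcome probabilities ≤ that of the observed count).
- Coverage intervals may overlap; per-site depth resolves to the
  maximum. Sites absent from the profile have depth 0.

## Design choices that were genuinely open

- Whether published scores used internal or external studentization is
  not documented; internal is the default and what tests pin.
- The PolyPhen-2 relabeling in `pp2` mode applies to both `missense` and
  `missense-near-splice` (it is a missense-specific filter; near-splice
  missense is still missense). Truncating and splice classes are never
  relabeled.
- Trio denominators count probands with at least one eligible mutation;
  probands with none never enter the proportions.
- Hot-zone boundaries are inclusive on both axes.
- Unknown effect strings are excluded with a warning rather than fatal,
  for robust batch processing.

## Known limitations

- The assessability rule uses per-site mean depth only; no base-quality
  or strand-bias modelling.
- No per-domain sub-gene scores, no site-frequency-spectrum elaboration,
  no integration of conservation scores.
- The published full-exome score table is not redistributed; the test
  that reproduces its printed disorder-list summaries requires the user
  to supply that table (see `tests/test_acceptance.py`).
- Logistic confidence intervals are Wald; profile-likelihood CIs are not
  implemented.
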