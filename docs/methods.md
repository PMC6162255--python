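# Methods

## Pipeline model

`mitoamt` treats a label-free LC-MS experiment as a collection of
per-run UMC feature tables: each row is one unique mass class with a
monoisotopic mass (Da), an elution coordinate (arbitrary scan units), a
summed component intensity, and an optional MS/MS-derived peptide
identity. The pipeline assumes the upstream steps — feature detection,
UMC clustering, mass refinement, database search — have already
happened; their outputs are its inputs.

### NET computation and calibration

Each run's elution axis is min-max rescaled to a normalized elution
time, NET = (t − t_min)/(t_max − t_min). Because chromatography drifts
between runs, each run is then calibrated onto a consensus scale with an
affine least-squares map fitted on the identified peptides the run
shares with the reference (≥ 3 anchors required), with one pass of
outlier rejection at |residual| > 3·sd followed by a refit; calibrated
values are clipped to [0, 1]. The affine two-parameter form is the
minimal model that absorbs both gradient-offset and gradient-stretch
drift; a piecewise fit was considered and rejected as underdetermined at
typical anchor counts. The master database build is a bounded two-pass
iteration: consensus medians from initially normalized NETs, per-run
calibration against them, then one recompile from calibrated NETs.
Runs that cannot be calibrated are retained uncalibrated and flagged.

Consensus coordinates per peptide are the arithmetic mean of observed
masses and the median of calibrated NETs; an even observation count
takes the midpoint of the central pair.

### AMT matching

An unidentified feature matches a database entry when
|10⁶·(m_obs − m_db)/m_db| ≤ 10 ppm and |NET_obs − NET_db| ≤ 0.025
(both tolerances configurable). The ppm denominator is the database
mass: the consensus is the reference quantity. Among in-box candidates
the winner minimizes the tolerance-scaled distance
√((Δppm/10)² + (ΔNET/0.025)²); two or more candidates set an
`ambiguous` flag, and a strict mode drops such matches instead. Matching
uses binary-search windowing on a mass-sorted index; its behavior is
defined by — and tested against — exhaustive pairwise search. Features
with a search-derived identity are never reassigned.

### Alignment, normalization, replicate collapse

Cell (peptide, run) of the alignment table is the sum of intensities of
every UMC carrying that peptide in that run (UMC intensity is itself a
component sum, so summation extends the same contract); absent pairs
are missing, never zero. Quantile normalization acts on run-level log2
intensities *before* replicate collapsing, since its purpose is to
remove per-run systematic variation. With missing cells, each column is
mapped through its empirical quantile ranks onto a shared reference
quantile function (the across-column mean of interpolated per-column
quantiles); on complete equal-depth data this reduces exactly to the
textbook order-statistic-mean procedure and is idempotent. Ties receive
the mean of the reference values they span. Technical replicates are
then averaged per subject on the log2 scale; a subject cell is missing
only when all replicates are.

### Differential expression

Peptides are filtered to those detected in strictly more than 50% of
subjects in each group whose protein keeps ≥ 2 distinct such peptides
(membership recomputed to a fixed point). Two statistics are computed
per peptide — pooled-variance Student t (the classical test is named,
so Welch is not used) and the log2-median ratio, both signed so that
positive means higher in the case group. Null distributions come from
balanced relabelings of subjects sampled without replacement from the
distinct non-identity assignments (exhaustive enumeration when there
are no more than the requested 1000); each statistic is recomputed for
every peptide under every relabeling and pooled across peptides and
permutations, which buys resolution below 1/B per peptide at the cost
of assuming approximately exchangeable peptide-level null scales after
quantile normalization. The adjusted p is
(1 + #{|null| ≥ |obs|})/(1 + N_null); infinite statistics (zero pooled
variance with unequal means) are excluded from the pooled null and
receive the floor p. The two adjusted p-values are combined with
signed-z Stouffer (two-sided reconstruction preserves direction while
accepting two-sided inputs) and converted to q-values with Storey's
method at λ = 0.5. Significance is conjunctive: q ≤ 0.1 AND
|log2 ratio| ≥ log2 1.5 — the fold criterion is two-sided because both
up- and downregulation are biologically expected. Proteins inherit DEP
status from any significant sibling; the protein log2 fold change is
the median over significant siblings (all siblings when none pass), and
conflicting significant signs yield an explicit `mixed` flag rather
than a silent vote.

### Enrichment and network

Term over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k); EASE mode decrements the overlap by one (floored at zero)
before the tail, penalizing single-protein overlaps. The universe
defaults to the proteins that passed peptide filtering — the measured
proteome, the standard background for proteomics enrichment — not the
genome. Enrichment significance is the conventional raw P ≤ 0.05; a
q-value column is emitted for information only. The network model seeds
on DEPs annotated to an enriched term, retains first neighbors that are
themselves DEPs or term-annotated, and keeps the induced edges with
source-database provenance; self-loops are dropped and duplicate edges
merged. Non-DEP, non-annotated interactors are excluded from the
displayed model.

## Synthetic cohorts

The generator emulates the targeted study conditions: 2 × 9 subjects ×
3 replicate runs (54 tables), peptide masses uniform on 700–4000 Da,
true NETs uniform on [0.02, 0.98], base log2 intensities N(22, 2²), and
a planted fraction of proteins with signed linear fold changes drawn
from [1.5, 4] shared by all sibling peptides. Per-feature mass error is
N(0, 3 ppm); elution is emitted in scan units through a run-specific
affine map (range 3000 scans, offset 500, gaussian perturbations of
slope 3% and intercept 2%) applied to trueNET plus
N(0, 0.005) jitter — the jitter enters inside the affine map so it
survives downstream renormalization. Identities attach with probability
0.104, the identification rate characteristic of undersampled
platforms. Detection follows a logistic curve in true log2 intensity
(midpoint 18.5, steepness 1.2), making missingness intensity-dependent
so the detection filter is actually exercised. Between-subject
biological variation N(0, 0.35²) is shared across a subject's
replicates; per-run technical noise is N(0, 0.25²). The subject-level
term is not part of the minimal field list for a noise model but is
required for the test's null to be non-degenerate once replicates are
averaged: without it, arbitrarily small planted effects would separate
the groups perfectly.

What the generator does *not* emulate: isotopic envelopes and charge
deconvolution, correlated (structured) missingness, retention-time
nonlinearity beyond affine, shared peptides between proteins,
ionization competition, and batch effects. Passing tests therefore
demonstrate algorithmic correctness and calibration under the stated
model, not robustness to every artifact of real instrument data.

## Numerical choices and problem sizes

- Even-count medians take the central-pair midpoint throughout.
- Permutation p-values are floored at 1/(N_null + 1); Storey q-values
  are clipped into (0, 1] and made monotone by step-down minimization.
- Stouffer input p = 0 is clamped to the smallest positive double.
- Mass-window binary search pads the bracket by 10⁻¹² relative and
  re-filters exactly inside the window, so indexing cannot change
  match semantics.
- Degenerate inputs fail loudly: constant elution axes, < 3 calibration
  anchors, columns with < 2 observations, unmapped runs, duplicate
  (run, UMC) records.
- Validation suites run cohorts of 400 five-peptide proteins
  (~2000 peptides) for null-FDR control and planted-effect recovery,
  and 1000 permutations per test; these sizes give stable Monte-Carlo
  estimates while keeping a full cohort under ten seconds on one core.

## Known limitations

- The pooled permutation null assumes comparable null dispersion across
  peptides; strongly heteroscedastic peptides would argue for a
  per-peptide null at much larger B.
- Peptides shared by multiple proteins are assumed unique-mapped;
  grouping/parsimony inference is out of scope.
- AMT assignment carries no decoy-based error estimate; accuracy is
  quantified on synthetic ground truth instead.
- Quantile normalization with heavy, structured missingness relies on
  interpolated per-column quantiles and can bias extreme ranks when a
  column observes very few values.
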