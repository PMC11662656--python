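# Methods

## Motif grammar and match semantics

The PUN motif grammar is a fixed regular pattern — three runs over a
positive alphabet (default `{R, K}`) separated by two spacer blocks over
the strict complement of that alphabet, with block length bounds
(1–3, 1–3, 2–3, 1–3, 1–3). Two consequences of "strict complement" are
deliberate: ambiguity codes (X, B, Z) and non-standard letters (U, O)
count as spacer characters, exactly as a `[^RK]` character class behaves
on raw FASTA text; and the grammar is case-insensitive only because
sequences are uppercased on ingest ('*', gaps and whitespace stripped).
The minimal motif is 6 residues, the maximal 15 (all five blocks at their
upper bound).

Scanning uses Perl-style leftmost, greedy, non-overlapping semantics:
quantifiers prefer the longest feasible extent with backtracking, and
after a match the scan resumes at the match end. Overlapping occurrences
are therefore not counted; a POSIX leftmost-longest mode is intentionally
not provided. The test suite pins these semantics against an independent
brute-force matcher that enumerates block decompositions in greedy order,
with exact agreement required on tens of thousands of random strings.

## PUN-protein call

A protein is a PUN protein when `motif_count >= 5` and at least 3 motifs
co-occur within one 150-aa window. "Within a window" is interpreted on
full motif spans — a run of consecutive matches counts when
`end(last) − start(first) <= window` (`cluster_mode="span"`). The
alternative start-to-start reading (`cluster_mode="start"`) is available
behind a switch so both interpretations can be compared on real proteomes;
span mode is the default. The variant rule for very short-protein
proteomes (*E. coli*) drops the clustering clause and lowers the count
threshold to 3 (`ECOLI_RULE`). Motif density uses the full protein length
as denominator, not the disordered-region length; ranking ties break by
motif count, then protein id, making the ranking fully deterministic.

## Disorder comparison

Disorder is consumed as per-residue score tracks in [0, 1] (e.g. IUPred2
output in long TSV format); no predictor is implemented or wrapped. Each
PUN protein contributes its mean per-residue score; the comparison group
is a uniform random sample (without replacement, seeded) of proteins with
*zero* motifs — a stricter condition than "not a PUN protein". The
two-sided Wilcoxon rank-sum test enumerates the exact null distribution of
the rank sum (dynamic program over ranks) when the smaller group has
<= 10 observations and the pooled values are tie-free; the two-sided p is
`min(1, 2·min(P(W<=w), P(W>=w)))`. Otherwise a normal approximation with
tie correction and a 0.5 continuity correction is used. Exact and
approximate branches agree to within |Δp| <= 0.01 at n1 = n2 = 10, and the
empirical type-I error at α = 0.05 under a zero-shift null is 0.05 ± 0.01
over 5000 seeded replicates at the study's group sizes (95 vs 500). When
every pooled value is identical, the test degenerates and returns p = 1
with a warning.

## Over-representation analysis

The one-sided upper-tail hypergeometric p-value is computed in log-gamma
space and summed over the tail; Benjamini–Hochberg adjustment is applied
across all tested terms. Both pieces are implemented in this package and
cross-checked in tests against one-sided Fisher's exact test (scipy) and
`fdr_bh` (statsmodels). The universe is restricted to proteins present in
the scanned FASTA: term sizes K count only universe members, and terms
outside K ∈ [10, 500] (configurable) are not tested. Annotations are read
from GAF 2.x (NOT-qualified rows dropped) or a two-column TSV; no GO-graph
propagation is performed — the annotation file is the membership source,
so results on propagated vs unpropagated inputs will differ accordingly.
Only enrichment (over-representation) is tested, not depletion.

## Ortholog conservation

Given profiles for a source and a target proteome scanned with the same
grammar, the summary partitions source PUN proteins into no-ortholog,
mappable (one2one/one2many) and many2many-only; many2many relations are
excluded from the conservation call. A mappable source protein counts as
"conserved PUN" if at least one of its targets is a PUN protein — the most
permissive reading of one-to-many orthology. No sequence alignment is
performed; motif-architecture similarity is reported descriptively
(count difference, density ratio, clustering difference, normalized motif
start positions) rather than scored, since no metric is defined for it.

## Binding isotherm and melting midpoint

The titration model is the quadratic (ligand-depletion) single-site
isotherm in CSP form; concentrations are in μM, CSP in ppm. The
discriminant is clamped at zero against floating-point rounding near the
stoichiometric corner. Fitting is unweighted least squares: the model is
linear in CSP_max, so a coarse 60-point log grid over K_d ∈ [10⁻², 10⁵] μM
with closed-form CSP_max per grid point seeds a Levenberg–Marquardt
refinement in log-parameter space (which also enforces positivity).
Convergence is the optimizer's gradient/step criterion and is reported in
the result. Fewer than 4 points or zero-variance CSP values are rejected.

The melting midpoint normalizes a curve to its low-temperature plateau
(mean of the first two samples) and reports the temperature of the *first*
downward crossing of 0.5, linearly interpolated between the bracketing
samples; a sample exactly at 0.5 returns that temperature. First-crossing
is a convention — for noisy, non-monotone curves other conventions exist,
and the error "melting not reached" is raised when no crossing occurs.
Temperature units pass through unchanged.

## Synthetic data: what it emulates, and what it does not

The generator produces proteomes whose *statistical skeleton* matches the
analysis setting: a controlled PUN fraction, known implanted motif counts
and clustering, a stated upward disorder shift, one enriched annotation
term, and an ortholog table onto a second generated proteome. Default
study conditions, chosen once:

| parameter | default | rationale |
|---|---|---|
| n_proteins | 1000 | large enough for a 500-protein background |
| length | uniform 80–600 aa | spans typical PUN-protein lengths (~100–600 aa) |
| pun_fraction | 0.05 | a few percent, matching real proteome-wide hit rates |
| motifs per PUN protein | uniform 5–8 | the call threshold up to the observed top densities |
| cluster | ≥3 motifs in one 150-aa window, p=1 | the clustering clause of the call rule |
| R/K background frequency | 2 % each, rest uniform | background motifs rare but possible |
| disorder | Beta, mean 0.30 (+0.20 for PUN), concentration 10 | clearly disjoint group means with realistic per-residue spread |
| enriched term | q_pun = 0.80, q_background = 0.05 | strong single-term signal |
| decoy terms | 20 at 8 % coverage | BH correction has something to correct over |
| orthologs | 60 % one2one + 10 % one2many of PUN proteins | mixed homology classes |

Implanted motifs are sampled from the grammar (block lengths uniform,
residues uniform within their class), placed without collisions and with
at least one non-positive flanking residue on each side. After
implantation each sequence is re-scanned: a PUN protein is accepted only
when the detected matches equal the implanted ones and the intended label
holds; background proteins are resampled until they contain no motif at
all. Accidental background motifs are thus removed by resampling rather
than masking, keeping accepted sequences i.i.d.-like; the resampling
budget (100 attempts) raises an explicit error when background frequencies
are too R/K-rich. Identical spec + seed give byte-identical output files.

What the generator does **not** emulate: real amino-acid composition,
di-residue statistics, domain structure, length–disorder correlation, or
annotation-term dependence beyond the single enriched term. Passing the
recovery tests therefore demonstrates the correctness of the scanner,
classifier and statistics under known ground truth — not that real
proteomes have the published motif counts. Those counts are checked
separately against the pinned UniProt reference proteomes when the
downloaded FASTAs are present (`scripts/fetch_proteomes.py`;
`data/proteomes/`), since proteome files are too large to ship and counts
can drift between UniProt releases — such drift is reported by the test
message, not silently accepted.

## Problem sizes and determinism

The default test-suite and acceptance-script problem sizes (10⁴ oracle
strings, 10³-protein synthetic proteomes, 5·10³ rank-sum replicates, 10²
noisy titration fits) were chosen so each statistical check has narrow
Monte-Carlo error while the whole run completes in seconds. All
randomness flows through `numpy.random.default_rng` seeded from a single
user-supplied seed; child seeds are derived via `SeedSequence`.

## Known limitations

* No motif discovery and no probabilistic (PWM) motif model — the grammar
  is fixed a priori.
* The per-protein profile keeps whole-motif granularity; residue-level
  disorder/motif colocalization is out of scope.
* The enrichment stage does not model the GO DAG; term p-values are as
  granular as the annotation file.
* `fit_isotherm` assumes a single binding site and unweighted residuals;
  heteroscedastic CSP errors would need a weighted extension.
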