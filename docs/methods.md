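# Methods

This note documents the models and procedures implemented in `kinmatch`,
the parameters that matter, the numerical conventions, and the design
choices made where the design was genuinely open. It also describes what
the synthetic-data generator does and does not emulate, and therefore
what passing tests do and do not establish about real data.

## Phosphosite windows

A phosphosite is represented by a 10-symbol window covering positions
−5..+4 relative to the phosphoacceptor, which sits at string index 5
(signed position 0). Two input conventions are accepted: a centered
sequence of length ≥ 10 (acceptor at index `len // 2`; longer sequences
are trimmed symmetrically), or a single `*` placed directly after the
phosphorylated residue (any length; flanks that fall outside the protein
are padded). Padding uses `_`, and any flank symbol outside the 20-letter
amino-acid alphabet is normalised to `_` at parse time. Both `_` and the
acceptor classes are hard rules: a central residue that is not S, T or Y
rejects the row, and every rejected row is reported with a reason — rows
are never dropped silently, so accepted + rejected always equals the
input row count.

Site positions are 1-based (protein coordinates); all internal window
indices are signed offsets. Duplicate windows under distinct peptide ids
are kept as distinct observations throughout: they are separate
measurements in the input, and collapsing them would silently reweight
the activity statistic.

## PSSM score

For kinase *k* and window *w* the match score is

    S(k, w) = Π_{p ∈ {−5..−1, +1..+4}} W_k(p, w_p) × C_k(w_0)

where `W_k` are the strictly positive PSSM weights and `C_k` is the
central term: for S/T kinases the favorability ratio
`w0_S / (w0_S + w0_T)` when the acceptor is serine (the T counterpart for
threonine), for Y kinases the constant 1. The favorability term expresses
a kinase's relative serine-vs-threonine preference at the acceptor
position and is included by default (`--no-favorability` disables it, in
which case `C ≡ 1`). Neutral symbols (`_` or unknown) contribute a factor
of 1 — "no information" — rather than an average weight, so terminal
sites score deterministically.

Scores are computed and stored in natural-log space. A product of nine
weights each far below 1 underflows double precision quickly, while the
downstream percentile step consumes ranks only, which the monotone log
transform preserves; the product form is recovered exactly by
exponentiation (verified against a direct-product oracle to < 1e-9
relative).

## Background percentiles and match calling

Raw scores are comparable only within a kinase, so each kinase's score is
ranked against its *background distribution*: the PSSM applied to a large
reference set of phosphosites of the matching class (S/T kinases use the
S/T-acceptor set, Y kinases the Y set). Backgrounds are input files, not
hard-coded sizes; a configurable floor (default 100 compatible sites)
guards against meaningless percentiles. Families inheriting the same
human PSSM share one computed distribution.

The percentile is the strict-below rank, `100 · #{bg < s} / n`, computed
by binary search on the sorted score vector — no interpolation and no
midpoint tie-splitting. This is the simplest rank definition, it makes
the self-consistency property exact (a background thresholded against
itself at the 90th percentile calls exactly ⌊n/10⌋ sites when scores are
distinct), and ties between real-valued PSSM scores are measure-zero. A
peptide matches a kinase when its percentile is ≥ the threshold (default
90); the boundary uses ≥, so threshold 100 demands strictly outscoring
the entire background. Peptides that match no kinase at all are flagged
unmatched and excluded from the activity, clustering and network stages.

## Orthology transfer

Human kinase specificities are transferred to model-organism kinases via
a precomputed ortholog table (model gene, human kinase, one-to-one flag,
optional evidence weight). The ortholog inference itself is an input
contract, not re-implemented: it depends on external database versions,
whereas the computation proper is mode selection and family collapsing.

When several model genes map to one human kinase their inherited
specificities are indistinguishable, so they are collapsed into a single
family whose id is the sorted member list joined with `/`. `one_to_one`
mode keeps only records flagged one-to-one whose human kinase is hit by
exactly one model gene and whose gene maps to exactly one human kinase —
both counted over the full table, the conservative reading. `ambiguous`
mode emits one family per human kinase over all genes that map to it; a
gene with complex orthology may then appear in one family per human
kinase, and is scored under each inherited specificity (logged). The
one-to-one catalog is always a subset, by member genes, of the ambiguous
catalog. For human data a passthrough catalog provides one identity
family per loaded PSSM. PSSM objects are shared by reference, never
copied.

## Activity inference (KSEA z-test)

For each family with at least `min_substrates` (default 3) matched
peptides carrying a log2 fold-change:

    z = (mean(substrate log2FC) − mean(all log2FC)) · √m / sd(all log2FC)

The reference population is **all quantified peptides in the experiment**,
matched or not; the unmatched-peptide exclusion governs which peptides
can be substrates and appear in downstream tables, not the reference
population of the statistic. `sd` uses the population convention
(denominator *n*), fixed so tests can assert exact values. The
`min_substrates` floor exists because a mean of fewer than three values
makes z unstable; excluded families stay in the match table.

The one-sided p-value is the fixed upper tail, `p = 1 − Φ(z)`, testing
*increased* substrate phosphorylation; the sign of z is reported
separately so inhibited kinases are visible (direction −1, p near 1).
The tail is fixed rather than taken in the direction of the observed
effect because only a fixed-direction p-value is uniform under the null —
`1 − Φ(|z|)` would reject at twice the nominal rate at any level below
one half, which the null-calibration test demonstrates. To test for
decreased activity, negate the input log2FC.

Benjamini–Hochberg step-up correction is applied once across all tested
families per experiment (a single decision set, not per kinase class),
with significance flags at the configured FDR (default 0.10). Aggregation
orders are fixed (sorted peptide ids), so results are exactly invariant
to input row permutation.

## Clustering and network

The heatmap matrix holds the percentile of every scored (peptide, family)
pair — sub-threshold cells included, so the display shows gradation — over
the rows/columns with at least one above-threshold match. Pairs never
scored (class-incompatible) are filled with 0 and flagged in a mask;
Euclidean distances run on the filled matrix, since leaving holes would
make the distance undefined. Both axes are clustered with Ward's method
on Euclidean distances via `scipy.cluster.hierarchy.linkage`; merge
heights are non-decreasing, and determinism follows scipy's fixed
tie-breaking, which is documented here as the package's ordering
convention. Single-item axes yield a trivial tree.

Network edges run from a matching kinase family to the protein owning the
phosphosite, kept at the network threshold (default: the match threshold;
may be stricter — the edge set is monotone non-increasing in the
threshold). Multiple matched sites on one target collapse to a single
edge carrying the maximum percentile, with per-site positions retained.
`target_is_kinase` is decided by membership of the target protein id in
the catalog's member-gene universe. Self-loops (a kinase matching its own
phosphosite) are retained and marked — autophosphorylation is
biologically meaningful. When a kinase subset is selected, edges touching
a selected family are kept, which pulls in non-selected kinases that
phosphorylate a selected one; non-kinase targets require the
include-nonkinase toggle.

## Synthetic data

The generator emulates the study conditions the pipeline is validated
under, with these defaults, chosen once: 6 S/T + 2 Y kinases;
`concentration` 0.1 (symmetric-Dirichlet sharpness of the specificity
profiles — small values concentrate weight on few residues per position,
as selective kinases do); 5000 background sites per class; experiments of
50 planted peptides (windows sampled residue-by-residue from the planted
kinase's normalised weight profile, acceptor by its favorability ratio,
log2FC ~ Normal(δ=1, σ=1)) among 2000 null peptides (uniform windows,
log2FC ~ Normal(0, σ)); 30 % of planted peptides sit on model-organism
kinase genes so the network stage has kinase–kinase edges; the ortholog
table maps one gene per kinase one-to-one plus one two-gene paralog
family to exercise collapsing. All draws derive from a single seed
through per-generator seed sequences, so every artifact is reproducible
independently of call order and identical seeds give byte-identical
files.

What is *not* emulated: proteome residue composition (backgrounds are
uniform — the simplest null with known properties), mass-spectrometry
missingness and intensity-dependent noise, correlated substrates, and
multiply-phosphorylated windows. Passing tests therefore establish the
statistical and numerical correctness of the machinery under a clean
null, not recovery rates on real experiments.

A structural property of the benchmark worth knowing: null windows are
drawn from the same law as the background, so at threshold 90 each kinase
chance-matches ~10 % of null peptides. The planted kinase's substrate set
is thus diluted (≈ 50 planted among ≈ 250 substrates at the default
sizes), which caps the power of the activity test at these conditions:
the planted-kinase recovery rate at BH ≤ 0.10 measured over an
800-replicate calibration run is ≈ 0.87–0.90, and the frozen test bound
(≥ 0.78 over 100 replicates) is that estimate minus ~2.9 binomial
standard deviations, so the check is stable under seed choice.

## Numerical and interface conventions

* Thresholds are percentiles in [0, 100]; FDR in (0, 1); defaults:
  threshold 90, favorability on, FDR 0.10, min_substrates 3,
  orthology mode one_to_one (the conservative option).
* p-values are floored at 1e-300 to stay strictly positive for log-scale
  plots.
* All output tables are TSV with fixed column orders and lexicographic
  sort orders; floats that must survive a read/write round trip are
  serialised with 17 significant digits and parsed with round-trip float
  precision. Two runs on identical inputs and configuration are
  byte-identical.
* CLI exit codes: 0 success, 2 usage error, 3 input/validation failure.

## Known limitations

* Favorability uses the central-column ratio of the PSSM; kinases whose
  S/T preference is context-dependent are not modelled.
* One acceptor per window: doubly phosphorylated 10-mers are out of
  scope.
* The activity test treats substrates as independent; shared peptides
  between families make family statistics correlated, which BH tolerates
  but does not model.
* Percentile ties are resolved by the strict-below count; with discrete
  or heavily tied score distributions (not the case for real PSSMs) the
  called fraction at a threshold can deviate from the nominal one.
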