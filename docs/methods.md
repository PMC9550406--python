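# Methods

## Problem setting and model

`entrosite` classifies fixed-length RNA segments (default 101 nt, site
base at 1-based position 51) as binding or nonbinding for one specific
RNA-binding protein. The model assumes that binding segments of a protein
share position-specific sequence preferences concentrated near the site
base — a 6–8-nt motif window — while nonbinding segments look like
background. All sequence is held internally in the DNA alphabet (U → T on
ingest); `N` is accepted and treated as missing wherever it appears.

## Feature encodings

**Entropy / information content.** For each class of the *training* split
a position profile is built: `p_{i,b} = (c_{i,b} + a) / (Σ_b c_{i,b} + 4a)`
with pseudocount `a = 1` by default. Add-one smoothing keeps every
`p_{i,b} > 0` so entropy and information content stay finite on small
training sets; increasing `a` monotonically pulls every position toward
the uniform 2-bit maximum. Entropy uses base-2 logarithms (bits), the
standard convention for nucleotide logos, with `0·log2(0) := 0`.

The per-segment IE feature is a deliberate design choice: the profile
defines per-base information contents, and the segment vector is the
lookup of the observed base's content under the positive profile
(entries 0..L-1) and the negative profile (entries L..2L-1), 202 features
at L = 101. This uses exactly the quantities the conservation analysis
defines, and gives the forest access to both "how positive-like" and "how
negative-like" each observed base is. Entropy-only or log-odds encodings
were considered; the two-profile lookup subsumes the information both
carry without extra tuning. `N` contributes 0 at its positions. Profiles
are frozen (read-only arrays) after construction, so featurizing held-out
segments cannot leak information back into them.

**k-mers.** Counts (not frequencies) are the default: all segments share
one length, so totals are comparable, and tree ensembles are
scale-insensitive; a `normalize` flag is available. Windows containing
`N` are skipped, hence `Σ counts + #(N windows) = L − k + 1`. A k-mer and
its reverse complement are distinct features (single-stranded RNA). The
k = 5 vector has 4^5 = 1024 entries.

**Secondary structure.** Folding is delegated to external tools; the
package consumes dot-bracket text. Paired positions are `S`; an unpaired
position is classified by its enclosing loop: hairpin `H` (no inner
helix), internal loop/bulge `I` (exactly one inner helix), multiloop `M`
(two or more); unpaired bases 5′ of the first pair are `F`, 3′ of the last
pair `T`. Two edge cases the six-state vocabulary leaves open are fixed as
the package dialect: exterior bases *between* helices are labeled `M`
(a junction is the closest category), and a completely unpaired string is
labeled all `T`. Pseudoknot symbols are rejected. One-hot encoding yields
6L features.

## Classifier

One random forest per protein (scikit-learn), 500 trees and √p features
per split by default — the standard defaults of the ensemble family, since
no stronger prior exists for these data. The prediction score is the
fraction of trees voting for the binding class (not averaged leaf
probabilities), which pairs naturally with the threshold-free ROC
construction. The seed is a required config field; the split, bagging and
any label shuffling all derive from it, so a run is reproducible
byte-for-byte. The out-of-bag accuracy is recorded when the sample size
supports it. The feature schema (block names and widths) travels with the
model and is enforced at prediction time.

## Data handling

Datasets from multiple experiments on the same protein are pooled by a
manifest into per-protein groups before splitting; the built-in manifest
encodes the canonical 31-experiment → 19-protein grouping, with
MNase-digested Ago2 and ELAVL1 kept as separate proteins. The train/test
split is 5:1 and stratified per class — the source procedure states only
the ratio; stratification preserves the class balance the balanced-class
metric identities assume.

## Evaluation

SE, SP and ACC come from the confusion matrix at a configurable threshold
(default 0.5). MCC is the standard Matthews form, defined as 0 when a
marginal is zero; the balanced-class closed form
`(SE+SP−1)/√((1+SE−SP)(1+SP−SE))` is exposed separately and raises on a
degenerate denominator instead. ROC is the sweep over unique scores with
ties crossing simultaneously; the trapezoidal area then equals the
Mann–Whitney statistic with half-credit for ties, which the test suite
verifies against exhaustive pair enumeration. For balanced test sets
ACC = (SE+SP)/2 exactly. Report tables carry
(group, protein, SE, SP, ACC, MCC, AUC_train, AUC_test) plus an
arithmetic macro-average row; positions in human-readable output are
1-based.

## Synthetic benchmark

The generator emulates the statistical shape of CLIP-derived segment
sets: 101-nt uniform-background sequences, positives carrying a PWM-drawn
7-mer implanted at 1-based 48–54 — the window where real binding motifs
concentrate around the crosslink base — in 90% of segments (implant
fraction < 1 emulates CLIP label noise while keeping the problem cleanly
solvable); the default PWM puts probability 0.85 on an A/T-rich consensus.
A structure toy set pairs hairpin-centered positives with stem-covered
negatives for end-to-end structure-encoder tests, with paired positions
complementary. What the generator does **not** emulate: genomic sequence
composition, transcript context, read coverage, crosslink-induced
mutations, or correlated negatives — so passing tests demonstrate correct
mechanics and motif recovery under the stated model, not real-data AUCs.

Default problem sizes in the test suite (600+600 segments, 5:1 split,
200-tree forests for repeated null fits) were chosen so the full suite
documents the end-to-end behavior at comfortably interactive runtimes
while keeping the null-control statistics meaningful: with 200 held-out
segments the chance-level AUC has a standard deviation of ≈0.04, so the
shuffled-label control is asserted on the mean of 10 repeats (sd ≈0.013)
with per-repeat sanity bounds.

## Numerical choices and degenerate inputs

- Entropy is clipped to [0, 2] to absorb round-off at fully conserved
  positions; IC row sums satisfy `Σ_b ic_{i,b} = 2 − H_i` to 1e-12.
- A position with zero effective count (all `N`) and zero pseudocount is
  an error, not a silent NaN.
- Splitting requires both classes with at least ratio-sum members; the
  per-class test count is rounded, clamped to keep at least one segment on
  each side.
- Unbalanced brackets or pseudoknot symbols in dot-bracket input raise
  with the offending position.
- Windows that would run past a sequence end raise; there is no padding.

## Known limitations

- The IE encoding is per-protein and transductive in spirit: profiles must
  be rebuilt for every new protein; there is no cross-protein model.
- Secondary-structure states depend on the chosen folding tool and the
  dialect decisions above; other tools' "exterior" classes map onto M/F/T.
- Metrics assume binary labels; no multi-class or regression support.
- The forest offers no calibrated probabilities; scores are vote shares.
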