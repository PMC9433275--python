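# Methods

## PPII assignment from backbone geometry

A residue's backbone conformation is summarized by the dihedrals
φ = C(i−1)–N–CA–C and ψ = N–CA–C–N(i+1), computed in degrees on
(−180, 180] with the IUPAC sign convention (cross-checked against two
independent torsion formulas and third-party structure libraries).
Consecutive residues separated by a C→N distance above 2 Å are treated as a
chain break and no dihedral is computed across the gap.  Alternate
conformations are resolved to the highest-occupancy atom; residues outside
the twenty standard amino acids are kept with code `X`.

Two PPII definitions are implemented.  Both require
ψ ∈ (−180, −160) ∪ (90, 180).  The strict definition additionally requires
φ ∈ (−105, −45) and a trans-compatibility criterion: the CA-trace
pseudo-torsion α(i) = torsion(CA(i−1), CA(i), CA(i+1), CA(i+2)) must lie in
(−145, −70).  All inequalities are strict (open intervals), so undefined
angles — chain termini, breaks — can never pass.

**Why the CA pseudo-torsion.**  The trans criterion is stated in the
assignment literature over an "αC" virtual angle without a construction.
Among the candidate virtual torsions, the four-CA pseudo-torsion (the angle
conventionally called α in CA-trace work) is the only one whose value at
ideal trans-PPII geometry (−109.3°) falls inside the printed (−145, −70)
band while cleanly excluding cis/PPI (+93.8°) and α-helical (+50.6°)
geometry; a CA(i−1)–CA(i)–C(i)–N(i+1) reading evaluates to +129.9° at ideal
PPII and would reject the very conformation the filter is meant to accept.
The band lives in `FilterConfig`, so alternative readings are a
configuration change.  The criterion applies in strict mode only and only
where computable (interior residues with two following neighbors).

**Segment acceptance.**  Maximal runs of residues passing the per-residue
filter become candidates.  A candidate of length n ≥ `min_segment_length`
(default 3, the short end of observed PPII lengths) is accepted when its
conformational uniformity score

    score = (1/(n−1)) · Σ_{k=1..n−1} √(wrap(ψ_k − ψ_{k+1})² + wrap(φ_k − φ_{k+1})²)

does not exceed τ.  Angular differences are wrapped into (−180, 180], so a
pair (179°, −179°) contributes 2°, not 358°.  The mean is taken over the
n−1 consecutive pairs; dividing by n instead is available via
`score_divisor="length"` and the choice is recorded in the segment-table
header.  No published value of τ exists for this score; the default 30° is
chosen so that ideal-geometry chains (score 0) pass with a wide margin
while segments alternating between the two ψ bands (score ≈ 80°) fail, and
it is always user-overridable.

**A monotonicity caveat.**  Per residue, passing the strict filter implies
passing the less-strict filter.  At the segment level, however, a finite
shared τ can break this containment: removing the φ band merges or extends
candidate runs, and a longer, less uniform run may exceed τ while its
strict sub-run passes.  With the τ gate disabled the strict PPII residue
set is always contained in the less-strict set.

**Numerical accuracy.**  Chains written as mmCIF round-trip their torsions
to ~5·10⁻⁶ degrees; the PDB format's fixed 3-decimal coordinate columns
limit round-trips to ~0.1°, which is why high-precision work should use
`.cif` output.

## Synthetic data

*Structures.*  Backbones are built from internal coordinates by sequential
natural-extension (NeRF) placement with fixed ideal geometry (N–CA 1.458 Å,
CA–C 1.525 Å, C–N 1.329 Å; N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°),
backbone atoms N/CA/C/O only.  ω defaults to 180° (trans) so PPII chains
exercise the trans filter in its passing regime.

*Sequences.*  The generator emulates the composition contrast between PPII
and non-PPII residues.  Positive labels come in runs of 3–8 (the typical
PPII length), placed to cover ≈5% of residues in 600 sequences of length
80–120 over a uniform background.  Positions within `motif_halfwidth`
(default 1) of a positive residue draw from an enriched distribution in
which proline has `proline_enrichment` (default 5) times its background
frequency and the remaining amino acids follow a PPII-propensity tilt
(A/E/K/L/Q/S favored ×3, the rest ×0.1 at the reference five-fold
enrichment; the tilt exponent is log e / log 5, so enrichment 1 reproduces
the background exactly and is a true no-signal null).  These defaults were
fixed by a design study with an independent linear classifier before the
network was built: they give a learnable but non-trivial task (oracle AUC
≈ 0.98) and a center-position proline frequency ratio of ≈5 between
classes.

What the generator does *not* model: evolutionary correlations and homology
structure, position-specific conservation profiles, long-range contacts,
and realistic (non-uniform) background composition.  Passing tests on this
generator therefore demonstrates that the pipeline can extract a local
composition signal at the stated sizes — not that it matches published
performance on curated structure-derived corpora, which additionally
require redundancy filtering and far larger training budgets.

## Dataset construction

Each residue of a labeled sequence yields exactly one window sample of odd
width w (default 15, selected by the window sweep on balanced data), padded
with `X` beyond the termini so the sample count always equals the sequence
length.  Undersampling keeps every positive and draws an equal number of
negatives uniformly without replacement.  Splits are stratified by class;
part sizes follow largest-remainder apportionment of the total, with the
per-class allocation pinned to those totals, so each part lands within one
sample of its ideal share overall and per class.  Balancing happens before
splitting.  All randomness flows from named sub-seeds of one run seed, so
subsystems are independently reproducible and any split can be rebuilt from
its JSON manifest.

## Network

Tokens are the 20 amino acids, the pad symbol `X`, and a CLS token
prepended at position 0.  The input is a learned embedding plus the
sinusoidal position code PE(pos, j) = sin(pos/10000^(j/d)) for even j and
cos(pos/10000^((j−1)/d)) for odd j.  Each encoder block applies multi-head
scaled dot-product self-attention, a residual connection, and layer
standardization of the form (x − μ)/(σ + ε) — the ε sits on σ itself, so a
constant row maps to the affine offset β rather than dividing by zero —
followed by a ReLU feed-forward sublayer with its own residual and
standardization.  Pad tokens participate in attention by default
(`mask_padding` is available but off).

The CLS output row is the global feature; the n residue rows form the
matrix B consumed by the convolution channels.  Each channel slides a
kernel over m consecutive rows (stride 1, no padding, map length n−m+1,
weights initialized from a uniform distribution) and global-max-pools per
filter; channel outputs concatenate in declared kernel order into η, and
the classifier applies a linear softmax head to M = concat(CLS, η), of
dimension d_model + q·|kernels|.

Training uses Adam (β₁ 0.9, β₂ 0.999) on cross-entropy, batch size 64,
learning rate 10⁻³, float64 throughout, and keeps the checkpoint with the
best validation AUC.  Architecture defaults follow the BERT-base shape
(768 × 12 × 12), which is also the published embedding width for this
problem; all tests and the reference experiments use the `tiny()`
configuration (d_model 32, 2 layers, 2 heads, d_ff 64, q 16), which trains
on 4,000 windows in well under a minute on one CPU while exercising every
code path.  Pretrained-weight loading is possible by assigning to
`PPIIClassifier.params` but nothing here depends on external checkpoints;
masked-language-model pretraining is out of scope.

Because both passes are hand-written, analytic gradients are checked
against central finite differences (relative error < 10⁻⁴ with a 10⁻³
denominator floor for near-zero components; observed ≈ 10⁻⁷ in float64).
Ties in the max-pool argmax and ReLU kinks are measure-zero for continuous
inputs and do not affect the check in practice.

## Evaluation

Sens, Spec, ACC and MCC are computed from the confusion table at a
configurable probability threshold (default 0.5; score ≥ threshold counts
positive).  Any zero marginal makes MCC (or a ratio) undefined; the
implementation reports 0 there and logs the fallback.  ROC curves sweep all
distinct score thresholds (scikit-learn, no intermediate dropping) and AUC
is the trapezoid area, which equals the rank statistic
P(score⁺ > score⁻) + ½·P(tie); the test suite verifies this identity
against an independent all-pairs implementation.  The sweep harnesses run
one seeded balance/split/train/evaluate cycle per window size (odd sizes,
step 2) or per kernel-size combination ({3}, {3,4}, {3,4,5}, {3,4,5,6},
{3,4,5,6,7}) and emit Sens/Spec/MCC/ACC(/AUC) tables.

## Problem sizes

The reference experiments run at deliberately small scale: tiny encoder
configuration, 4,000 balanced windows for signal recovery, 2,000 for the
label-shuffled control, ~10,000 windows for composition recovery, a
5°-step dihedral grid for the filter truth table, and segments up to length
8 for the uniformity-score cross-check.  These sizes were chosen so the
whole suite plus the reproduction script completes in a few minutes on a
single CPU while every contract is still exercised at meaningful n.

## Known limitations

- Assignment quality on real structures depends on coordinate quality; no
  resolution/R-value screening or homology reduction is performed (these
  are database-level filters, out of scope).
- The less-strict/strict containment caveat above.
- The classifier is trained from random initialization; results on real
  corpora would require the full-size configuration, large labeled data,
  and ideally encoder pretraining, none of which the synthetic experiments
  claim to reproduce.
- `X` participates as an ordinary token (pad and nonstandard-residue code
  coincide by design, matching how termini are padded).
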