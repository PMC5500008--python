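# Methods

## Recombination model

The generative model covers the junction region of a rearranged TCR
chain. A scenario consists of a joint segment choice (V, J for the alpha
chain; V, D, J for beta), non-negative deletion counts from the joining
ends (V 3', J 5', and both ends of D), insertion lengths for each
junction, and the inserted nucleotides themselves. Its probability
factorizes as

    P(scenario) = P(V,(D,)J) · P_delV(dV|V) [· P_del5(d5|D) P_del3(d3|D)]
                  · P_delJ(dJ|J) · P_ins(ℓ) [· P_ins'(ℓ')] · Π p_nt(n_i)

with every factor a categorical distribution supplied in the model file.
Design choices where the underlying biology admits richer options:

* **Inserted nucleotides are i.i.d.** from `p_nt`. Published inference
  tools use dinucleotide Markov models; none of the statistics computed
  here (Pgen sums, insertion-length posteriors, zero-insertion
  consistency) depends on within-insertion correlations strongly enough
  to justify the extra parameters.
* **No palindromic (P) nucleotides; deletions ≥ 0.** Zero-insertion
  consistency therefore means "entirely matchable to trimmed germline
  segments".
* **Joint segment choice** `P(V,(D,)J)` rather than independent
  marginals; independence is a representable special case.
* **`d_max` and `ℓ_max` are explicit model fields.** For VDJ models,
  validation additionally requires `d5_max + d3_max ≤ len(D)` so every
  deletion combination leaves a well-defined D core; without this the
  model would place mass on unrealizable scenarios and Pgen would not
  normalize over sequences.

`Pgen(σ)` sums scenario probabilities over every explanation of σ. The
implementation first computes, per V (J) segment, the feasible trimmed
prefix (suffix) match lengths against σ — almost all segment choices are
eliminated here — then iterates over feasible (lv, lj) windows. For VDJ
models D placements are resolved through a precomputed map from trimmed
D-core strings to their summed deletion probabilities, so placement
search is a hash lookup per candidate insertion split. `enumerate_scenarios`
provides the same sum as an explicit scenario list and serves as the
in-package cross-check; the test suite carries a second, fully
independent oracle that enumerates inserted strings exhaustively.

Zero-insertion consistency deliberately ignores the weight of
`P_ins(0)`: it asks whether a germline-only explanation *exists* (with
positive segment and deletion support), matching how the fraction F₀ is
measured from data without reference to the fitted insertion law.

## Per-individual models and restricted EM

Sharing predictions use one generative model per donor. Rather than
re-inferring all parameters, only the insertion-length distribution(s)
are re-estimated from the donor's own (out-of-frame) sequences by EM:
the E-step computes, per sequence, the posterior over insertion lengths
from the scenario table; the M-step sets `P_ins(ℓ)` proportional to the
accumulated posterior mass. The log-likelihood is verified to be
non-decreasing at every iteration and the iteration stops at |ΔlogL| <
1e-8 or 200 iterations. This captures the donor-specific feature that
matters most for sharing — an excess of zero-insertion (fetal)
sequences — while keeping segment-usage and deletion profiles shared.
At 10⁴ input sequences the recovered distribution is typically within
total-variation distance ~0.015 of the truth; the residual is sampling
noise, not bias.

Per-bin mean insertion numbers are offered in two modes: the default
averages per-sequence posterior means (deterministic, no iteration); the
"em" mode runs the restricted EM on the bin and reports the mean of the
fitted distribution. The two agree exactly on unambiguous data.

## Sharing statistics

Sharing is computed on distinct clonotype keys (CDR3 nucleotide sequence
by default; optionally (V, CDR3, J)). The normalized sharing number
|S₁∩S₂|/(|S₁||S₂|) carries a Poisson standard deviation √shared/(|S₁||S₂|);
Monte-Carlo predictions report mean ± SD across replicate synthetic
cloneset pairs built of *distinct* sequences passing the frame filter.
The in-frame estimator reweights each shared sequence by the product of
the two donors' selection factors Q and reduces exactly to the
unweighted statistic at Q ≡ 1.

The twin mixture fit is binned maximum likelihood: observed bin counts of
log₁₀ Pgen over the shared set are modelled as multinomial draws from
w·regular + (1−w)·coincidental, with w optimized on [0,1] and its SD from
a multinomial bootstrap (≥200 resamples). The coincidental reference
pools sequences found shared between replicate synthetic cloneset pairs;
the regular reference is the Pgen distribution of generated (not
necessarily shared) sequences. Bins outside the support of both
components are excluded with a warning.

The sharing-vs-abundance prediction draws, per abundance class C and per
side, an artificial cloneset mixing germline-matchable sequences (group
A) and the rest (group B) in proportions F₀(C) : 1−F₀(C), with F₀(C)
measured from the pooled top-C clonotypes of the two data repertoires.
The two sides draw from independently generated pools so that overlap
reflects genuine convergent recombination, not pool reuse. A single
global multiplicative scale factor between observed and predicted curves
is fit by least squares and always reported, never silently applied.

## Aging fits

Both decay models are fit by bounded nonlinear least squares
(unweighted; the data provide no replicate-based weights), c, a, a′ ∈
[0,1] and b, b′ ∈ [0,1] yr⁻¹, with multi-start initialization over
b ∈ {0.005, 0.02, 0.08} and the lowest SSR retained. Standard errors come
from the Jacobian-based covariance. A near-constant series leaves b
unidentifiable (the amplitude a vanishes); the fit is then flagged rather
than rejected. The naive-confound curve c + a·exp(−b′T) anchors the
naive-pool rate to the Z curve's endpoints: both curves equal c + a at
birth and c in the long-time limit, so the comparison isolates the rate.
Parameter-recovery simulations (50 ages in 6–90, Gaussian noise sd 0.002,
100 replicates) recover the generating rate to within ±0.003 /yr; the
estimator carries a small positive bias (~0.001 /yr) from the
non-negativity bounds, well inside one reported standard error.

## Synthetic cohort

The generator emulates the data structure the analyses assume:

* **Clone sizes** are Zipf-like: P(size ≥ s) ~ s^(−α) with α = 1.1 by
  default, giving the heavy tail typical of UMI-counted repertoires.
* **Fetal (TdT−) clones** — a fraction f₀ (default 0.15; 0.3 for
  cord-blood scenarios mirroring the strong neonatal signal) drawn from a
  model with P_ins(0) = 1 — receive a multiplicative size advantage
  (default 10) applied to the continuous size before integer truncation,
  with per-clone lognormal variability (sd 0.5 in log space). The jitter
  matters: a sharp multiplier on integer sizes piles fetal clones onto a
  single size value and creates an artifactual plateau in the F₀-vs-rank
  curve. The advantage is the implementation of the vacant-niche
  narrative: clones that arrived first expanded into an empty repertoire.
* **Aging**: fetal clones survive to age T with probability exp(−bT)
  (clone-level Bernoulli survival, default b = 0.027 /yr), are replaced
  by post-natal TdT+ clones, and retain their advantage in naive and
  unpartitioned compartments. Memory compartments keep the same clone
  composition but draw sizes without the advantage — clonal expansion
  resets sizes — which produces the flat F₀-vs-rank profile.
* **Twins**: each twin's fetal-era pool consists of the TdT− clones plus
  an equal-size cord TdT+ pool (fetal in origin but with ordinary
  insertion statistics and no size advantage). A fraction τ of this pool
  is present with identical nucleotide sequence in both twins; survival
  is applied per twin. τ defaults to 0.5: the study that motivates this
  generator does not quantify the in-utero transfer, and monochorionic
  twins share placental circulation, so a large transferred fraction is
  plausible; the value is chosen so the twin excess is unambiguous at
  desk-scale cohort sizes (~10⁴ clones), comparable to the several-fold
  excess seen in real twin pairs. Because the transferred pool includes
  the TdT+ component, shared clonotypes include high-insertion, low-Pgen
  sequences — the signature that distinguishes transfer from convergent
  recombination.
* **Out-of-frame fractions** default to 13% (alpha) and 3% (beta),
  enforced by stratified sampling during pool assembly.
* **Q factors** are log-normal with median 1, deterministic per
  (amino-acid sequence, seed).

All generators are deterministic given (config, seed); per-donor streams
are derived from the global seed, the donor id and the compartment, so
any donor can be re-simulated in isolation.

What the generator does *not* emulate: sequencing error and UMI
collapsing artifacts, real germline alleles (segments are synthetic
random DNA of realistic length and count), dinucleotide insertion bias,
selection on in-frame sequences beyond the Q-factor abstraction, and
clonal dynamics richer than Bernoulli survival. Passing tests therefore
demonstrate that the *analysis machinery* is correct and sensitive under
the assumed data structure, not that real repertoires satisfy those
assumptions.

## Problem sizes and numerical choices

Simulated repertoires in the tests and the acceptance script use 10⁴–6×10⁴
clones, 50-point aging tables, 10⁵-draw mixture recoveries and ≤10
Monte-Carlo replicates per prediction — sizes at which every qualitative
signature is statistically unambiguous (z ≳ 3) while a full run stays in
the minutes range on one core. Categorical distributions must normalize
to 1 within 1e-9 at model load. Ranking ties are broken lexicographically
on the CDR3 sequence so all rank-based statistics are deterministic.
In-frame clonotypes carrying a stop codon are excluded from both frame
analysis sets by default (they are neither productive nor
selection-free), but are retained in the tables and recoverable via a
flag. Degenerate two-sample comparisons (identical zero-variance groups)
report p = 1 by convention.
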