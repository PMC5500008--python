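# tcrshare

Analysis of T-cell receptor (TCR) repertoire sharing and the persistence
of fetal clonotypes, built around a generative model of V(D)J
recombination.

## The problem

T-cell receptors are assembled by V(D)J recombination: germline V, (D,)
and J segments are joined with random end deletions and non-templated (N)
nucleotide insertions at each junction. The process is so diverse that two
independent rearrangements rarely produce the same nucleotide sequence —
yet unrelated people share thousands of identical clonotypes (the
"public" repertoire), and monozygous twins share even more. Two
mechanisms are at play:

* **convergent recombination** — high-probability sequences (few
  insertions, little trimming) recur by chance; and
* **fetal persistence** — clones recombined before birth, when the
  insertion enzyme TdT is downregulated, are zero-insertion, expanded
  (they filled an initially empty repertoire), can be exchanged between
  twins through shared cord blood, and decay only slowly with age.

`tcrshare` implements the quantitative machinery to separate the two:

* **Generation probability.** For a sequence σ, the recombination model
  assigns

      Pgen(σ) = Σ_scenarios P(V,(D,)J) · P(delV) (· P(del5'D) P(del3'D)) · P(delJ)
                · P(ins ℓ) · Π p(n_i)

  summed over every scenario (segment choice, deletion counts, inserted
  strings) whose realization equals σ. The implementation sums over
  feasible V-prefix / J-suffix match lengths and D-core placements, and is
  validated against exhaustive scenario enumeration.
* **Normalized sharing.** For clonesets S₁, S₂ the statistic
  |S₁ ∩ S₂| / (|S₁|·|S₂|) estimates the per-pair coincidence probability;
  it is predicted by Monte Carlo from per-individual models (insertion
  distributions re-fit to each donor's out-of-frame sequences by
  restricted EM), with the in-frame variant reweighted by selection
  factors: 1/(|S₁||S₂|) Σ_{s∈S₁∩S₂} Q⁽¹⁾(s) Q⁽²⁾(s).
* **Twin excess as a Pgen mixture.** The log₁₀ Pgen distribution of
  shared clonotypes is fit as w·(regular) + (1−w)·(coincidental); w > 0
  flags sharing that convergent recombination cannot explain.
* **Zero-insertion profiles.** F₀(C), the fraction of clonotypes
  consistent with zero insertions (entirely germline-matchable) per
  abundance class, with per-bin posterior-mean insertion numbers and a
  mixture model that predicts sharing as a function of abundance from
  F₀(C) alone.
* **Aging decay.** Z ≈ c + a·exp(−bT) for the zero-insertion fraction
  among the top-K clones vs donor age T, and N ≈ a′·exp(−b′T) for
  naive-pool attrition; b > b′ means fetal clones vanish faster than the
  naive compartment, i.e. the decay is not a naive-fraction artifact.

A synthetic-cohort generator produces repertoires with the statistical
structure these analyses assume (Zipf clone sizes, TdT−/TdT+ mixture with
a fetal size advantage, twin transfer, exponential fetal decay), so the
whole pipeline is testable end to end without access to sequencing data.

## Worked example

```python
import numpy as np
import tcrshare as ts

# toy generation-probability check
m = ts.tiny_demo_model()
print("Pgen(CATT) =", m.pgen("CATT"))
print("Pgen(CAGTT) =", m.pgen("CAGTT"))

# cord blood: zero-insertion fraction vs abundance rank
tm, tp = ts.default_models("beta")
cfg = ts.CohortConfig(n_clones=20_000, fetal_fraction=0.3, fetal_advantage=10.0, seed=1)
cord = ts.simulate_cord_blood(tm, tp, cfg)
for prof in ts.profile_by_rank(cord, tp, bin_size=3000)[:3]:
    print(f"ranks {prof.label:>12}: mean insertions {prof.mean_insertions:.2f}, F0 = {prof.f0:.3f}")

# aging: decay of zero-insertion clonotypes vs naive-pool attrition
table = ts.simulate_aging_series(np.linspace(6, 90, 50),
                                 (0.00363, 0.016696, 0.0272, 0.68, 0.01485),
                                 noise_sd=0.002, rng_seed=1)
obs = [ts.AgingObservation(r.donor, r.age, r.Z, r.N) for r in table.itertuples()]
fit = ts.fit_decay_models(obs)
print(f"zero-insertion decay b = {fit.b:.4f}/yr  (t = {ts.characteristic_time(fit.b):.0f} y)")
print(f"naive-pool decay    b' = {fit.b_naive:.4f}/yr (t = {ts.characteristic_time(fit.b_naive):.0f} y)")
```

prints

```
Pgen(CATT) = 0.6
Pgen(CAGTT) = 0.1
ranks       1-3000: mean insertions 1.03, F0 = 0.868
ranks    3001-6000: mean insertions 1.31, F0 = 0.806
ranks    6001-9000: mean insertions 2.79, F0 = 0.426
zero-insertion decay b = 0.0317/yr  (t = 32 y)
naive-pool decay    b' = 0.0149/yr (t = 67 y)
```

The demo model's universe has five sequences: `CATT` arises from the
unique zero-insertion scenario (probability 0.6), each one-insertion
variant has probability 0.4 × 0.25. In the simulated cord blood the most
abundant clones are strongly enriched in germline-matchable
(zero-insertion) sequences, and the enrichment fades with rank. The aging
fit recovers a fetal decay rate of roughly 0.03/yr — a characteristic
persistence of a few decades — about twice the naive-pool attrition rate.

A CLI mirrors the library: `tcrshare run --config pipeline.yaml` executes
simulate → profile → sharing → aging from a single YAML config and writes
TSV outputs plus a checksummed manifest; `simulate-cohort`,
`insertion-profile`, `sharing` and `aging-fit` run single stages.

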