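"""Clonotype sharing between repertoires and its model predictions.

The *normalized sharing number* of two clonesets is the number of
clonotype keys they have in common divided by the product of the cloneset
sizes.  In the regime of rare convergent recombination it estimates the
probability that two independent recombination events produce the same
sequence, and is therefore comparable across sequencing depths.

Model predictions come from Monte Carlo: synthetic clonesets of distinct
sequences are drawn from each individual's generative model, optionally
restricted by reading frame, and the sharing analysis is repeated on them.
For productive (in-frame) repertoires the shared count is reweighted by
per-sequence selection factors Q:

    1/(|S1| |S2|) * sum_{s in S1 ∩ S2} Q1(s) Q2(s)

Excess sharing beyond coincidence (as between monozygous twins) is
quantified by fitting the observed distribution of log10 Pgen among shared
sequences as a two-component mixture of "regular" sequences and
coincidentally shared ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .model import RecombinationModel
from .repertoire import Repertoire, rank_clonotypes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SharingResult:
    """Pairwise sharing with Poisson uncertainty on the shared count."""

    donor1: str
    donor2: str
    size1: int
    size2: int
    shared: int
    normalized: float
    sd: float


@dataclass(frozen=True)
class PgenMixtureFit:
    """Weight of the 'regular' component in a two-component Pgen mixture."""

    w: float
    sd: float
    n_bins_used: int
    excluded_bins: tuple[int, ...] = ()


@dataclass
class AbundanceClassSharing:
    size: int
    f0: float
    observed: float
    observed_sd: float
    predicted: float
    predicted_sd: float


@dataclass
class MixtureSharingCurve:
    """Observed vs mixture-model-predicted sharing per abundance class."""

    classes: list[AbundanceClassSharing]
    scale_factor: float

    def within_2sd_fraction(self) -> float:
        """Fraction of classes where scaled prediction is within 2 SD of data."""
        ok = 0
        for c in self.classes:
            sd = np.hypot(c.observed_sd, self.scale_factor * c.predicted_sd)
            if abs(c.observed - self.scale_factor * c.predicted) <= 2.0 * sd:
                ok += 1
        return ok / len(self.classes)


# --------------------------------------------------------- observed sharing


def normalized_sharing(
    r1: Repertoire, r2: Repertoire, key: str = "cdr3nt"
) -> SharingResult:
    """Shared clonotype count normalized by the product of cloneset sizes."""
    if len(r1) == 0 or len(r2) == 0:
        raise ValueError("repertoires must be non-empty")
    if r1.chain != r2.chain:
        raise ValueError(f"chain mismatch: {r1.chain} vs {r2.chain}")
    s1, s2 = r1.keyset(key), r2.keyset(key)
    return _sharing_from_sets(s1, s2, r1.donor_id, r2.donor_id)


def _sharing_from_sets(
    s1: set, s2: set, donor1: str = "", donor2: str = ""
) -> SharingResult:
    shared = len(s1 & s2)
    denom = len(s1) * len(s2)
    return SharingResult(
        donor1, donor2, len(s1), len(s2), shared, shared / denom,
        float(np.sqrt(shared)) / denom,
    )


# ------------------------------------------------------- synthetic clonesets


def _passes_frame(seq: str, frame_filter: str | None) -> bool:
    if frame_filter in (None, "none"):
        return True
    if frame_filter == "out_of_frame":
        return len(seq) % 3 != 0
    if frame_filter == "in_frame":
        return len(seq) % 3 == 0
    raise ValueError(f"unknown frame filter {frame_filter!r}")


def sample_distinct_sequences(
    model: RecombinationModel,
    n: int,
    rng: np.random.Generator,
    frame_filter: str | None = None,
    max_attempts_factor: int = 400,
) -> list[str]:
    """Draw until ``n`` distinct sequences pass the frame filter."""
    if n < 1:
        raise ValueError("n must be >= 1")
    seen: dict[str, None] = {}
    attempts = 0
    limit = max(10_000, max_attempts_factor * n)
    while len(seen) < n:
        if attempts >= limit:
            raise RuntimeError(
                f"could not draw {n} distinct sequences passing filter "
                f"{frame_filter!r} in {limit} attempts; the filter may be "
                "unsatisfiable or the model's diversity too low"
            )
        seq, _ = model.sample(rng)
        attempts += 1
        if _passes_frame(seq, frame_filter):
            seen.setdefault(seq, None)
    return list(seen)


def predict_sharing_mc(
    model1: RecombinationModel,
    model2: RecombinationModel,
    n1: int,
    n2: int,
    frame_filter: str | None = "out_of_frame",
    replicates: int = 10,
    rng_seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo predicted normalized sharing between two models.

    Per replicate, distinct-clonotype sets of sizes n1 and n2 are drawn
    from the two models and their normalized sharing computed; returns the
    mean and SD over replicates.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(rng_seed)
    vals = []
    for _ in range(replicates):
        s1 = set(sample_distinct_sequences(model1, n1, rng, frame_filter))
        s2 = set(sample_distinct_sequences(model2, n2, rng, frame_filter))
        vals.append(len(s1 & s2) / (n1 * n2))
    return float(np.mean(vals)), float(np.std(vals, ddof=1))


def predict_sharing_inframe_weighted(
    sample1: set[str],
    q1: Mapping[str, float],
    sample2: set[str],
    q2: Mapping[str, float],
) -> float:
    """Q-reweighted normalized sharing of two synthetic in-frame samples.

    Returns ``1/(|S1||S2|) * sum_{s in S1 ∩ S2} Q1(s) Q2(s)``; with all
    Q = 1 this reduces to the unweighted normalized sharing.
    """
    total = 0.0
    for s in sample1 & sample2:
        if s not in q1 or s not in q2:
            raise KeyError(f"missing Q factor for shared sequence {s!r}")
        total += q1[s] * q2[s]
    return total / (len(sample1) * len(sample2))


# -------------------------------------------------------- Pgen distributions


def pgen_distribution_of_shared(
    shared_keys: Sequence[str],
    model: RecombinationModel,
    bins: Sequence[float],
) -> tuple[np.ndarray, int]:
    """Normalized histogram of log10 Pgen over the shared set.

    Sequences with Pgen = 0 cannot be placed on the log scale; they are
    counted separately and reported as the second return value.
    """
    if len(shared_keys) == 0:
        raise ValueError("shared set is empty")
    vals = []
    n_zero = 0
    for s in shared_keys:
        p = model.pgen(s)
        if p == 0.0:
            n_zero += 1
        else:
            vals.append(np.log10(p))
    hist, _ = np.histogram(vals, bins=np.asarray(bins, dtype=float))
    total = hist.sum()
    return (hist / total if total else hist.astype(float)), n_zero


def coincidental_shared_pgen_reference(
    model: RecombinationModel,
    n1: int,
    n2: int,
    replicates: int = 10,
    rng_seed: int = 0,
    bins: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo reference distribution of log10 Pgen for shared sequences.

    Pools sequences found shared between replicate synthetic cloneset
    pairs; sharing weights sequences by their recurrence probability, so
    this reference is shifted toward higher Pgen relative to the generic
    generated-sequence distribution.  Returns (normalized histogram, bin
    edges).
    """
    rng = np.random.default_rng(rng_seed)
    pooled: list[str] = []
    for _ in range(replicates):
        s1 = set(sample_distinct_sequences(model, n1, rng))
        s2 = set(sample_distinct_sequences(model, n2, rng))
        pooled.extend(s1 & s2)
    if not pooled:
        raise RuntimeError(
            "no shared sequences found in any replicate; increase n1/n2"
        )
    logp = np.array([np.log10(model.pgen(s)) for s in pooled])
    if bins is None:
        bins = np.arange(np.floor(logp.min()) - 1.0, np.ceil(logp.max()) + 1.0, 0.5)
    hist, edges = np.histogram(logp, bins=np.asarray(bins, dtype=float))
    return hist / hist.sum(), edges


def fit_pgen_mixture(
    observed_counts: Sequence[float],
    regular_hist: Sequence[float],
    coincidental_hist: Sequence[float],
    n_boot: int = 200,
    rng_seed: int = 0,
) -> PgenMixtureFit:
    """Maximum-likelihood weight of the regular component.

    Fits observed bin counts as multinomial draws from
    ``w * regular + (1 - w) * coincidental`` on a 1-d bounded optimizer;
    the SD comes from a multinomial bootstrap.  Observed bins outside the
    support of both components are excluded with a warning.
    """
    obs = np.asarray(observed_counts, dtype=float)
    reg = np.asarray(regular_hist, dtype=float)
    coi = np.asarray(coincidental_hist, dtype=float)
    if not (obs.shape == reg.shape == coi.shape):
        raise ValueError("all three histograms must share the same bins")
    reg = reg / reg.sum()
    coi = coi / coi.sum()
    bad = (obs > 0) & (reg == 0) & (coi == 0)
    if bad.any():
        logger.warning(
            "%d observed bin(s) outside the support of both components excluded",
            int(bad.sum()),
        )
    use = ~bad
    excluded = tuple(np.flatnonzero(bad))

    def fit_once(counts: np.ndarray) -> float:
        def nll(w: float) -> float:
            mix = w * reg[use] + (1.0 - w) * coi[use]
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = np.where(counts[use] > 0, counts[use] * np.log(mix), 0.0)
            return -float(np.sum(ll))

        res = optimize.minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded")
        # the boundary can beat the interior optimum
        cands = [0.0, 1.0, float(res.x)]
        return min(cands, key=nll)

    w_hat = fit_once(obs)
    rng = np.random.default_rng(rng_seed)
    total = int(round(obs.sum()))
    p = obs / obs.sum()
    boots = [
        fit_once(rng.multinomial(total, p).astype(float)) for _ in range(n_boot)
    ]
    return PgenMixtureFit(w_hat, float(np.std(boots, ddof=1)), int(use.sum()), excluded)


# ------------------------------------------------- sharing vs abundance (F0)


def sharing_vs_abundance(
    r1: Repertoire,
    r2: Repertoire,
    model: RecombinationModel,
    classes: Sequence[int],
    replicates: int = 5,
    rng_seed: int = 0,
    frame_filter: str | None = None,
    key: str = "cdr3nt",
) -> MixtureSharingCurve:
    """Observed and mixture-model-predicted sharing per abundance class.

    For each cumulative top-C class the observed normalized sharing is
    computed on the top-C clonotypes of both repertoires.  The prediction
    draws, per side, an artificial cloneset of C distinct model-generated
    sequences mixing zero-insertion-consistent sequences (group A) and the
    rest (group B) in proportions F0(C) / 1 - F0(C), where F0(C) is
    measured from the data class itself.  A single global multiplicative
    scale factor is fit by least squares and reported, never silently
    applied.
    """
    ranked1 = rank_clonotypes(r1)
    ranked2 = rank_clonotypes(r2)
    cmax = max(classes)
    if sorted(classes) != list(classes) or len(set(classes)) != len(classes):
        raise ValueError("classes must be strictly increasing")
    if cmax > min(len(ranked1), len(ranked2)):
        raise ValueError("largest class exceeds a repertoire size")

    observed = []
    f0s = []
    need_a = 0
    for c in classes:
        top1 = ranked1[:c]
        top2 = ranked2[:c]
        s1 = {cl.cdr3_nt for cl in top1}
        s2 = {cl.cdr3_nt for cl in top2}
        res = _sharing_from_sets(s1, s2, r1.donor_id, r2.donor_id)
        observed.append(res)
        pooled = top1 + top2
        f0 = np.mean([model.is_zero_insertion_consistent(cl.cdr3_nt) for cl in pooled])
        f0s.append(float(f0))
        need_a = max(need_a, int(round(f0 * c)))

    rng = np.random.default_rng(rng_seed)
    pools = []
    for _ in range(2):
        group_a: dict[str, None] = {}
        group_b: dict[str, None] = {}
        attempts, limit = 0, max(200_000, 500 * cmax)
        while len(group_a) < need_a + 1 or len(group_b) < cmax:
            if attempts >= limit:
                raise RuntimeError("could not fill A/B sequence pools; model too restrictive")
            seq, _ = model.sample(rng)
            attempts += 1
            if not _passes_frame(seq, frame_filter):
                continue
            if model.is_zero_insertion_consistent(seq):
                group_a.setdefault(seq, None)
            else:
                group_b.setdefault(seq, None)
        pools.append((np.array(list(group_a)), np.array(list(group_b))))

    out = []
    for c, f0, obs in zip(classes, f0s, observed):
        n_a = int(round(f0 * c))
        vals = []
        for _ in range(replicates):
            sides = []
            for a_pool, b_pool in pools:
                pick_a = rng.choice(a_pool, size=n_a, replace=False)
                pick_b = rng.choice(b_pool, size=c - n_a, replace=False)
                sides.append(set(pick_a) | set(pick_b))
            vals.append(len(sides[0] & sides[1]) / (c * c))
        out.append(
            AbundanceClassSharing(
                c,
                f0,
                obs.normalized,
                obs.sd,
                float(np.mean(vals)),
                float(np.std(vals, ddof=1)),
            )
        )

    pred = np.array([c.predicted for c in out])
    obs_v = np.array([c.observed for c in out])
    denom = float(pred @ pred)
    scale = float(obs_v @ pred / denom) if denom > 0 else 1.0
    return MixtureSharingCurve(out, scale)
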