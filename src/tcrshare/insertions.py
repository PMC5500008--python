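"""Insertion-length statistics for repertoire subsets.

Two estimators are provided for the mean number of N insertions in a group
of sequences:

* the per-sequence *posterior mean*: the expected number of inserted
  nucleotides given the sequence, averaging over all recombination
  scenarios weighted by their posterior probability; and
* a *restricted EM* that re-estimates only the insertion-length
  distribution(s) for the group, keeping segment choice and deletion
  profiles fixed at the full-repertoire model.

The zero-insertion-consistent fraction F0 uses germline matchability (a
scenario with no insertions exists), not posterior weight, so it can be
measured directly from data without the model's insertion distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .model import RecombinationModel
from .repertoire import Repertoire, rank_clonotypes, slice_bins, slice_top_classes

logger = logging.getLogger(__name__)


# ------------------------------------------------------------ scenario tables


def scenario_insertion_weights(
    model: RecombinationModel, seq: str
) -> list[tuple[tuple[int, ...], float]]:
    """Per-scenario base weights grouped by insertion lengths.

    Returns ``[(lengths, weight), ...]`` where ``lengths`` is ``(l,)`` for
    VJ or ``(l_vd, l_dj)`` for VDJ and ``weight`` is the scenario
    probability with the insertion-length factor divided out.  Pgen under
    any insertion distribution q is ``sum(weight * q[lengths])``.
    """
    return sorted(model.insertion_weight_table(seq).items())


def insertion_posterior_mean(model: RecombinationModel, seq: str) -> float | None:
    """Expected total number of inserted nucleotides given the sequence.

    Returns None when the sequence has zero likelihood under the model
    (no scenario exists), which callers report as missing.
    """
    table = scenario_insertion_weights(model, seq)
    if model.variant == "VJ":
        weights = [w * model.p_ins[l[0]] for l, w in table]
    else:
        weights = [w * model.p_ins_vd[l[0]] * model.p_ins_dj[l[1]] for l, w in table]
    total = sum(weights)
    if total == 0.0:
        return None
    return sum(w * sum(l) for (l, _), w in zip(table, weights)) / total


# ---------------------------------------------------------------- EM fitting


@dataclass
class EMResult:
    """Restricted EM output: insertion distribution(s) and diagnostics."""

    p_ins: np.ndarray | None
    p_ins_vd: np.ndarray | None
    p_ins_dj: np.ndarray | None
    log_likelihoods: list[float]
    n_used: int
    skipped: list[str]
    converged: bool

    @property
    def mean_insertions(self) -> float:
        if self.p_ins is not None:
            return float(np.arange(self.p_ins.size) @ self.p_ins)
        m1 = float(np.arange(self.p_ins_vd.size) @ self.p_ins_vd)
        m2 = float(np.arange(self.p_ins_dj.size) @ self.p_ins_dj)
        return m1 + m2


def em_insertion_distribution(
    model: RecombinationModel,
    sequences: Sequence[str],
    max_iter: int = 200,
    tol: float = 1e-8,
) -> EMResult:
    """Re-estimate only the insertion-length distribution(s) by EM.

    The E-step computes the posterior over enumerated scenarios per
    sequence; the M-step sets P_ins(l) proportional to the total posterior
    mass at insertion length l.  All other model parameters stay fixed.
    The log-likelihood is checked to be non-decreasing at every iteration.
    """
    if len(sequences) == 0:
        raise ValueError("empty sequence list")
    tables = []
    skipped: list[str] = []
    for s in sequences:
        t = scenario_insertion_weights(model, s)
        if not t:
            skipped.append(s)
        else:
            tables.append(t)
    if skipped:
        logger.warning(
            "%d sequence(s) have zero likelihood under the model and were excluded",
            len(skipped),
        )
    if not tables:
        raise ValueError("no sequence has positive likelihood under the model")

    # flatten to arrays: one row per (sequence, length-combo)
    idx = np.concatenate(
        [np.full(len(t), i) for i, t in enumerate(tables)]
    ).astype(np.intp)
    base = np.concatenate([[w for _, w in t] for t in tables])
    n = len(tables)
    vdj = model.variant == "VDJ"
    if vdj:
        l1 = np.concatenate([[l[0] for l, _ in t] for t in tables]).astype(np.intp)
        l2 = np.concatenate([[l[1] for l, _ in t] for t in tables]).astype(np.intp)
        k1, k2 = model.p_ins_vd.size, model.p_ins_dj.size
        p1 = np.full(k1, 1.0 / k1)
        p2 = np.full(k2, 1.0 / k2)
    else:
        l1 = np.concatenate([[l[0] for l, _ in t] for t in tables]).astype(np.intp)
        k1 = model.p_ins.size
        p1 = np.full(k1, 1.0 / k1)

    logls: list[float] = []
    converged = False
    for _ in range(max_iter):
        w = base * p1[l1] * (p2[l2] if vdj else 1.0)
        lik = np.zeros(n)
        np.add.at(lik, idx, w)
        logl = float(np.log(lik).sum())
        if logls and logl < logls[-1] - 1e-8 * (1.0 + abs(logls[-1])):
            raise RuntimeError(
                f"EM log-likelihood decreased: {logls[-1]} -> {logl}"
            )
        if logls and abs(logl - logls[-1]) < tol:
            logls.append(logl)
            converged = True
            break
        logls.append(logl)
        resp = w / lik[idx]
        c1 = np.bincount(l1, weights=resp, minlength=k1)
        p1 = c1 / c1.sum()
        if vdj:
            c2 = np.bincount(l2, weights=resp, minlength=k2)
            p2 = c2 / c2.sum()

    if vdj:
        return EMResult(None, p1, p2, logls, n, skipped, converged)
    return EMResult(p1, None, None, logls, n, skipped, converged)


# ------------------------------------------------------------- rank profiles


@dataclass
class AbundanceBinProfile:
    """Insertion statistics for one abundance bin or cumulative class."""

    label: str
    start_rank: int
    end_rank: int
    n: int
    mean_insertions: float
    se_insertions: float
    f0: float
    f0_sd: float
    n_missing: int = 0
    flagged: bool = False


def _bin_profile(
    label: str,
    start: int,
    end: int,
    clones,
    model: RecombinationModel,
    mode: str,
) -> AbundanceBinProfile:
    seqs = [c.cdr3_nt for c in clones]
    n = len(seqs)
    zero = sum(model.is_zero_insertion_consistent(s) for s in seqs)
    f0 = zero / n
    f0_sd = float(np.sqrt(f0 * (1.0 - f0) / n))
    if mode == "posterior":
        means = [insertion_posterior_mean(model, s) for s in seqs]
        ok = np.array([m for m in means if m is not None])
        n_missing = n - ok.size
        if ok.size == 0:
            return AbundanceBinProfile(
                label, start, end, n, np.nan, np.nan, f0, f0_sd, n_missing, True
            )
        mean = float(ok.mean())
        se = float(ok.std(ddof=1) / np.sqrt(ok.size)) if ok.size > 1 else 0.0
        return AbundanceBinProfile(
            label, start, end, n, mean, se, f0, f0_sd, n_missing, n_missing > 0
        )
    if mode != "em":
        raise ValueError(f"mode must be 'posterior' or 'em', got {mode!r}")
    res = em_insertion_distribution(model, seqs)
    if res.p_ins is not None:
        support = np.arange(res.p_ins.size)
        var = float(((support - res.mean_insertions) ** 2) @ res.p_ins)
    else:
        m1 = np.arange(res.p_ins_vd.size) @ res.p_ins_vd
        m2 = np.arange(res.p_ins_dj.size) @ res.p_ins_dj
        var = float(
            ((np.arange(res.p_ins_vd.size) - m1) ** 2) @ res.p_ins_vd
            + ((np.arange(res.p_ins_dj.size) - m2) ** 2) @ res.p_ins_dj
        )
    se = float(np.sqrt(var / res.n_used))
    return AbundanceBinProfile(
        label,
        start,
        end,
        n,
        res.mean_insertions,
        se,
        f0,
        f0_sd,
        len(res.skipped),
        bool(res.skipped),
    )


def profile_by_rank(
    rep: Repertoire,
    model: RecombinationModel,
    *,
    bin_size: int | None = 3000,
    classes: Sequence[int] | None = None,
    mode: str = "posterior",
) -> list[AbundanceBinProfile]:
    """Per-rank-bin mean insertion numbers and zero-insertion fractions.

    With ``bin_size``, consecutive disjoint groups of that many clonotypes
    in decreasing abundance; with ``classes``, cumulative top-K classes.
    Mean insertions use the per-sequence posterior mean (default) or a
    bin-level restricted EM; the standard error is sd/sqrt(n), and F0
    carries a binomial standard deviation.
    """
    ranked = rank_clonotypes(rep)
    out = []
    if classes is not None:
        for k, clones in slice_top_classes(ranked, classes):
            out.append(_bin_profile(f"top{k}", 1, len(clones), clones, model, mode))
    else:
        for (start, end), clones in slice_bins(ranked, bin_size):
            out.append(_bin_profile(f"{start}-{end}", start, end, clones, model, mode))
    return out


def fit_individual_model(
    base_model: RecombinationModel,
    sequences: Sequence[str],
    max_sequences: int = 2000,
    rng_seed: int = 0,
) -> RecombinationModel:
    """Per-individual generative model: insertion distribution re-fit by EM.

    Mirrors inferring a recombination model from each donor's own
    (out-of-frame) cloneset while keeping segment-choice and deletion
    parameters shared: only the insertion-length distribution(s) are
    re-estimated, which captures donor-specific features such as an excess
    of zero-insertion (fetal) sequences.  A random subsample caps the EM
    input size.
    """
    seqs = list(sequences)
    if len(seqs) > max_sequences:
        rng = np.random.default_rng(rng_seed)
        seqs = list(rng.choice(seqs, size=max_sequences, replace=False))
    res = em_insertion_distribution(base_model, seqs)
    if base_model.variant == "VJ":
        return base_model.with_insertion_distribution(p_ins=res.p_ins)
    return base_model.with_insertion_distribution(
        p_ins_vd=res.p_ins_vd, p_ins_dj=res.p_ins_dj
    )


def compare_insertion_means(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Welch two-sided t-test on per-sequence posterior-mean insertions."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    if a.std() == 0.0 and b.std() == 0.0 and a.mean() == b.mean():
        logger.info("degenerate identical zero-variance groups: p = 1 by convention")
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
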