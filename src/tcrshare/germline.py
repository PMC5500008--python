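"""Synthetic germline segments and default recombination models.

The segment sequences here are synthetic: reproducibly generated random
DNA, not human germline alleles.  They give the generative models enough
combinatorial diversity (segment choice x deletions x insertions) to
reproduce the statistical structure of junctional diversity — heavy
convergent recombination for zero-insertion sequences, vanishingly small
generation probabilities for long N-insertion runs — without shipping any
reference database.

A "TdT-" variant of each model has its insertion-length distribution
concentrated at zero, emulating fetal rearrangement under downregulated
terminal deoxynucleotidyl transferase; all other parameters are shared
with the "TdT+" model, since TdT only affects N insertions.
"""

from __future__ import annotations

import numpy as np

from .model import GermlineSegment, RecombinationModel

_SEGMENT_SEED = 987_001


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _geometric(ratio: float, max_value: int) -> np.ndarray:
    p = ratio ** np.arange(max_value + 1)
    return p / p.sum()


def synthetic_segments(chain: str, seed: int = _SEGMENT_SEED) -> list[GermlineSegment]:
    """Synthetic germline segment set for one chain ("alpha" or "beta")."""
    rng = np.random.default_rng(seed if chain == "alpha" else seed + 1)
    segs: list[GermlineSegment] = []
    if chain == "alpha":
        prefix = "SYNA"
        n_v, n_j = 16, 12
    elif chain == "beta":
        prefix = "SYNB"
        n_v, n_j = 12, 8
    else:
        raise ValueError(f"chain must be alpha or beta, got {chain!r}")
    for i in range(n_v):
        segs.append(GermlineSegment(f"{prefix}V{i + 1}", "V", _random_dna(rng, 14)))
    if chain == "beta":
        for i in range(3):
            segs.append(GermlineSegment(f"{prefix}D{i + 1}", "D", _random_dna(rng, 12)))
    for i in range(n_j):
        segs.append(GermlineSegment(f"{prefix}J{i + 1}", "J", _random_dna(rng, 14)))
    return segs


def _joint_choice(
    rng: np.random.Generator, groups: list[list[GermlineSegment]]
) -> dict[tuple[str, ...], float]:
    """Joint segment-choice distribution with log-normal usage tilts."""
    keys = [()]
    for group in groups:
        keys = [k + (s.name,) for k in keys for s in group]
    w = rng.lognormal(0.0, 0.6, size=len(keys))
    w /= w.sum()
    return dict(zip(keys, map(float, w)))


def build_model(
    chain: str = "alpha",
    *,
    tdt_minus: bool = False,
    seed: int = _SEGMENT_SEED,
) -> RecombinationModel:
    """Default synthetic model: VJ for alpha, VDJ for beta.

    Deletion profiles are truncated geometrics; insertion lengths are
    geometric with mean ~3 per junction (TdT+) or a point mass at zero
    (TdT-); inserted nucleotides carry a slight GC bias.
    """
    segs = synthetic_segments(chain, seed)
    rng = np.random.default_rng(seed + 17)
    by_kind: dict[str, list[GermlineSegment]] = {"V": [], "D": [], "J": []}
    for s in segs:
        by_kind[s.kind].append(s)

    p_del_v = {s.name: _geometric(0.70, 10) for s in by_kind["V"]}
    p_del_j = {s.name: _geometric(0.70, 10) for s in by_kind["J"]}
    p_nt = (0.22, 0.28, 0.28, 0.22)

    if chain == "alpha":
        p_choice = _joint_choice(rng, [by_kind["V"], by_kind["J"]])
        p_ins = np.zeros(11)
        if tdt_minus:
            p_ins[0] = 1.0
        else:
            p_ins = _geometric(0.75, 10)
        return RecombinationModel(
            "VJ", segs, p_choice, p_del_v, p_del_j, p_ins=p_ins, p_nt=p_nt
        )

    p_choice = _joint_choice(rng, [by_kind["V"], by_kind["D"], by_kind["J"]])
    p_del_d5 = {s.name: _geometric(0.65, 6) for s in by_kind["D"]}
    p_del_d3 = {s.name: _geometric(0.65, 6) for s in by_kind["D"]}
    if tdt_minus:
        p_ins_vd = np.zeros(9)
        p_ins_vd[0] = 1.0
        p_ins_dj = p_ins_vd.copy()
    else:
        p_ins_vd = _geometric(0.70, 8)
        p_ins_dj = _geometric(0.70, 8)
    return RecombinationModel(
        "VDJ",
        segs,
        p_choice,
        p_del_v,
        p_del_j,
        p_ins_vd=p_ins_vd,
        p_ins_dj=p_ins_dj,
        p_del_d5=p_del_d5,
        p_del_d3=p_del_d3,
        p_nt=p_nt,
    )


def tiny_demo_model() -> RecombinationModel:
    """Minimal VJ model with a 5-sequence universe, handy for demos and checks.

    One V ("CA") and one J ("TT"), no deletions, insertion length 0 with
    probability 0.6 or 1 with probability 0.4, uniform inserted
    nucleotides.  The realizable sequences are CATT (Pgen 0.6) and
    CA{A,C,G,T}TT (Pgen 0.1 each).
    """
    return RecombinationModel(
        "VJ",
        [GermlineSegment("V0", "V", "CA"), GermlineSegment("J0", "J", "TT")],
        {("V0", "J0"): 1.0},
        {"V0": [1.0]},
        {"J0": [1.0]},
        p_ins=[0.6, 0.4],
    )
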