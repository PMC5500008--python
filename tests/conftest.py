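"""Shared fixtures: toy models and an independent brute-force Pgen oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from tcrshare.model import GermlineSegment, RecombinationModel

NT = "ACGT"


@pytest.fixture
def m0() -> RecombinationModel:
    """V='CA', J='TT', no deletions, P_ins = (0.6, 0.4), uniform nucleotides."""
    return RecombinationModel(
        "VJ",
        [GermlineSegment("V0", "V", "CA"), GermlineSegment("J0", "J", "TT")],
        {("V0", "J0"): 1.0},
        {"V0": [1.0]},
        {"J0": [1.0]},
        p_ins=[0.6, 0.4],
    )


@pytest.fixture
def m1() -> RecombinationModel:
    """V='CAT' with 0 or 1 deletions (p=0.5 each), J='TT', zero insertions."""
    return RecombinationModel(
        "VJ",
        [GermlineSegment("V0", "V", "CAT"), GermlineSegment("J0", "J", "TT")],
        {("V0", "J0"): 1.0},
        {"V0": [0.5, 0.5]},
        {"J0": [1.0]},
        p_ins=[1.0],
    )


def random_toy_model(rng: np.random.Generator) -> RecombinationModel:
    """Small random VJ or VDJ model with full-support distributions."""
    variant = "VJ" if rng.random() < 0.5 else "VDJ"

    def dna(lo, hi):
        return "".join(NT[i] for i in rng.integers(0, 4, size=rng.integers(lo, hi + 1)))

    def cat(k):
        return rng.dirichlet(np.ones(k) * 2.0)

    n_v, n_j = rng.integers(1, 3), rng.integers(1, 3)
    segs = [GermlineSegment(f"V{i}", "V", dna(3, 5)) for i in range(n_v)]
    segs += [GermlineSegment(f"J{i}", "J", dna(2, 4)) for i in range(n_j)]
    if variant == "VDJ":
        segs.append(GermlineSegment("D0", "D", dna(3, 4)))
    p_del_v = {s.name: cat(min(3, len(s.sequence) + 1)) for s in segs if s.kind == "V"}
    p_del_j = {s.name: cat(min(3, len(s.sequence) + 1)) for s in segs if s.kind == "J"}
    p_nt = rng.dirichlet(np.ones(4) * 4.0)
    if variant == "VJ":
        keys = [(v.name, j.name) for v in segs if v.kind == "V" for j in segs if j.kind == "J"]
        w = rng.dirichlet(np.ones(len(keys)))
        return RecombinationModel(
            "VJ", segs, dict(zip(keys, w)), p_del_v, p_del_j,
            p_ins=cat(3), p_nt=p_nt,
        )
    keys = [
        (v.name, "D0", j.name)
        for v in segs
        if v.kind == "V"
        for j in segs
        if j.kind == "J"
    ]
    w = rng.dirichlet(np.ones(len(keys)))
    return RecombinationModel(
        "VDJ", segs, dict(zip(keys, w)), p_del_v, p_del_j,
        p_ins_vd=cat(3), p_ins_dj=cat(3),
        p_del_d5={"D0": cat(2)}, p_del_d3={"D0": cat(2)},
        p_nt=p_nt,
    )


def brute_pgen(model: RecombinationModel, seq: str) -> float:
    """Exhaustive Pgen oracle: enumerate every latent choice including
    inserted strings, assemble the realization with plain string ops, and
    sum the probabilities of those equal to ``seq``.  Independent of the
    model's own Pgen summation path."""
    nt_p = {c: model.p_nt[i] for i, c in enumerate(NT)}
    total = 0.0
    for key, pc in model.p_choice.items():
        vseq = model.segment(key[0]).sequence
        jseq = model.segment(key[-1]).sequence
        for dv, pv in enumerate(model.p_del_v[key[0]]):
            for dj, pj in enumerate(model.p_del_j[key[-1]]):
                left = vseq[: len(vseq) - dv]
                right = jseq[dj:]
                if model.variant == "VJ":
                    for ell, pl in enumerate(model.p_ins):
                        for ins in itertools.product(NT, repeat=ell):
                            s = left + "".join(ins) + right
                            if s == seq:
                                total += pc * pv * pj * pl * float(
                                    np.prod([nt_p[c] for c in ins])
                                )
                else:
                    dseq = model.segment(key[1]).sequence
                    for d5, p5 in enumerate(model.p_del_d5[key[1]]):
                        for d3, p3 in enumerate(model.p_del_d3[key[1]]):
                            core = dseq[d5 : len(dseq) - d3]
                            for l1, pl1 in enumerate(model.p_ins_vd):
                                for l2, pl2 in enumerate(model.p_ins_dj):
                                    for i1 in itertools.product(NT, repeat=l1):
                                        for i2 in itertools.product(NT, repeat=l2):
                                            s = (
                                                left
                                                + "".join(i1)
                                                + core
                                                + "".join(i2)
                                                + right
                                            )
                                            if s == seq:
                                                total += (
                                                    pc * pv * pj * p5 * p3 * pl1 * pl2
                                                    * float(np.prod([nt_p[c] for c in i1 + i2]))
                                                )
    return total
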