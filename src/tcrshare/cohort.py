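"""Synthetic repertoire cohorts with the statistical structure of real data.

The generator emulates the features the downstream analyses rely on:

* heavy-tailed (Zipf-like) clone-size distributions;
* a TdT-/TdT+ clonotype mixture in which fetal (TdT-, zero-insertion)
  clones carry a multiplicative size advantage — the "vacant ecological
  niche" of the early repertoire — so the zero-insertion fraction rises
  with clonal abundance in cord blood and young naive repertoires;
* clone-level survival of fetal clones with probability exp(-b * age),
  with gradual replacement by post-natal TdT+ clones;
* memory compartments whose clone sizes are drawn independently of
  insertion number (clonal expansion resets sizes);
* in-utero transfer of identical nucleotide clonotypes between twin
  pairs, drawn from the full cord mixture and therefore including
  high-insertion, low-Pgen clones;
* per-clonotype selection factors Q and noisy aging tables.

All generators are deterministic given (config, seed); per-donor streams
are derived from the global seed so donors can be re-simulated in
isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .germline import build_model
from .model import RecombinationModel
from .repertoire import Clonotype, Repertoire

OUT_OF_FRAME_DEFAULTS = {"alpha": 0.13, "beta": 0.03}


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    ``fetal_fraction`` is the fraction of clones recombined under
    downregulated TdT (zero insertions) at birth; ``fetal_advantage``
    multiplies their clone sizes before rank assignment.  Decay rates are
    per year; the defaults follow the decay of abundant zero-insertion
    clonotypes (0.027/yr) and of the naive pool (0.01485/yr).
    Out-of-frame fractions default to 13% (alpha) and 3% (beta).
    """

    n_clones: int = 20_000
    zipf_exponent: float = 1.1
    fetal_fraction: float = 0.15
    fetal_advantage: float = 10.0
    fetal_decay_rate: float = 0.027
    naive_decay_rate: float = 0.01485
    twin_transfer: float = 0.5
    out_of_frame_fraction: Mapping[str, float] = field(
        default_factory=lambda: dict(OUT_OF_FRAME_DEFAULTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fetal_fraction", "twin_transfer"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for chain, v in self.out_of_frame_fraction.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"out_of_frame_fraction[{chain}] must be in [0, 1]")
        if self.fetal_decay_rate < 0 or self.naive_decay_rate < 0:
            raise ValueError("decay rates must be >= 0")
        if self.fetal_advantage < 1.0:
            raise ValueError("fetal_advantage must be >= 1")
        if self.zipf_exponent <= 0 or self.n_clones < 1:
            raise ValueError("zipf_exponent must be > 0 and n_clones >= 1")


@dataclass(frozen=True)
class DonorSpec:
    donor_id: str
    age: float
    compartment: str = "unpartitioned"
    chain: str = "beta"
    twin_partner: str | None = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be >= 0")


def default_models(chain: str = "beta") -> tuple[RecombinationModel, RecombinationModel]:
    """(TdT-, TdT+) model pair sharing germline and deletion profiles."""
    return build_model(chain, tdt_minus=True), build_model(chain, tdt_minus=False)


def _donor_rng(config: CohortConfig, *tokens: object) -> np.random.Generator:
    """Deterministic per-donor/per-role stream derived from the global seed."""
    hashes = [zlib.crc32(str(t).encode()) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence([config.seed % (2**31), *hashes]))


def _clone_sizes(
    n: int,
    exponent: float,
    rng: np.random.Generator,
    advantage: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Zipf-law sizes: P(size >= s) ~ s**(-exponent).

    The (fetal) size advantage multiplies the continuous size before
    integer truncation, with per-clone lognormal variability so fetal
    clones do not pile up at a single size floor.
    """
    u = rng.random(n)
    base = u ** (-1.0 / exponent)
    adv = np.asarray(advantage, dtype=float)
    jitter = np.where(adv > 1.0, np.exp(0.5 * rng.standard_normal(n)), 1.0)
    return np.clip(np.floor(base * adv * jitter), 1, 1e7)


def _validate_models(
    tdt_minus: RecombinationModel, tdt_plus: RecombinationModel
) -> None:
    if tdt_minus.variant != tdt_plus.variant:
        raise ValueError("TdT- and TdT+ models must share the same variant")
    zero = (
        (tdt_minus.p_ins[0],)
        if tdt_minus.variant == "VJ"
        else (tdt_minus.p_ins_vd[0], tdt_minus.p_ins_dj[0])
    )
    if min(zero) < 0.99:
        raise ValueError("TdT- model must have P_ins(0) >= 0.99")
    segs_m = {s.name: s.sequence for k in ("V", "D", "J") for s in tdt_minus.segments_by_kind[k]}
    segs_p = {s.name: s.sequence for k in ("V", "D", "J") for s in tdt_plus.segments_by_kind[k]}
    if segs_m != segs_p:
        raise ValueError("TdT- and TdT+ models must share germline segments")


def _sample_pool(
    model: RecombinationModel,
    n: int,
    rng: np.random.Generator,
    oof_fraction: float | None,
    exclude: set[str] | None = None,
) -> list[str]:
    """Distinct sequences, optionally hitting a target out-of-frame fraction."""
    if n <= 0:
        return []
    exclude = exclude or set()
    if oof_fraction is None:
        quota = {None: n}
        cls = lambda s: None
    else:
        n_oof = int(round(n * oof_fraction))
        quota = {"oof": n_oof, "if": n - n_oof}
        cls = lambda s: "oof" if len(s) % 3 else "if"
    got: dict[str, str | None] = {}
    counts = {k: 0 for k in quota}
    attempts, limit = 0, max(100_000, 500 * n)
    while any(counts[k] < quota[k] for k in quota):
        if attempts >= limit:
            raise RuntimeError("could not assemble a distinct clone pool; model too restrictive")
        seq, _ = model.sample(rng)
        attempts += 1
        if seq in got or seq in exclude:
            continue
        c = cls(seq)
        if counts[c] < quota[c]:
            got[seq] = c
            counts[c] += 1
    seqs = list(got)
    rng.shuffle(seqs)
    return seqs


def _assemble(
    donor_id: str,
    chain: str,
    compartment: str,
    age: float | None,
    fetal_seqs: Sequence[str],
    other_seqs: Sequence[str],
    config: CohortConfig,
    rng: np.random.Generator,
    advantage: float,
) -> Repertoire:
    seqs = list(fetal_seqs) + list(other_seqs)
    adv = np.ones(len(seqs))
    adv[: len(fetal_seqs)] = advantage
    sizes = _clone_sizes(len(seqs), config.zipf_exponent, rng, advantage=adv)
    clonotypes = [
        Clonotype(cdr3_nt=s, count=int(c)) for s, c in zip(seqs, sizes)
    ]
    return Repertoire(
        donor_id=donor_id,
        chain=chain,
        clonotypes=clonotypes,
        compartment=compartment,
        age=age,
    )


def simulate_cord_blood(
    tdt_minus_model: RecombinationModel,
    tdt_plus_model: RecombinationModel,
    config: CohortConfig,
    donor_id: str = "cord",
    chain: str = "beta",
) -> Repertoire:
    """Cord-blood repertoire: fetal TdT- clones with a size advantage.

    A fraction ``fetal_fraction`` of clones is drawn from the TdT- model
    and has its clone sizes multiplied by ``fetal_advantage`` before rank
    assignment; the rest come from the TdT+ model.  With advantage > 1 the
    zero-insertion-consistent fraction decreases with abundance rank.
    """
    _validate_models(tdt_minus_model, tdt_plus_model)
    rng = _donor_rng(config, donor_id, "cord", chain)
    n = config.n_clones
    n_f = int(round(config.fetal_fraction * n))
    oof = config.out_of_frame_fraction.get(chain)
    fetal = _sample_pool(tdt_minus_model, n_f, rng, oof)
    rest = _sample_pool(tdt_plus_model, n - n_f, rng, oof, exclude=set(fetal))
    return _assemble(
        donor_id, chain, "cord", 0.0, fetal, rest, config, rng, config.fetal_advantage
    )


def simulate_adult(
    spec: DonorSpec,
    models: tuple[RecombinationModel, RecombinationModel],
    config: CohortConfig,
) -> Repertoire:
    """Adult repertoire for one donor and compartment.

    Naive (and unpartitioned) compartments keep fetal clones that survive
    with probability exp(-fetal_decay_rate * age), retaining their size
    advantage, topped up with post-natal TdT+ clones.  Memory compartments
    have the same clone composition but sizes drawn independently of
    insertion number (no advantage): clonal expansions reset sizes.
    """
    tdt_minus, tdt_plus = models
    _validate_models(tdt_minus, tdt_plus)
    rng = _donor_rng(config, spec.donor_id, spec.compartment, spec.chain)
    n = config.n_clones
    n_f = int(round(config.fetal_fraction * n))
    oof = config.out_of_frame_fraction.get(spec.chain)
    fetal = _sample_pool(tdt_minus, n_f, rng, oof)
    surv_p = float(np.exp(-config.fetal_decay_rate * spec.age))
    fetal = [s for s in fetal if rng.random() < surv_p]
    rest = _sample_pool(tdt_plus, n - len(fetal), rng, oof, exclude=set(fetal))
    advantage = 1.0 if spec.compartment == "memory" else config.fetal_advantage
    return _assemble(
        spec.donor_id,
        spec.chain,
        spec.compartment,
        spec.age,
        fetal,
        rest,
        config,
        rng,
        advantage,
    )


def simulate_twin_pair(
    spec1: DonorSpec,
    spec2: DonorSpec,
    models: tuple[RecombinationModel, RecombinationModel],
    config: CohortConfig,
) -> tuple[Repertoire, Repertoire]:
    """Twin repertoires with a shared in-utero clone pool.

    A fraction ``twin_transfer`` of each twin's fetal-era clones is
    present with identical nucleotide sequence in both repertoires.  The
    fetal-era pool is the full cord mixture: TdT- clones (size advantage)
    plus an equal-size cord TdT+ pool (ordinary sizes), so transferred
    clones include high-insertion, low-Pgen sequences.  Survival
    exp(-b * age) applies per twin; remaining clones are private.
    """
    tdt_minus, tdt_plus = models
    _validate_models(tdt_minus, tdt_plus)
    tau = config.twin_transfer
    n = config.n_clones
    n_f = int(round(config.fetal_fraction * n))
    n_sh = int(round(tau * n_f))
    oof = config.out_of_frame_fraction.get(spec1.chain)

    pair_key = "|".join(sorted([spec1.donor_id, spec2.donor_id]))
    rng_sh = _donor_rng(config, pair_key, "shared", spec1.chain)
    shared_minus = _sample_pool(tdt_minus, n_sh, rng_sh, oof)
    shared_plus = _sample_pool(tdt_plus, n_sh, rng_sh, oof, exclude=set(shared_minus))

    out = []
    for spec in (spec1, spec2):
        rng = _donor_rng(config, spec.donor_id, spec.compartment, spec.chain)
        exclude = set(shared_minus) | set(shared_plus)
        priv_minus = _sample_pool(tdt_minus, n_f - n_sh, rng, oof, exclude=exclude)
        exclude |= set(priv_minus)
        priv_plus = _sample_pool(tdt_plus, n_f - n_sh, rng, oof, exclude=exclude)
        surv_p = float(np.exp(-config.fetal_decay_rate * spec.age))
        fetal_minus = [s for s in shared_minus + priv_minus if rng.random() < surv_p]
        fetal_plus = [s for s in shared_plus + priv_plus if rng.random() < surv_p]
        exclude |= set(priv_plus)
        n_post = n - len(fetal_minus) - len(fetal_plus)
        post = _sample_pool(tdt_plus, n_post, rng, oof, exclude=exclude)
        out.append(
            _assemble(
                spec.donor_id,
                spec.chain,
                spec.compartment,
                spec.age,
                fetal_minus,
                fetal_plus + post,
                config,
                rng,
                config.fetal_advantage,
            )
        )
    return out[0], out[1]


def simulate_q_factors(
    rep: Repertoire, sigma: float, rng_seed: int = 0
) -> dict[str, float]:
    """Log-normal selection factors Q per in-frame CDR3 amino-acid sequence.

    Median 1, log-scale ``sigma``; deterministic per (sequence, seed) so
    repeated calls agree clone by clone.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out: dict[str, float] = {}
    found_inframe = False
    for c in rep.clonotypes:
        if c.frame != "in_frame" or c.has_stop:
            continue
        found_inframe = True
        aa = c.cdr3_aa or str(Seq(c.cdr3_nt).translate())
        if aa in out:
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence([rng_seed % (2**31), zlib.crc32(aa.encode())])
        )
        out[aa] = float(np.exp(sigma * rng.standard_normal()))
    if not found_inframe:
        raise ValueError("repertoire has no in-frame clonotypes")
    return out


def simulate_aging_series(
    ages: Sequence[float],
    true_params: tuple[float, float, float, float, float],
    noise_sd: float,
    per_age_k: int = 2000,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Aging table: Z = c + a exp(-b T) + noise, N = a' exp(-b' T) + noise."""
    c, a, b, a_p, b_p = true_params
    if min(c, a, b, a_p, b_p) < 0 or noise_sd < 0:
        raise ValueError("parameters and noise_sd must be >= 0")
    rng = np.random.default_rng(rng_seed)
    ages = np.asarray(ages, dtype=float)
    z = c + a * np.exp(-b * ages) + noise_sd * rng.standard_normal(ages.size)
    nv = a_p * np.exp(-b_p * ages) + noise_sd * rng.standard_normal(ages.size)
    return pd.DataFrame(
        {
            "donor": [f"D{i + 1}" for i in range(ages.size)],
            "age": ages,
            "Z": np.clip(z, 0.0, 1.0),
            "N": np.clip(nv, 0.0, 1.0),
            "K": per_age_k,
        }
    )
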