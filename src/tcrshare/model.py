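"""Generative model of V(D)J recombination at the CDR3 junction.

T-cell receptor chains are assembled by joining germline V and J segments
(alpha chain) or V, D and J segments (beta chain), randomly trimming
nucleotides from the joining ends, and inserting non-templated (N)
nucleotides at each junction.  This module implements a parametric model of
that process: a joint categorical distribution over segment choice,
per-segment deletion-length distributions, insertion-length distributions
for each junction, and an i.i.d. composition model for inserted
nucleotides.

The central quantity is the generation probability ``Pgen(s)``: the
probability that one recombination event produces the nucleotide sequence
``s``, obtained by summing the probabilities of every *scenario* (segment
choice, deletion counts, inserted strings) whose realization equals ``s``.
Because different scenarios can yield the same sequence (convergent
recombination), Pgen is a many-to-one marginal and must be computed by
explicit summation.

The model covers the junction region only: the (trimmed) V contribution is
a prefix and the (trimmed) J contribution a suffix of the modelled
sequence.  Deletions are non-negative; palindromic (P) nucleotides are not
modelled.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import yaml

NUCLEOTIDES = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}
STOP_CODONS = ("TAA", "TAG", "TGA")

_NORM_TOL = 1e-9


class ModelValidationError(ValueError):
    """Raised when model parameters violate the model contract."""


def _check_dna(seq: str, what: str = "sequence") -> None:
    if not seq and what == "sequence":
        raise ModelValidationError(f"empty {what}")
    bad = set(seq) - set(NUCLEOTIDES)
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)!r}")


def _as_prob_array(p: Sequence[float], what: str) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ModelValidationError(f"{what} must be a non-empty 1-d probability vector")
    if (arr < 0).any():
        raise ModelValidationError(f"{what} has negative entries")
    if abs(arr.sum() - 1.0) > _NORM_TOL:
        raise ModelValidationError(f"{what} does not sum to 1 (sum={arr.sum()!r})")
    return arr


@dataclass(frozen=True)
class GermlineSegment:
    """A germline gene segment (V, D or J) contributing to the junction."""

    name: str
    kind: str
    sequence: str

    def __post_init__(self) -> None:
        if self.kind not in ("V", "D", "J"):
            raise ModelValidationError(f"segment kind must be V, D or J, got {self.kind!r}")
        if not self.sequence:
            raise ModelValidationError(f"segment {self.name} has an empty sequence")
        _check_dna(self.sequence, f"segment {self.name}")


@dataclass(frozen=True)
class RecombinationScenario:
    """One concrete generative explanation of a sequence.

    ``segments`` holds segment names, ``(V, J)`` or ``(V, D, J)``;
    ``deletions`` holds ``(dV, dJ)`` or ``(dV, d5, d3, dJ)`` where d5/d3
    trim the 5'/3' ends of D; ``insertions`` holds the inserted string(s),
    ``(vj,)`` or ``(vd, dj)``.  ``probability`` is the product of all
    factor probabilities.
    """

    segments: tuple[str, ...]
    deletions: tuple[int, ...]
    insertions: tuple[str, ...]
    probability: float

    @property
    def total_insertions(self) -> int:
        return sum(len(s) for s in self.insertions)

    def is_zero_insertion(self) -> bool:
        return self.total_insertions == 0


def frame_class(cdr3_nt: str) -> tuple[str, bool]:
    """Classify a CDR3 nucleotide sequence by reading frame.

    Returns ``(frame, has_stop)`` where frame is ``"in_frame"`` iff the
    length is a multiple of 3 (out-of-frame rearrangements are
    nonproductive and carry a frameshift), and ``has_stop`` is True when
    any complete codon read from position 0 is TAA/TAG/TGA.
    """
    if not cdr3_nt:
        raise ValueError("empty sequence")
    _check_dna(cdr3_nt)
    frame = "in_frame" if len(cdr3_nt) % 3 == 0 else "out_of_frame"
    has_stop = any(
        cdr3_nt[i : i + 3] in STOP_CODONS for i in range(0, len(cdr3_nt) - 2, 3)
    )
    return frame, has_stop


def _lcp(a: str, b: str) -> int:
    """Length of the longest common prefix of two strings."""
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _lcs(a: str, b: str) -> int:
    """Length of the longest common suffix of two strings."""
    n = min(len(a), len(b))
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


class RecombinationModel:
    """Parametric V(D)J recombination model (``variant`` "VJ" or "VDJ").

    Parameters
    ----------
    variant:
        "VJ" (single junction, alpha-like) or "VDJ" (two junctions,
        beta-like).
    segments:
        Iterable of :class:`GermlineSegment`.
    p_choice:
        Mapping from segment-name tuples ``(V, J)`` or ``(V, D, J)`` to
        probabilities; the joint segment-choice distribution.
    p_del_v, p_del_j:
        Mapping segment name -> categorical over deletion counts
        ``0..d_max`` (index = number of trimmed nucleotides).
    p_del_d5, p_del_d3:
        VDJ only; deletions from the 5' and 3' end of D.
    p_ins:
        VJ only; categorical over insertion lengths ``0..l_max``.
    p_ins_vd, p_ins_dj:
        VDJ only; insertion-length distributions at the two junctions.
    p_nt:
        Length-4 categorical over inserted nucleotides, order ACGT.
    """

    def __init__(
        self,
        variant: str,
        segments: Iterable[GermlineSegment],
        p_choice: Mapping[tuple[str, ...], float],
        p_del_v: Mapping[str, Sequence[float]],
        p_del_j: Mapping[str, Sequence[float]],
        *,
        p_ins: Sequence[float] | None = None,
        p_ins_vd: Sequence[float] | None = None,
        p_ins_dj: Sequence[float] | None = None,
        p_del_d5: Mapping[str, Sequence[float]] | None = None,
        p_del_d3: Mapping[str, Sequence[float]] | None = None,
        p_nt: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    ) -> None:
        if variant not in ("VJ", "VDJ"):
            raise ModelValidationError(f"variant must be 'VJ' or 'VDJ', got {variant!r}")
        self.variant = variant
        self._seg: dict[str, GermlineSegment] = {}
        self.segments_by_kind: dict[str, list[GermlineSegment]] = {"V": [], "D": [], "J": []}
        for seg in segments:
            if seg.name in self._seg:
                raise ModelValidationError(f"duplicate segment name {seg.name!r}")
            self._seg[seg.name] = seg
            self.segments_by_kind[seg.kind].append(seg)

        n_names = 2 if variant == "VJ" else 3
        self.p_choice: dict[tuple[str, ...], float] = {}
        total = 0.0
        for key, p in p_choice.items():
            key = tuple(key)
            if len(key) != n_names:
                raise ModelValidationError(
                    f"p_choice key {key!r} must name {n_names} segments for {variant}"
                )
            kinds = ("V", "J") if variant == "VJ" else ("V", "D", "J")
            for name, kind in zip(key, kinds):
                if name not in self._seg or self._seg[name].kind != kind:
                    raise ModelValidationError(f"p_choice names unknown {kind} segment {name!r}")
            if p < 0:
                raise ModelValidationError("p_choice has negative entries")
            self.p_choice[key] = float(p)
            total += p
        if abs(total - 1.0) > _NORM_TOL:
            raise ModelValidationError(f"p_choice does not sum to 1 (sum={total!r})")

        self.p_del_v = self._check_del(p_del_v, "V", "p_del_v")
        self.p_del_j = self._check_del(p_del_j, "J", "p_del_j")
        self.p_nt = _as_prob_array(p_nt, "p_nt")
        if self.p_nt.size != 4:
            raise ModelValidationError("p_nt must have 4 entries (ACGT)")

        if variant == "VJ":
            if p_ins is None:
                raise ModelValidationError("VJ model requires p_ins")
            self.p_ins = _as_prob_array(p_ins, "p_ins")
            self.p_ins_vd = self.p_ins_dj = None
            self.p_del_d5 = self.p_del_d3 = None
        else:
            if p_ins_vd is None or p_ins_dj is None:
                raise ModelValidationError("VDJ model requires p_ins_vd and p_ins_dj")
            if p_del_d5 is None or p_del_d3 is None:
                raise ModelValidationError("VDJ model requires p_del_d5 and p_del_d3")
            self.p_ins = None
            self.p_ins_vd = _as_prob_array(p_ins_vd, "p_ins_vd")
            self.p_ins_dj = _as_prob_array(p_ins_dj, "p_ins_dj")
            self.p_del_d5 = self._check_del(p_del_d5, "D", "p_del_d5")
            self.p_del_d3 = self._check_del(p_del_d3, "D", "p_del_d3")
            # Every (d5, d3) combination must leave a non-negative D core,
            # otherwise the model does not normalize over sequences.
            for seg in self.segments_by_kind["D"]:
                dmax5 = len(self.p_del_d5[seg.name]) - 1
                dmax3 = len(self.p_del_d3[seg.name]) - 1
                if dmax5 + dmax3 > len(seg.sequence):
                    raise ModelValidationError(
                        f"D segment {seg.name!r}: d5_max + d3_max exceeds segment length"
                    )
            if not self.segments_by_kind["D"]:
                raise ModelValidationError("VDJ model has no D segments")

        if not self.segments_by_kind["V"] or not self.segments_by_kind["J"]:
            raise ModelValidationError("model needs at least one V and one J segment")

        # flat arrays for fast inverse-CDF sampling
        self._choice_keys = list(self.p_choice)
        self._choice_cum = np.cumsum([self.p_choice[k] for k in self._choice_keys])
        self._nt_cum = np.cumsum(self.p_nt)

        # per-D map: trimmed core string -> summed P(d5) P(d3) over all
        # (d5, d3) yielding that core; turns D-placement search into
        # hash lookups during Pgen summation
        self._d_core_probs: dict[str, dict[str, float]] = {}
        if variant == "VDJ":
            for seg in self.segments_by_kind["D"]:
                cores: dict[str, float] = {}
                pd5 = self.p_del_d5[seg.name]
                pd3 = self.p_del_d3[seg.name]
                for d5 in range(pd5.size):
                    for d3 in range(pd3.size):
                        p = float(pd5[d5] * pd3[d3])
                        if p > 0.0:
                            core = seg.sequence[d5 : len(seg.sequence) - d3]
                            cores[core] = cores.get(core, 0.0) + p
                self._d_core_probs[seg.name] = cores

    def _check_del(
        self, mapping: Mapping[str, Sequence[float]], kind: str, what: str
    ) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for seg in self.segments_by_kind[kind]:
            if seg.name not in mapping:
                raise ModelValidationError(f"{what} missing entry for segment {seg.name!r}")
            arr = _as_prob_array(mapping[seg.name], f"{what}[{seg.name}]")
            if arr.size - 1 > len(seg.sequence):
                raise ModelValidationError(
                    f"{what}[{seg.name}]: d_max exceeds segment length"
                )
            out[seg.name] = arr
        return out

    # ------------------------------------------------------------------ util

    def segment(self, name: str) -> GermlineSegment:
        return self._seg[name]

    @property
    def l_max(self) -> int:
        if self.variant == "VJ":
            return self.p_ins.size - 1
        return max(self.p_ins_vd.size, self.p_ins_dj.size) - 1

    def realize(self, sc: RecombinationScenario) -> str:
        """Assemble the nucleotide sequence a scenario produces."""
        if self.variant == "VJ":
            (v, j), (dv, dj), (ins,) = sc.segments, sc.deletions, sc.insertions
            vseq = self._seg[v].sequence
            jseq = self._seg[j].sequence
            return vseq[: len(vseq) - dv] + ins + jseq[dj:]
        (v, d, j), (dv, d5, d3, dj) = sc.segments, sc.deletions
        ins_vd, ins_dj = sc.insertions
        vseq = self._seg[v].sequence
        dseq = self._seg[d].sequence
        jseq = self._seg[j].sequence
        core = dseq[d5 : len(dseq) - d3]
        return vseq[: len(vseq) - dv] + ins_vd + core + ins_dj + jseq[dj:]

    def _nt_prob(self, s: str) -> float:
        p = 1.0
        for c in s:
            p *= self.p_nt[_NT_INDEX[c]]
        return p

    # -------------------------------------------------------------- sampling

    def _draw(self, rng: np.random.Generator, cum: np.ndarray) -> int:
        return int(np.searchsorted(cum, rng.random(), side="right"))

    def _draw_insert(self, rng: np.random.Generator, length: int) -> str:
        return "".join(
            NUCLEOTIDES[self._draw(rng, self._nt_cum)] for _ in range(length)
        )

    def sample(self, rng: np.random.Generator) -> tuple[str, RecombinationScenario]:
        """Draw one recombination event; returns (sequence, scenario)."""
        key = self._choice_keys[self._draw(rng, self._choice_cum)]
        prob = self.p_choice[key]
        if self.variant == "VJ":
            v, j = key
            dv = self._draw(rng, np.cumsum(self.p_del_v[v]))
            dj = self._draw(rng, np.cumsum(self.p_del_j[j]))
            ell = self._draw(rng, np.cumsum(self.p_ins))
            ins = self._draw_insert(rng, ell)
            prob *= (
                self.p_del_v[v][dv]
                * self.p_del_j[j][dj]
                * self.p_ins[ell]
                * self._nt_prob(ins)
            )
            sc = RecombinationScenario(key, (dv, dj), (ins,), prob)
        else:
            v, d, j = key
            dv = self._draw(rng, np.cumsum(self.p_del_v[v]))
            d5 = self._draw(rng, np.cumsum(self.p_del_d5[d]))
            d3 = self._draw(rng, np.cumsum(self.p_del_d3[d]))
            dj = self._draw(rng, np.cumsum(self.p_del_j[j]))
            l1 = self._draw(rng, np.cumsum(self.p_ins_vd))
            l2 = self._draw(rng, np.cumsum(self.p_ins_dj))
            ins1 = self._draw_insert(rng, l1)
            ins2 = self._draw_insert(rng, l2)
            prob *= (
                self.p_del_v[v][dv]
                * self.p_del_d5[d][d5]
                * self.p_del_d3[d][d3]
                * self.p_del_j[j][dj]
                * self.p_ins_vd[l1]
                * self.p_ins_dj[l2]
                * self._nt_prob(ins1)
                * self._nt_prob(ins2)
            )
            sc = RecombinationScenario(key, (dv, d5, d3, dj), (ins1, ins2), prob)
        return self.realize(sc), sc

    # ---------------------------------------------------------- enumeration

    def enumerate_scenarios(self, seq: str) -> list[RecombinationScenario]:
        """All scenarios whose realization equals ``seq``, with exact probabilities.

        Inserted strings are determined by the sequence once segments and
        deletions are fixed, so the enumeration is over discrete latent
        choices only.
        """
        _check_dna(seq)
        out: list[RecombinationScenario] = []
        L = len(seq)
        for key, pc in self.p_choice.items():
            if pc == 0.0:
                continue
            v, j = key[0], key[-1]
            vseq = self._seg[v].sequence
            jseq = self._seg[j].sequence
            pdv = self.p_del_v[v]
            pdj = self.p_del_j[j]
            for dv in range(pdv.size):
                if pdv[dv] == 0.0:
                    continue
                lv = len(vseq) - dv
                if lv > L or seq[:lv] != vseq[:lv]:
                    continue
                for dj in range(pdj.size):
                    if pdj[dj] == 0.0:
                        continue
                    lj = len(jseq) - dj
                    if lv + lj > L or (lj > 0 and seq[-lj:] != jseq[dj:]):
                        continue
                    middle = seq[lv : L - lj]
                    if self.variant == "VJ":
                        ell = len(middle)
                        if ell >= self.p_ins.size or self.p_ins[ell] == 0.0:
                            continue
                        p = pc * pdv[dv] * pdj[dj] * self.p_ins[ell] * self._nt_prob(middle)
                        if p > 0.0:
                            out.append(
                                RecombinationScenario((v, j), (dv, dj), (middle,), p)
                            )
                    else:
                        out.extend(
                            self._d_placements(key, pc * pdv[dv] * pdj[dj], dv, dj, middle)
                        )
        return out

    def _d_placements(
        self,
        key: tuple[str, ...],
        base: float,
        dv: int,
        dj: int,
        middle: str,
    ) -> Iterator[RecombinationScenario]:
        d = key[1]
        dseq = self._seg[d].sequence
        pd5 = self.p_del_d5[d]
        pd3 = self.p_del_d3[d]
        m = len(middle)
        for d5 in range(pd5.size):
            if pd5[d5] == 0.0:
                continue
            for d3 in range(pd3.size):
                if pd3[d3] == 0.0:
                    continue
                core = dseq[d5 : len(dseq) - d3]
                k = len(core)
                if k > m:
                    continue
                for pos in range(m - k + 1):
                    if middle[pos : pos + k] != core:
                        continue
                    l1, l2 = pos, m - k - pos
                    if l1 >= self.p_ins_vd.size or l2 >= self.p_ins_dj.size:
                        continue
                    ins1, ins2 = middle[:pos], middle[pos + k :]
                    p = (
                        base
                        * pd5[d5]
                        * pd3[d3]
                        * self.p_ins_vd[l1]
                        * self.p_ins_dj[l2]
                        * self._nt_prob(ins1)
                        * self._nt_prob(ins2)
                    )
                    if p > 0.0:
                        yield RecombinationScenario(
                            key, (dv, d5, d3, dj), (ins1, ins2), p
                        )

    # ---------------------------------------------------------------- pgen

    def _feasible_matches(
        self, seq: str
    ) -> tuple[dict[str, list[tuple[float, int]]], dict[str, list[tuple[float, int]]]]:
        """Per-segment feasible (deletion-probability, match-length) pairs.

        A V contributes a prefix of length ``lv = len(V) - dV``; only
        lengths within the longest common prefix of V and the sequence can
        match, which prunes almost all segment choices up front.
        """
        feas_v: dict[str, list[tuple[float, int]]] = {}
        for s in self.segments_by_kind["V"]:
            lcp = _lcp(s.sequence, seq)
            pdv = self.p_del_v[s.name]
            feas_v[s.name] = [
                (float(pdv[dv]), len(s.sequence) - dv)
                for dv in range(pdv.size)
                if pdv[dv] > 0.0 and len(s.sequence) - dv <= lcp
            ]
        feas_j: dict[str, list[tuple[float, int]]] = {}
        for s in self.segments_by_kind["J"]:
            lcs = _lcs(s.sequence, seq)
            pdj = self.p_del_j[s.name]
            feas_j[s.name] = [
                (float(pdj[dj]), len(s.sequence) - dj)
                for dj in range(pdj.size)
                if pdj[dj] > 0.0 and len(s.sequence) - dj <= lcs
            ]
        return feas_v, feas_j

    def insertion_weight_table(self, seq: str) -> dict[tuple[int, ...], float]:
        """Scenario mass grouped by insertion lengths, insertion-length factor excluded.

        Maps ``(l,)`` (VJ) or ``(l_vd, l_dj)`` (VDJ) to the summed
        probability of all scenarios with those insertion lengths,
        *without* the P_ins factor but *with* the inserted-nucleotide
        composition factor.  Pgen under any insertion-length distribution
        q is ``sum(w * q[lens])``; the table is also the E-step sufficient
        statistic for re-estimating q.
        """
        _check_dna(seq)
        L = len(seq)
        feas_v, feas_j = self._feasible_matches(seq)
        # nt composition of every middle substring via cumulative products
        if (self.p_nt > 0.0).all():
            cum = np.concatenate(
                ([1.0], np.cumprod([self.p_nt[_NT_INDEX[c]] for c in seq]))
            )
            ntw = lambda i, j: cum[j] / cum[i]
        else:
            ntw = lambda i, j: self._nt_prob(seq[i:j])
        table: dict[tuple[int, ...], float] = {}
        if self.variant == "VJ":
            kmax = self.p_ins.size - 1
            for key, pc in self.p_choice.items():
                fv, fj = feas_v[key[0]], feas_j[key[1]]
                if pc == 0.0 or not fv or not fj:
                    continue
                for pv, lv in fv:
                    for pj, lj in fj:
                        ell = L - lv - lj
                        if 0 <= ell <= kmax:
                            lens = (ell,)
                            table[lens] = table.get(lens, 0.0) + pc * pv * pj * ntw(
                                lv, L - lj
                            )
            return table

        # VDJ: cache D placements per (D segment, middle window)
        k1max = self.p_ins_vd.size - 1
        k2max = self.p_ins_dj.size - 1
        dcache: dict[tuple[str, int, int], list[tuple[int, int, float]]] = {}

        def d_weights(d: str, lv: int, lj: int) -> list[tuple[int, int, float]]:
            ck = (d, lv, lj)
            hit = dcache.get(ck)
            if hit is not None:
                return hit
            cores = self._d_core_probs[d]
            lo, hi = lv, L - lj
            m = hi - lo
            out: list[tuple[int, int, float]] = []
            for l1 in range(min(m, k1max) + 1):
                for l2 in range(min(m - l1, k2max) + 1):
                    p = cores.get(seq[lo + l1 : hi - l2])
                    if p is not None:
                        out.append((l1, l2, p * ntw(lo, lo + l1) * ntw(hi - l2, hi)))
            dcache[ck] = out
            return out

        for key, pc in self.p_choice.items():
            fv, fj = feas_v[key[0]], feas_j[key[2]]
            if pc == 0.0 or not fv or not fj:
                continue
            for pv, lv in fv:
                for pj, lj in fj:
                    if lv + lj > L:
                        continue
                    for l1, l2, w in d_weights(key[1], lv, lj):
                        lens = (l1, l2)
                        table[lens] = table.get(lens, 0.0) + pc * pv * pj * w
        return table

    def pgen(self, seq: str) -> float:
        """Generation probability of ``seq``: sum over all scenarios.

        Iterates over feasible V-prefix and J-suffix match lengths (and D
        core placements for VDJ) rather than materializing scenario
        objects; returns 0 for unreachable sequences.
        """
        table = self.insertion_weight_table(seq)
        if self.variant == "VJ":
            return float(sum(w * self.p_ins[l[0]] for l, w in table.items()))
        return float(
            sum(w * self.p_ins_vd[l[0]] * self.p_ins_dj[l[1]] for l, w in table.items())
        )

    def is_zero_insertion_consistent(self, seq: str) -> bool:
        """True iff some scenario with all insertion lengths zero exists.

        This is the germline-matchability criterion: the sequence can be
        entirely covered by (trimmed) germline segments.  Segment-choice
        and deletion factors must have positive support, but the weight of
        P_ins(0) is not consulted.
        """
        _check_dna(seq)
        L = len(seq)
        feas_v, feas_j = self._feasible_matches(seq)
        for key, pc in self.p_choice.items():
            fv, fj = feas_v[key[0]], feas_j[key[-1]]
            if pc == 0.0 or not fv or not fj:
                continue
            for _, lv in fv:
                for _, lj in fj:
                    if lv + lj > L:
                        continue
                    if self.variant == "VJ":
                        if lv + lj == L:
                            return True
                        continue
                    # VDJ: the D core must cover the middle exactly
                    d = key[1]
                    dseq = self._seg[d].sequence
                    pd5 = self.p_del_d5[d]
                    pd3 = self.p_del_d3[d]
                    m = L - lv - lj
                    for d5 in range(pd5.size):
                        if pd5[d5] == 0.0:
                            continue
                        d3 = len(dseq) - d5 - m
                        if d3 < 0 or d3 >= pd3.size or pd3[d3] == 0.0:
                            continue
                        if dseq[d5 : d5 + m] == seq[lv : L - lj]:
                            return True
        return False

    # ------------------------------------------------------------- file I/O

    def to_dict(self) -> dict:
        d: dict = {
            "variant": self.variant,
            "segments": [
                {"name": s.name, "kind": s.kind, "sequence": s.sequence}
                for k in ("V", "D", "J")
                for s in self.segments_by_kind[k]
            ],
            "p_choice": [
                {"segments": list(k), "p": p} for k, p in self.p_choice.items()
            ],
            "p_del_v": {k: list(map(float, v)) for k, v in self.p_del_v.items()},
            "p_del_j": {k: list(map(float, v)) for k, v in self.p_del_j.items()},
            "p_nt": list(map(float, self.p_nt)),
        }
        if self.variant == "VJ":
            d["p_ins"] = list(map(float, self.p_ins))
        else:
            d["p_ins_vd"] = list(map(float, self.p_ins_vd))
            d["p_ins_dj"] = list(map(float, self.p_ins_dj))
            d["p_del_d5"] = {k: list(map(float, v)) for k, v in self.p_del_d5.items()}
            d["p_del_d3"] = {k: list(map(float, v)) for k, v in self.p_del_d3.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RecombinationModel":
        segments = [GermlineSegment(**s) for s in d["segments"]]
        p_choice = {tuple(e["segments"]): e["p"] for e in d["p_choice"]}
        kwargs: dict = {"p_nt": d.get("p_nt", (0.25,) * 4)}
        for k in ("p_ins", "p_ins_vd", "p_ins_dj", "p_del_d5", "p_del_d3"):
            if k in d:
                kwargs[k] = d[k]
        return cls(d["variant"], segments, p_choice, d["p_del_v"], d["p_del_j"], **kwargs)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            yaml.safe_dump(self.to_dict(), sort_keys=False)
            if path.suffix in (".yaml", ".yml")
            else json.dumps(self.to_dict(), indent=1)
        )
        path.write_text(text)

    @classmethod
    def from_file(cls, path: str | Path) -> "RecombinationModel":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(d)

    def with_insertion_distribution(
        self,
        p_ins: Sequence[float] | None = None,
        p_ins_vd: Sequence[float] | None = None,
        p_ins_dj: Sequence[float] | None = None,
    ) -> "RecombinationModel":
        """Copy of the model with replaced insertion-length distribution(s)."""
        d = self.to_dict()
        if self.variant == "VJ":
            if p_ins is None:
                raise ValueError("VJ model needs p_ins")
            d["p_ins"] = list(map(float, p_ins))
        else:
            if p_ins_vd is not None:
                d["p_ins_vd"] = list(map(float, p_ins_vd))
            if p_ins_dj is not None:
                d["p_ins_dj"] = list(map(float, p_ins_dj))
        return RecombinationModel.from_dict(d)


def segments_from_fasta(path: str | Path) -> list[GermlineSegment]:
    """Load germline segments from FASTA with headers ``name|kind``."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name, _, kind = rec.id.partition("|")
        if not kind:
            raise ValueError(f"FASTA header {rec.id!r} is not of the form 'name|kind'")
        out.append(GermlineSegment(name, kind, str(rec.seq).upper()))
    return out


def generate_repertoire(
    model: RecombinationModel, n: int, rng_seed: int | np.random.Generator
) -> list[tuple[str, RecombinationScenario]]:
    """Sample ``n`` recombination events; reproducible given the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    return [model.sample(rng) for _ in range(n)]


def enumerate_universe(model: RecombinationModel, max_scenarios: int = 2_000_000) -> dict[str, float]:
    """Map every realizable sequence to its Pgen by exhausting all scenarios.

    Enumerates segment choices, deletion counts, insertion lengths and
    inserted strings; only feasible for toy models (cost grows as
    ``4**l_max``).  The returned values sum to 1 for a valid model.
    """
    out: dict[str, float] = {}
    count = 0

    def _bump() -> None:
        nonlocal count
        count += 1
        if count > max_scenarios:
            raise RuntimeError("universe too large to enumerate; toy models only")

    for key, pc in model.p_choice.items():
        if pc == 0.0:
            continue
        v, j = key[0], key[-1]
        vseq = model.segment(v).sequence
        jseq = model.segment(j).sequence
        for dv, pv in enumerate(model.p_del_v[v]):
            for dj, pj in enumerate(model.p_del_j[j]):
                base = pc * pv * pj
                if base == 0.0:
                    continue
                left = vseq[: len(vseq) - dv]
                right = jseq[dj:]
                if model.variant == "VJ":
                    for ell, pl in enumerate(model.p_ins):
                        if pl == 0.0:
                            continue
                        for ins in itertools.product(NUCLEOTIDES, repeat=ell):
                            _bump()
                            s = left + "".join(ins) + right
                            out[s] = out.get(s, 0.0) + base * pl * model._nt_prob(
                                "".join(ins)
                            )
                else:
                    d = key[1]
                    dseq = model.segment(d).sequence
                    for d5, p5 in enumerate(model.p_del_d5[d]):
                        for d3, p3 in enumerate(model.p_del_d3[d]):
                            if p5 == 0.0 or p3 == 0.0:
                                continue
                            core = dseq[d5 : len(dseq) - d3]
                            for l1, pl1 in enumerate(model.p_ins_vd):
                                for l2, pl2 in enumerate(model.p_ins_dj):
                                    if pl1 == 0.0 or pl2 == 0.0:
                                        continue
                                    for i1 in itertools.product(NUCLEOTIDES, repeat=l1):
                                        for i2 in itertools.product(
                                            NUCLEOTIDES, repeat=l2
                                        ):
                                            _bump()
                                            s1, s2 = "".join(i1), "".join(i2)
                                            s = left + s1 + core + s2 + right
                                            out[s] = out.get(s, 0.0) + (
                                                base
                                                * p5
                                                * p3
                                                * pl1
                                                * pl2
                                                * model._nt_prob(s1)
                                                * model._nt_prob(s2)
                                            )
    return out
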