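"""Clonotype tables: reading, writing, ranking and slicing.

A clonotype is a distinct receptor sequence with a unique-molecule count.
Tables are TSV with a header; the built-in dialects cover the generic
column names written by this package and MiXCR-style exports
(``cloneCount``, ``nSeqCDR3``, ...).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .model import frame_class

logger = logging.getLogger(__name__)

CHAINS = ("alpha", "beta")
COMPARTMENTS = ("cord", "naive", "memory", "PBMC", "unpartitioned")

#: generic dialect: package column name -> file column name
GENERIC_DIALECT: dict[str, str] = {
    "count": "count",
    "cdr3_nt": "cdr3_nt",
    "cdr3_aa": "cdr3_aa",
    "v_name": "v_name",
    "d_name": "d_name",
    "j_name": "j_name",
}

MIXCR_DIALECT: dict[str, str] = {
    "count": "cloneCount",
    "cdr3_nt": "nSeqCDR3",
    "cdr3_aa": "aaSeqCDR3",
    "v_name": "allVHitsWithScore",
    "d_name": "allDHitsWithScore",
    "j_name": "allJHitsWithScore",
}

DIALECTS = {"generic": GENERIC_DIALECT, "mixcr": MIXCR_DIALECT}


class TableFormatError(ValueError):
    """Raised when a clonotype table violates the expected format."""


@dataclass(frozen=True)
class Clonotype:
    """A distinct CDR3 nucleotide sequence with its molecule count."""

    cdr3_nt: str
    count: int
    cdr3_aa: str | None = None
    v_name: str | None = None
    d_name: str | None = None
    j_name: str | None = None
    frame: str = field(init=False)
    has_stop: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")
        frame, has_stop = frame_class(self.cdr3_nt)
        object.__setattr__(self, "frame", frame)
        object.__setattr__(self, "has_stop", has_stop)


@dataclass
class Repertoire:
    """A donor-tagged collection of clonotypes."""

    donor_id: str
    chain: str
    clonotypes: list[Clonotype]
    compartment: str = "unpartitioned"
    age: float | None = None

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise ValueError(f"chain must be one of {CHAINS}, got {self.chain!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"compartment must be one of {COMPARTMENTS}, got {self.compartment!r}"
            )

    def __len__(self) -> int:
        return len(self.clonotypes)

    def keyset(self, key: str = "cdr3nt") -> set:
        return {clonotype_key(c, key) for c in self.clonotypes}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": [c.count for c in self.clonotypes],
                "cdr3_nt": [c.cdr3_nt for c in self.clonotypes],
                "cdr3_aa": [c.cdr3_aa for c in self.clonotypes],
                "v_name": [c.v_name for c in self.clonotypes],
                "d_name": [c.d_name for c in self.clonotypes],
                "j_name": [c.j_name for c in self.clonotypes],
                "frame": [c.frame for c in self.clonotypes],
                "has_stop": [c.has_stop for c in self.clonotypes],
            }
        )


def clonotype_key(c: Clonotype, key: str = "cdr3nt"):
    """Sharing/merge key: the CDR3 nucleotide sequence, optionally with genes."""
    if key == "cdr3nt":
        return c.cdr3_nt
    if key == "vcj":
        return (c.v_name, c.cdr3_nt, c.j_name)
    raise ValueError(f"unknown key {key!r} (expected 'cdr3nt' or 'vcj')")


def _parse_gene(raw: object) -> str | None:
    """Best gene call from a MiXCR hits column like 'TRAV1-1*00(1200),...'."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
        return None
    first = str(raw).split(",")[0]
    return first.split("*")[0].split("(")[0]


def _parse_count(raw: object, row: int) -> int:
    try:
        val = float(raw)
    except (TypeError, ValueError):
        raise TableFormatError(f"non-numeric count {raw!r} in row {row}") from None
    if val != int(val):
        raise TableFormatError(f"non-integer count {raw!r} in row {row}")
    return int(val)


def read_clonotype_table(
    path: str | Path,
    dialect: str | Mapping[str, str] = "generic",
    *,
    donor_id: str = "",
    chain: str = "alpha",
    compartment: str = "unpartitioned",
    age: float | None = None,
    key: str = "cdr3nt",
) -> Repertoire:
    """Read a TSV clonotype table into a :class:`Repertoire`.

    Duplicate rows under the active key are merged by summing counts (a
    warning is logged).  The mandatory columns are the count and CDR3
    nucleotide sequence; gene columns are optional.
    """
    mapping = DIALECTS[dialect] if isinstance(dialect, str) else dict(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("count", "cdr3_nt"):
        if mapping[col] not in df.columns:
            raise TableFormatError(
                f"missing mandatory column {mapping[col]!r} in {path}"
            )
    is_mixcr = mapping is MIXCR_DIALECT or mapping.get("count") == "cloneCount"

    merged: dict[object, dict] = {}
    for i, row in enumerate(df.to_dict("records")):
        rec = {
            f: row.get(mapping[f]) if mapping.get(f) in df.columns else None
            for f in ("count", "cdr3_nt", "cdr3_aa", "v_name", "d_name", "j_name")
        }
        rec["count"] = _parse_count(rec["count"], i)
        rec["cdr3_nt"] = str(rec["cdr3_nt"]).upper()
        for f in ("cdr3_aa", "v_name", "d_name", "j_name"):
            if isinstance(rec[f], float) and pd.isna(rec[f]):
                rec[f] = None
            elif rec[f] is not None:
                rec[f] = str(rec[f])
        if is_mixcr:
            for f in ("v_name", "d_name", "j_name"):
                rec[f] = _parse_gene(rec[f])
        c = Clonotype(**rec)
        k = clonotype_key(c, key)
        if k in merged:
            merged[k]["count"] += c.count
            logger.warning(
                "duplicate clonotype %r in %s: counts merged", k, path
            )
        else:
            merged[k] = {
                "cdr3_nt": c.cdr3_nt,
                "count": c.count,
                "cdr3_aa": c.cdr3_aa,
                "v_name": c.v_name,
                "d_name": c.d_name,
                "j_name": c.j_name,
            }
    clonotypes = [Clonotype(**rec) for rec in merged.values()]
    return Repertoire(
        donor_id=donor_id,
        chain=chain,
        clonotypes=clonotypes,
        compartment=compartment,
        age=age,
    )


def write_clonotype_table(rep: Repertoire, path: str | Path) -> None:
    """Write a repertoire as a TSV table in the generic dialect."""
    rep.to_frame().to_csv(path, sep="\t", index=False)


def frame_subset(
    rep: Repertoire, frame: str, *, include_stops: bool = False
) -> Repertoire:
    """Restrict to in-frame or out-of-frame clonotypes.

    In-frame clonotypes carrying a stop codon are excluded from both
    subsets unless ``include_stops`` is set: the out-of-frame set is the
    selection-free readout and the in-frame set the productive one, and
    stop-carrying sequences belong to neither analysis.
    """
    if frame not in ("in_frame", "out_of_frame"):
        raise ValueError(f"frame must be in_frame or out_of_frame, got {frame!r}")
    keep = [
        c
        for c in rep.clonotypes
        if c.frame == frame and (include_stops or not (c.frame == "in_frame" and c.has_stop))
    ]
    return replace(rep, clonotypes=keep)


def rank_clonotypes(rep: Repertoire | Sequence[Clonotype]) -> list[Clonotype]:
    """Clonotypes sorted by count descending, ties broken lexicographically.

    The deterministic tie-break makes every rank-based statistic
    reproducible across runs and platforms.
    """
    clonotypes = rep.clonotypes if isinstance(rep, Repertoire) else list(rep)
    if not clonotypes:
        raise ValueError("repertoire is empty")
    return sorted(clonotypes, key=lambda c: (-c.count, c.cdr3_nt))


def slice_bins(
    ranked: Sequence[Clonotype], bin_size: int
) -> list[tuple[tuple[int, int], list[Clonotype]]]:
    """Disjoint consecutive rank bins: [(rank_range, clones), ...] (1-based)."""
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    out = []
    for start in range(0, len(ranked), bin_size):
        chunk = list(ranked[start : start + bin_size])
        out.append(((start + 1, start + len(chunk)), chunk))
    return out


def slice_top_classes(
    ranked: Sequence[Clonotype], classes: Sequence[int]
) -> list[tuple[int, list[Clonotype]]]:
    """Cumulative top-K abundance classes: [(K, top-K clones), ...]."""
    prev = 0
    out = []
    for k in classes:
        if k <= prev:
            raise ValueError("classes must be strictly increasing positive sizes")
        out.append((k, list(ranked[:k])))
        prev = k
    return out


def rank_and_slice(
    rep: Repertoire,
    *,
    bin_size: int | None = None,
    classes: Sequence[int] | None = None,
):
    """Rank by abundance then slice into disjoint bins or cumulative classes."""
    ranked = rank_clonotypes(rep)
    if (bin_size is None) == (classes is None):
        raise ValueError("give exactly one of bin_size or classes")
    if bin_size is not None:
        return slice_bins(ranked, bin_size)
    return slice_top_classes(ranked, classes)
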