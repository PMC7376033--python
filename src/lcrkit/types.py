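"""Core domain types shared across the toolkit.

Every stage of the pipeline trades in ordered label positions: an optical
map is nothing but the 1-based basepair coordinates of fluorescent labels
(DLE-1 recognition sites, motif CTTAAG) along a molecule, a consensus
contig, or an in-silico digested reference. Coordinates are 1-based
inclusive basepairs throughout; decimal inputs are rounded half-up on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "LabelMap",
    "Molecule",
    "AnnotationInterval",
    "MapValidationError",
]


class MapValidationError(ValueError):
    """An object violated a label-map invariant (ordering, bounds, lengths)."""


def _as_int_positions(positions: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(positions), dtype=float)
    # round half-up: label resolution is ~kbp, sub-bp precision is meaningless
    return np.floor(arr + 0.5).astype(np.int64)


@dataclass(frozen=True)
class LabelMap:
    """An ordered set of label positions on a named map.

    Parameters
    ----------
    map_id : str
        Identifier (CMapId, haplotype id, ...).
    length_bp : int
        Total map length in bp; every position must lie in [1, length_bp].
    positions : ndarray of int64
        Strictly increasing 1-based label coordinates.
    meta : dict
        Free-form annotations (locus, coordinate offset, provenance).
    """

    map_id: str
    length_bp: int
    positions: np.ndarray
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self):
        pos = _as_int_positions(np.atleast_1d(np.asarray(self.positions, dtype=float)))
        if self.length_bp <= 0:
            raise MapValidationError(f"{self.map_id}: non-positive length {self.length_bp}")
        if pos.size:
            if pos[0] < 1 or pos[-1] > self.length_bp:
                raise MapValidationError(
                    f"{self.map_id}: positions outside [1, {self.length_bp}]"
                )
            if np.any(np.diff(pos) <= 0):
                raise MapValidationError(f"{self.map_id}: positions not strictly increasing")
        pos.setflags(write=False)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "length_bp", int(self.length_bp))

    @property
    def n_labels(self) -> int:
        return int(self.positions.size)

    def density_per_100kbp(self) -> float:
        """Observed label density in quality-report units (labels / 100 kbp)."""
        return 1e5 * self.n_labels / self.length_bp

    def reflected(self, map_id: str | None = None) -> "LabelMap":
        """The map read from the opposite end: position p -> length - p + 1."""
        pos = (self.length_bp - self.positions + 1)[::-1]
        return LabelMap(map_id or self.map_id, self.length_bp, pos, dict(self.meta))

    def window(self, start_bp: int, end_bp: int) -> np.ndarray:
        """Positions falling in [start_bp, end_bp] (1-based inclusive)."""
        lo = np.searchsorted(self.positions, start_bp, side="left")
        hi = np.searchsorted(self.positions, end_bp, side="right")
        return self.positions[lo:hi]

    def with_meta(self, **extra) -> "LabelMap":
        meta = dict(self.meta)
        meta.update(extra)
        return replace(self, meta=meta)


@dataclass(frozen=True)
class Molecule:
    """A single imaged DNA molecule: a label map observed with error.

    ``label_quality`` holds one score in [0, 1] per label (BNX QX11 channel).
    ``source_meta`` carries run/scan identifiers and, for simulated
    molecules, the truth bookkeeping used by recovery tests.
    """

    molecule_id: str
    labelmap: LabelMap
    label_quality: np.ndarray
    source_meta: Mapping = field(default_factory=dict)

    def __post_init__(self):
        q = np.asarray(self.label_quality, dtype=float)
        if q.size != self.labelmap.n_labels:
            raise MapValidationError(
                f"molecule {self.molecule_id}: {q.size} quality scores for "
                f"{self.labelmap.n_labels} labels"
            )
        if q.size and (q.min() < 0 or q.max() > 1):
            raise MapValidationError(f"molecule {self.molecule_id}: quality outside [0,1]")
        q.setflags(write=False)
        object.__setattr__(self, "label_quality", q)

    @property
    def length_bp(self) -> int:
        return self.labelmap.length_bp

    @property
    def n_labels(self) -> int:
        return self.labelmap.n_labels


@dataclass(frozen=True)
class AnnotationInterval:
    """A named genomic interval, 1-based inclusive on ``reference_id``."""

    name: str
    start_bp: int
    end_bp: int
    reference_id: str = ""

    def __post_init__(self):
        if self.start_bp >= self.end_bp:
            raise MapValidationError(
                f"annotation {self.name}: start {self.start_bp} >= end {self.end_bp}"
            )

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def overlaps(self, start_bp: int, end_bp: int) -> bool:
        """1-bp inclusive overlap with [start_bp, end_bp]."""
        return self.start_bp <= end_bp and start_bp <= self.end_bp


def merge_by_resolution(positions: Sequence[int] | np.ndarray, res_bp: int) -> np.ndarray:
    """Collapse runs of labels closer than ``res_bp`` to their (rounded) midpoint.

    Models the imaging resolution limit: two fluorophores closer than the
    optical resolution are reported as a single site. Runs are formed
    greedily left to right; a run's emitted position is the midpoint of its
    extremes.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if res_bp <= 0 or pos.size < 2:
        return pos.copy()
    out = []
    run_start = run_end = int(pos[0])
    for p in pos[1:]:
        p = int(p)
        if p - run_end < res_bp:
            run_end = p
        else:
            out.append((run_start + run_end + 1) // 2)
            run_start = run_end = p
    out.append((run_start + run_end + 1) // 2)
    return np.asarray(out, dtype=np.int64)
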