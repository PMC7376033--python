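"""Readers/writers for the optical-mapping text formats.

Supported dialects (deliberately minimal, see package docs):

* **BNX** -- the raw-molecule format. We read/write the 0/1/QX11 line
  subset of BNX 1.2/1.3: a ``0`` line with molecule id and length, a ``1``
  line with the label positions (bp, decimals allowed), and a ``QX11`` line
  with one quality score per label. Unrecognized header lines are ignored
  with a logged warning; unsupported versions are rejected.
* **CMAP** -- consensus/reference maps. Tab-separated columns CMapId,
  ContigLength, NumSites, SiteID, LabelChannel, Position; one channel-0
  terminal row per map at the contig length (vendor convention).
* **BED** -- annotation intervals, converted on read from 0-based
  half-open to the internal 1-based inclusive convention.

All writers produce deterministic byte output for identical input.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .types import AnnotationInterval, LabelMap, Molecule

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_bnx",
    "write_bnx",
    "read_cmap",
    "write_cmap",
    "read_annotations",
    "write_annotations",
]

_SUPPORTED_BNX_VERSIONS = {"1.2", "1.3"}


class ParseError(ValueError):
    """Structured parse failure; carries the offending path and line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


def _round_half_up(values: Iterable[float]) -> np.ndarray:
    return np.floor(np.asarray(list(values), dtype=float) + 0.5).astype(np.int64)


# ---------------------------------------------------------------------------
# BNX


def read_bnx(path) -> list[Molecule]:
    """Parse a BNX file into molecules, preserved in file order."""
    path = Path(path)
    molecules: list[Molecule] = []
    version_seen = False
    cur_id = None
    cur_len = None
    cur_pos: np.ndarray | None = None
    cur_line0 = 0

    def _flush(lineno: int):
        nonlocal cur_id, cur_len, cur_pos
        if cur_id is None:
            return
        if cur_pos is None:
            raise ParseError(path, cur_line0, f"molecule {cur_id}: missing 1 line")
        raise ParseError(path, lineno, f"molecule {cur_id}: missing QX11 line")

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "BNX File Version" in line:
                    version = line.split(":", 1)[1].strip()
                    if version not in _SUPPORTED_BNX_VERSIONS:
                        raise ParseError(path, lineno, f"unsupported BNX version {version!r}")
                    version_seen = True
                elif "Label Channels" in line or line.startswith("#0h") or line.startswith("#0f"):
                    pass
                else:
                    logger.warning("%s:%d: ignoring header line %r", path, lineno, line[:60])
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "0":
                if cur_id is not None:
                    _flush(lineno)
                if len(fields) < 3:
                    raise ParseError(path, lineno, "0 line needs id and length")
                cur_id = fields[1]
                cur_len = int(np.floor(float(fields[2]) + 0.5))
                cur_pos = None
                cur_line0 = lineno
            elif tag == "1":
                if cur_id is None:
                    raise ParseError(path, lineno, "1 line before any 0 line")
                cur_pos = _round_half_up(float(v) for v in fields[1:])
            elif tag == "QX11":
                if cur_id is None or cur_pos is None:
                    raise ParseError(path, lineno, "QX11 line without preceding 0/1 lines")
                quality = np.asarray([float(v) for v in fields[1:]], dtype=float)
                if quality.size != cur_pos.size:
                    raise ParseError(
                        path,
                        lineno,
                        f"molecule {cur_id}: {quality.size} quality scores "
                        f"for {cur_pos.size} labels",
                    )
                labelmap = LabelMap(cur_id, cur_len, cur_pos)
                molecules.append(Molecule(cur_id, labelmap, quality))
                cur_id = cur_len = cur_pos = None
            else:
                logger.warning("%s:%d: ignoring unsupported record %r", path, lineno, tag)
        if cur_id is not None:
            _flush(lineno if molecules or cur_id else 0)
    if not version_seen:
        raise ParseError(path, 0, "missing '# BNX File Version' header")
    return molecules


def write_bnx(molecules: Sequence[Molecule], path) -> None:
    """Write molecules as BNX 1.3 (0/1/QX11 subset); deterministic bytes."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# BNX File Version: 1.3\n")
        fh.write("# Label Channels: 1\n")
        fh.write("#0h\tLabelChannel\tMoleculeId\tLength\n")
        for mol in molecules:
            fh.write(f"0\t{mol.molecule_id}\t{mol.length_bp:.1f}\n")
            pos = "\t".join(f"{p:.1f}" for p in mol.labelmap.positions)
            fh.write(f"1\t{pos}\n" if pos else "1\n")
            qual = "\t".join(f"{q:.4f}" for q in mol.label_quality)
            fh.write(f"QX11\t{qual}\n" if qual else "QX11\n")


# ---------------------------------------------------------------------------
# CMAP

_CMAP_COLUMNS = ("CMapId", "ContigLength", "NumSites", "SiteID", "LabelChannel", "Position")


def read_cmap(path) -> list[LabelMap]:
    """Parse a CMAP file into label maps, one per CMapId, in file order."""
    path = Path(path)
    order: list[str] = []
    rows: dict[str, list[tuple[int, int, int, float, int]]] = {}
    declared: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(path, lineno, f"expected >=6 columns, got {len(fields)}")
            map_id = fields[0]
            try:
                length = int(np.floor(float(fields[1]) + 0.5))
                num_sites = int(fields[2])
                site_id = int(fields[3])
                channel = int(fields[4])
                position = float(fields[5])
            except ValueError as exc:
                raise ParseError(path, lineno, f"bad numeric field: {exc}") from None
            if map_id not in rows:
                rows[map_id] = []
                order.append(map_id)
                declared[map_id] = (length, num_sites)
            rows[map_id].append((lineno, site_id, channel, position, num_sites))

    maps: list[LabelMap] = []
    for map_id in order:
        length, num_sites = declared[map_id]
        site_rows = [r for r in rows[map_id] if r[2] != 0]
        prev_site = 0
        prev_pos = -np.inf
        positions = []
        for lineno, site_id, _channel, position, _n in site_rows:
            if site_id <= prev_site:
                raise ParseError(path, lineno, f"map {map_id}: non-monotone SiteID {site_id}")
            if position < prev_pos:
                raise ParseError(
                    path, lineno, f"map {map_id}: Position out of order at SiteID {site_id}"
                )
            prev_site, prev_pos = site_id, position
            positions.append(position)
        if len(positions) != num_sites:
            raise ParseError(
                path,
                rows[map_id][0][0],
                f"map {map_id}: NumSites={num_sites} but {len(positions)} site rows",
            )
        maps.append(LabelMap(map_id, length, _round_half_up(positions)))
    return maps


def write_cmap(maps: Sequence[LabelMap], path) -> None:
    """Write label maps as CMAP with a channel-0 terminal row per map."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#h\t" + "\t".join(_CMAP_COLUMNS) + "\n")
        for m in maps:
            n = m.n_labels
            for site_id, pos in enumerate(m.positions, start=1):
                fh.write(f"{m.map_id}\t{m.length_bp:.1f}\t{n}\t{site_id}\t1\t{pos:.1f}\n")
            fh.write(f"{m.map_id}\t{m.length_bp:.1f}\t{n}\t{n + 1}\t0\t{m.length_bp:.1f}\n")


# ---------------------------------------------------------------------------
# BED annotations


def read_annotations(path) -> list[AnnotationInterval]:
    """Read BED (4+ columns); start is shifted +1 into 1-based inclusive."""
    path = Path(path)
    out: list[AnnotationInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(path, lineno, "BED line needs >=4 columns (incl. name)")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if start >= end:
                raise ParseError(path, lineno, f"inverted interval {start} >= {end}")
            out.append(AnnotationInterval(name, start + 1, end, chrom))
    return out


def write_annotations(intervals: Sequence[AnnotationInterval], path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.reference_id or 'chr22'}\t{iv.start_bp - 1}\t{iv.end_bp}\t{iv.name}\n")
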