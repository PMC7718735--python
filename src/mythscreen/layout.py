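"""Arrayed prey-library layout and 96↔384 plate-format geometry.

A membrane yeast two-hybrid (MYTH) prey library is arrayed in 96-well source
plates.  During screening each bait–prey diploid is pinned in technical
quadruplicate onto 384-spot test plates: the 96-format well (r, c) expands to
the contiguous 2×2 block of 384-format positions
``{(2r-1, 2c-1), (2r-1, 2c), (2r, 2c-1), (2r, 2c)}`` — the standard
replicate-pinning geometry of RoToR-style colony arrayers, which keeps
technical replicates spatially adjacent on the plate photograph.

Coordinates here are 1-based and row-major, matching bench convention
(row A ≡ 1).  Pixel coordinates elsewhere in the package are 0-based; this
module is the boundary between the two conventions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

__all__ = [
    "PlateAddress",
    "LibraryLayout",
    "load_layout",
    "write_layout",
    "map_96_to_384",
    "map_384_to_96",
    "prey_at",
    "EMPTY",
]

#: Marker returned for unoccupied wells.
EMPTY = ""

_FORMAT_DIMS = {96: (8, 12), 384: (16, 24)}

_ROW_LETTERS = "ABCDEFGHIJKLMNOP"


def parse_row(row: Union[int, str], n_rows: int) -> int:
    """Normalize a row given as letter (``'A'``–``'P'``) or integer to 1-based int."""
    if isinstance(row, str):
        r = row.strip()
        if r.isdigit():
            out = int(r)
        elif len(r) == 1 and r.upper() in _ROW_LETTERS:
            out = _ROW_LETTERS.index(r.upper()) + 1
        else:
            raise ValueError(f"unparseable row label: {row!r}")
    else:
        out = int(row)
    if not 1 <= out <= n_rows:
        raise ValueError(f"row {row!r} outside 1..{n_rows}")
    return out


@dataclass(frozen=True, order=True)
class PlateAddress:
    """A well/spot address: 1-based plate, row and column in 96 or 384 format."""

    plate: int
    row: int
    col: int
    format: int = 96

    def __post_init__(self) -> None:
        if self.format not in _FORMAT_DIMS:
            raise ValueError(f"format must be 96 or 384, got {self.format}")
        n_rows, n_cols = _FORMAT_DIMS[self.format]
        if self.plate < 1:
            raise ValueError(f"plate index must be >= 1, got {self.plate}")
        if not 1 <= self.row <= n_rows:
            raise ValueError(
                f"row {self.row} outside 1..{n_rows} for {self.format}-format plate"
            )
        if not 1 <= self.col <= n_cols:
            raise ValueError(
                f"col {self.col} outside 1..{n_cols} for {self.format}-format plate"
            )

    @property
    def row_letter(self) -> str:
        return _ROW_LETTERS[self.row - 1]

    def __str__(self) -> str:  # e.g. "p1:A1" / "p1:O23 (384)"
        suffix = "" if self.format == 96 else " (384)"
        return f"p{self.plate}:{self.row_letter}{self.col}{suffix}"


class LibraryLayout:
    """Mapping from 96-format plate addresses to prey identifiers.

    Wells may be left unoccupied (e.g. for controls); querying them returns
    the empty marker rather than raising.
    """

    def __init__(self, entries: Mapping[PlateAddress, str], n_plates: Optional[int] = None):
        self._entries: dict[PlateAddress, str] = {}
        max_plate = 0
        for addr, prey in entries.items():
            if addr.format != 96:
                raise ValueError(f"layout entries must use 96 format: {addr}")
            if not prey:
                raise ValueError(f"empty prey identifier at {addr}")
            if addr in self._entries:
                raise ValueError(f"duplicate address {addr}")
            self._entries[addr] = prey
            max_plate = max(max_plate, addr.plate)
        self.n_plates = n_plates if n_plates is not None else max_plate
        if max_plate > self.n_plates:
            raise ValueError(
                f"entry addresses plate {max_plate} but n_plates={self.n_plates}"
            )

    @property
    def entries(self) -> dict[PlateAddress, str]:
        return dict(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, addr: PlateAddress) -> bool:
        return addr in self._entries

    def preys(self) -> set[str]:
        return set(self._entries.values())

    def addresses(self) -> list[PlateAddress]:
        return sorted(self._entries)


def map_96_to_384(addr: PlateAddress) -> set[PlateAddress]:
    """Expand a 96-format well to its four quadruplicate 384-format spots."""
    if addr.format != 96:
        raise ValueError(f"expected a 96-format address, got {addr}")
    r, c = addr.row, addr.col
    return {
        PlateAddress(addr.plate, 2 * r - 1 + dr, 2 * c - 1 + dc, format=384)
        for dr in (0, 1)
        for dc in (0, 1)
    }


def map_384_to_96(addr: PlateAddress) -> PlateAddress:
    """Collapse a 384-format spot back onto its 96-format source well."""
    if addr.format != 384:
        raise ValueError(f"expected a 384-format address, got {addr}")
    return PlateAddress(addr.plate, (addr.row + 1) // 2, (addr.col + 1) // 2, format=96)


def prey_at(layout: LibraryLayout, addr: PlateAddress) -> str:
    """Prey identifier at a 96- or 384-format address (``EMPTY`` if unoccupied)."""
    if addr.format == 384:
        addr = map_384_to_96(addr)
    return layout._entries.get(addr, EMPTY)


def load_layout(path: Union[str, Path]) -> LibraryLayout:
    """Read a layout CSV with header ``plate,row,col,prey``.

    Rows are accepted as letters A–H or 1-based integers.  Lines starting
    with ``#`` are ignored.  Duplicate addresses and malformed coordinates
    are hard errors naming the offending address or line.
    """
    path = Path(path)
    entries: dict[PlateAddress, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [
            (lineno, line)
            for lineno, line in enumerate(fh, start=1)
            if line.strip() and not line.lstrip().startswith("#")
        ]
    if not rows:
        raise ValueError(f"{path}: empty layout file")
    reader = csv.DictReader([line for _, line in rows])
    if reader.fieldnames is None or not {"plate", "row", "col", "prey"} <= set(
        f.strip() for f in reader.fieldnames
    ):
        raise ValueError(f"{path}: header must contain plate,row,col,prey")
    linenos = [lineno for lineno, _ in rows][1:]
    for lineno, rec in zip(linenos, reader):
        try:
            plate = int(rec["plate"])
            row = parse_row(rec["row"], 8)
            col = int(rec["col"])
            addr = PlateAddress(plate, row, col, format=96)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
        prey = (rec["prey"] or "").strip()
        if not prey:
            raise ValueError(f"{path}: line {lineno}: empty prey identifier")
        if addr in entries:
            raise ValueError(f"{path}: duplicate address {addr}")
        entries[addr] = prey
    return LibraryLayout(entries)


def write_layout(layout: LibraryLayout, path: Union[str, Path]) -> None:
    """Write a layout back to CSV (inverse of :func:`load_layout`)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["plate", "row", "col", "prey"])
        for addr in layout.addresses():
            writer.writerow([addr.plate, addr.row_letter, addr.col, layout.entries[addr]])


def default_layout(n_plates: int, preys: Optional[Iterable[str]] = None) -> LibraryLayout:
    """Dense row-major layout filling ``n_plates`` 96-well plates.

    With no explicit prey names, wells are named ``prey_0001`` … in pinning
    order.  If ``preys`` is given, fills wells row-major until exhausted
    (trailing wells stay empty, as in a partially filled final plate).
    """
    addrs = [
        PlateAddress(p, r, c, format=96)
        for p in range(1, n_plates + 1)
        for r in range(1, 9)
        for c in range(1, 13)
    ]
    if preys is None:
        preys = [f"prey_{i + 1:04d}" for i in range(len(addrs))]
    else:
        preys = list(preys)
        if len(preys) > len(addrs):
            raise ValueError(f"{len(preys)} preys exceed capacity {len(addrs)}")
    return LibraryLayout(dict(zip(addrs, preys)), n_plates=n_plates)
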