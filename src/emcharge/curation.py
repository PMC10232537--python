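"""Micrograph stage-position proximity filter.

Beam exposure damages an area larger than the imaged hole, so a micrograph
acquired too close to any *previously exposed* position must be discarded.
The filter scans positions in acquisition order and removes a micrograph iff
its stage position lies within ``min_distance`` (default 1.5 um) of any
earlier position -- retained or removed, since both were exposed.  The result
is order-dependent by design.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StagePosition",
    "micrograph_proximity_filter",
    "read_mdoc_positions",
    "read_positions_csv",
]


@dataclass(frozen=True)
class StagePosition:
    micrograph_id: str
    x: float  # stage coordinate, um
    y: float
    acquisition_order: int


def micrograph_proximity_filter(
    positions: Sequence[StagePosition], min_distance: float = 1.5
) -> tuple[list[str], list[str]]:
    """(retained ids, removed ids) after the earlier-exposure distance scan.

    Positions must be supplied in acquisition order (checked); duplicate
    micrograph ids raise.  The first position is always retained.  Removal
    uses strict inequality: distance < min_distance removes.
    """
    ids = [p.micrograph_id for p in positions]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate micrograph ids: {dupes}")
    orders = [p.acquisition_order for p in positions]
    if sorted(orders) != orders or len(set(orders)) != len(orders):
        raise ValueError("positions must be sorted by unique acquisition_order")
    retained, removed = [], []
    xy = np.array([(p.x, p.y) for p in positions], dtype=float).reshape(-1, 2)
    for i, p in enumerate(positions):
        if i and np.min(np.hypot(*(xy[:i] - xy[i]).T)) < min_distance:
            removed.append(p.micrograph_id)
        else:
            retained.append(p.micrograph_id)
    return retained, removed


_MDOC_SECTION = re.compile(r"\[\s*ZValue\s*=\s*(\d+)\s*\]")
_MDOC_KEYVAL = re.compile(r"^\s*(\w+)\s*=\s*(.+?)\s*$")


def read_mdoc_positions(path, micrograph_id: str | None = None) -> list[StagePosition]:
    """StagePosition records from a SerialEM-style .mdoc metadata file.

    Minimal parser: ``[ZValue = k]`` sections with ``StagePosition = x y``
    lines; the micrograph id defaults to ``<stem>#<ZValue>``.
    """
    path = Path(path)
    stem = micrograph_id or path.stem
    out = []
    current = None
    for line in path.read_text().splitlines():
        m = _MDOC_SECTION.search(line)
        if m:
            current = int(m.group(1))
            continue
        kv = _MDOC_KEYVAL.match(line)
        if kv and kv.group(1) == "StagePosition" and current is not None:
            x, y = (float(v) for v in kv.group(2).split()[:2])
            out.append(StagePosition(f"{stem}#{current}", x, y, current))
    return out


def read_positions_csv(path) -> list[StagePosition]:
    """CSV with columns micrograph_id, x, y[, acquisition_order]."""
    out = []
    with open(path, newline="") as fh:
        for k, row in enumerate(csv.DictReader(fh)):
            out.append(
                StagePosition(
                    row["micrograph_id"],
                    float(row["x"]),
                    float(row["y"]),
                    int(row.get("acquisition_order", k)),
                )
            )
    return sorted(out, key=lambda p: p.acquisition_order)
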