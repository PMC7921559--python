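"""Nucleus-cell matching, point-to-cell assignment and cell retention.

Masks are 2D integer label images (0 = background).  Matching pairs each
nucleus with the cell it overlaps most; the retention rule keeps cells with 1
or 2 detected centrosomes and strictly more than 10 detected mRNAs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellRecord",
    "match_nuclei_to_cells",
    "assign_points_to_cells",
    "filter_cells",
    "build_cell_records",
]


@dataclass
class CellRecord:
    cell_id: int
    nucleus_id: int
    spot_indices: list[int] = field(default_factory=list)
    centrosome_indices: list[int] = field(default_factory=list)
    retained: bool = False

    @property
    def n_mrna(self) -> int:
        return len(self.spot_indices)

    @property
    def n_centrosomes(self) -> int:
        return len(self.centrosome_indices)


def match_nuclei_to_cells(
    nucleus_mask: np.ndarray, cell_mask: np.ndarray
) -> dict[int, int]:
    """Pair each nucleus with the cell of maximal pixel overlap.

    Nuclei with zero overlap with any cell are dropped with a warning; a cell
    receives at most one nucleus (conflicts resolved by larger overlap, then
    smaller cell id, then smaller nucleus id); cells without a matched
    nucleus simply do not appear.  Returns nucleus_id -> cell_id.
    """
    if nucleus_mask.shape != cell_mask.shape:
        raise ValueError(
            f"mask shapes differ: {nucleus_mask.shape} vs {cell_mask.shape}"
        )
    nuc = nucleus_mask.ravel()
    cell = cell_mask.ravel()
    inside = (nuc > 0) & (cell > 0)
    pairs, overlaps = np.unique(
        np.stack([nuc[inside], cell[inside]]), axis=1, return_counts=True
    )
    order = np.lexsort((pairs[0], pairs[1], -overlaps))
    mapping: dict[int, int] = {}
    used_cells: set[int] = set()
    for idx in order:
        n_id, c_id = int(pairs[0, idx]), int(pairs[1, idx])
        if n_id in mapping or c_id in used_cells:
            continue
        mapping[n_id] = c_id
        used_cells.add(c_id)
    orphans = set(np.unique(nuc[nuc > 0]).tolist()) - set(mapping)
    if orphans:
        warnings.warn(f"nuclei without a matching cell dropped: {sorted(orphans)}")
    return mapping


def assign_points_to_cells(
    points_px: np.ndarray, cell_mask: np.ndarray
) -> tuple[dict[int, list[int]], list[int]]:
    """Assign each (y, x) point to the label of the pixel containing it.

    Points on background (label 0) or outside the image are unassigned (the
    latter with a warning).  Every input point lands in exactly one bucket.
    """
    points_px = np.asarray(points_px, dtype=float).reshape(-1, 2)
    assigned: dict[int, list[int]] = {}
    unassigned: list[int] = []
    ny, nx = cell_mask.shape
    n_outside = 0
    for i, (y, x) in enumerate(points_px):
        iy, ix = int(round(y)), int(round(x))
        if not (0 <= iy < ny and 0 <= ix < nx):
            unassigned.append(i)
            n_outside += 1
            continue
        label = int(cell_mask[iy, ix])
        if label == 0:
            unassigned.append(i)
        else:
            assigned.setdefault(label, []).append(i)
    if n_outside:
        warnings.warn(f"{n_outside} point(s) outside image bounds left unassigned")
    return assigned, unassigned


def build_cell_records(
    mapping: dict[int, int],
    spot_assignment: dict[int, list[int]],
    centrosome_assignment: dict[int, list[int]],
) -> list[CellRecord]:
    """Combine matching and assignments into one record per matched cell."""
    records = []
    for nucleus_id, cell_id in sorted(mapping.items(), key=lambda kv: kv[1]):
        records.append(
            CellRecord(
                cell_id=cell_id,
                nucleus_id=nucleus_id,
                spot_indices=list(spot_assignment.get(cell_id, [])),
                centrosome_indices=list(centrosome_assignment.get(cell_id, [])),
            )
        )
    return records


def filter_cells(records: list[CellRecord]) -> list[CellRecord]:
    """Retain cells with 1 or 2 centrosomes and more than 10 mRNAs (strict)."""
    kept = []
    for rec in records:
        rec.retained = rec.n_centrosomes in (1, 2) and rec.n_mrna > 10
        if rec.retained:
            kept.append(rec)
    return kept
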