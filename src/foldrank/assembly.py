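"""Divide-and-conquer fragment assembly.

Long filament-like chains defeat end-to-end prediction; predicting
overlapping regions independently and stitching them back is the
workaround.  Each fragment after the first is rigidly superposed onto
the growing assembly over the residues the two share, and overlap
coordinates are taken from the earlier fragment (or blended).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compare import kabsch_superpose
from .containers import StructureModel
from .errors import ArgumentError, AssemblyError

__all__ = ["FragmentModel", "AssemblyResult", "assemble"]


@dataclass
class FragmentModel:
    """One independently predicted region of a full-length chain."""

    model: StructureModel
    span: tuple[int, int]  # 1-based inclusive, full-length numbering

    def validate(self) -> None:
        self.model.validate()
        start, end = self.span
        expected = np.arange(start, end + 1)
        if not np.array_equal(self.model.residue_ids, expected):
            raise ArgumentError(
                f"fragment {self.model.model_id}: residue_ids must cover "
                f"span {start}-{end} contiguously"
            )


@dataclass
class AssemblyResult:
    model: StructureModel
    #: RMSD over each junction's overlap after superposition, Å
    junction_rmsd: list[float]


def assemble(
    fragments: list[FragmentModel],
    min_overlap: int = 20,
    overlap_mode: str = "earlier",
) -> AssemblyResult:
    """Stitch overlapping fragments into one full-length CA model.

    Fragments must be sorted by span start and consecutive spans must
    share at least ``min_overlap`` residues.  The first fragment fixes
    the frame; each later fragment is Kabsch-superposed onto the
    assembly over the shared residues.  ``overlap_mode`` decides what
    an overlap region keeps: ``"earlier"`` (default, deterministic
    geometry from the already-placed fragment) or ``"blend"`` (midpoint
    average of the two copies).
    """
    if not fragments:
        raise ArgumentError("no fragments given")
    if overlap_mode not in ("earlier", "blend"):
        raise ArgumentError(f"unknown overlap_mode {overlap_mode!r}")
    for frag in fragments:
        frag.validate()
    starts = [f.span[0] for f in fragments]
    if starts != sorted(starts):
        raise ArgumentError("fragments must be sorted by span start")

    first = fragments[0]
    placed: dict[int, np.ndarray] = {
        int(r): c.copy()
        for r, c in zip(first.model.residue_ids, first.model.ca_coords)
    }
    sequence: dict[int, str] = {
        int(r): s for r, s in zip(first.model.residue_ids, first.model.sequence)
    }
    junction_rmsd: list[float] = []
    prev_end = first.span[1]

    for k, frag in enumerate(fragments[1:], start=1):
        start, end = frag.span
        if start > prev_end + 1:
            raise AssemblyError(
                f"junction {k}: fragments leave residues "
                f"{prev_end + 1}-{start - 1} uncovered"
            )
        shared = np.array(sorted(set(placed) & set(int(r) for r in frag.model.residue_ids)))
        if len(shared) < min_overlap:
            raise AssemblyError(
                f"junction {k}: overlap of {len(shared)} residues is below "
                f"the minimum of {min_overlap}"
            )
        ref_coords = np.stack([placed[r] for r in shared])
        frag_sub = frag.model.subset(shared)
        sup = kabsch_superpose(ref_coords, frag_sub.ca_coords)
        junction_rmsd.append(sup.rmsd)
        moved = sup.apply(frag.model.ca_coords)
        for r, c, s in zip(frag.model.residue_ids, moved, frag.model.sequence):
            r = int(r)
            if r in placed:
                if overlap_mode == "blend":
                    placed[r] = 0.5 * (placed[r] + c)
            else:
                placed[r] = c
                sequence[r] = s
        prev_end = max(prev_end, end)

    residue_ids = np.array(sorted(placed))
    model = StructureModel(
        model_id="+".join(f.model.model_id for f in fragments),
        residue_ids=residue_ids,
        ca_coords=np.stack([placed[int(r)] for r in residue_ids]),
        sequence="".join(sequence[int(r)] for r in residue_ids),
        generator="other",
    )
    model.validate()
    return AssemblyResult(model=model, junction_rmsd=junction_rmsd)
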