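"""MSA engineering: depth profiling, domain segmentation from template
hits, per-domain alignment pairing and gap padding, full-length
domain-based MSA assembly, and profile-based alignment augmentation.

The pipeline this implements addresses multi-domain targets whose
full-length sequence searches are dominated by one domain: template
hits delineate domains, per-domain searches recover depth for the weak
domains, and the domain alignments are stitched back to full length so
a structure predictor sees one consistent alignment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .containers import (
    AA20,
    DisorderTrack,
    DomainSegmentation,
    Msa,
    SequenceRecord,
    TemplateHit,
)
from .errors import ArgumentError

__all__ = [
    "column_depth",
    "window_mean_depth",
    "filter_hits",
    "segment_domains",
    "pair_domain_alignments",
    "PairedAlignments",
    "pad_unpaired",
    "build_domain_msa",
    "combine_domain_msas",
    "augment_with_profile",
]

#: template-hit significance filters: hits with e-value above
#: MAX_EVALUE, aligned length of at most MIN_ALIGNED_LENGTH residues, or
#: coverage of at most MIN_COVERAGE are considered insignificant.
MAX_EVALUE = 1.0
MIN_ALIGNED_LENGTH = 40
MIN_COVERAGE = 0.5

#: unaligned regions longer than this become their own domain; shorter
#: ones are split between the flanking domains.
GAP_DOMAIN_THRESHOLD = 40


# ---------------------------------------------------------------------------
# Depth profiling
# ---------------------------------------------------------------------------

def column_depth(msa: Msa) -> np.ndarray:
    """Number of sequences (query included) aligned at each match column.

    Insertion states do not contribute: depth is a property of the
    query-indexed columns only.
    """
    depth = np.zeros(msa.n_columns, dtype=np.int64)
    for record in msa.all_records():
        depth += np.frombuffer(record.residues.encode("ascii"), dtype=np.uint8) != ord("-")
    return depth


def window_mean_depth(msa: Msa, start: int, end: int) -> float:
    """Mean column depth over the 1-based inclusive residue interval."""
    if not (1 <= start <= end <= msa.n_columns):
        raise ArgumentError(
            f"window [{start}, {end}] outside alignment of length {msa.n_columns}"
        )
    return float(column_depth(msa)[start - 1 : end].mean())


# ---------------------------------------------------------------------------
# Domain segmentation
# ---------------------------------------------------------------------------

def filter_hits(hits: Sequence[TemplateHit]) -> list[TemplateHit]:
    """Drop insignificant template hits; order is preserved.

    A hit survives iff e-value <= 1, aligned length > 40 residues and
    coverage > 0.5.  Idempotent by construction.
    """
    return [
        h
        for h in hits
        if h.evalue <= MAX_EVALUE
        and h.aligned_length > MIN_ALIGNED_LENGTH
        and h.coverage > MIN_COVERAGE
    ]


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals as maximal continuous runs.

    Intervals that touch (end + 1 == next start) are continuous."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def segment_domains(
    hits: Sequence[TemplateHit],
    target_length: int,
    disorder: DisorderTrack | None = None,
    gap_domain_threshold: int = GAP_DOMAIN_THRESHOLD,
    disorder_run_min: int = 5,
) -> DomainSegmentation:
    """Derive a full-coverage domain partition from filtered template hits.

    Each maximal continuous target region covered by hits is a domain.
    Unaligned gaps longer than ``gap_domain_threshold`` become their own
    domain; shorter internal gaps are split at their midpoint between
    the flanking domains (the left flank takes ``gap // 2`` residues),
    and short leading/trailing gaps are absorbed into the first/last
    domain.  If a disorder track is supplied, any internal boundary that
    falls strictly inside a disordered run of at least
    ``disorder_run_min`` residues is moved to the midpoint of that run.
    """
    if target_length < 1:
        raise ArgumentError("target_length must be >= 1")
    clamped = [
        (max(1, h.target_start), min(target_length, h.target_end))
        for h in hits
        if h.target_start <= target_length and h.target_end >= 1
    ]
    aligned = _merge_intervals(clamped)
    if not aligned:
        return DomainSegmentation(target_length, [(1, target_length)])

    domains: list[list[int]] = []
    # leading gap
    first_start = aligned[0][0]
    lead = first_start - 1
    if lead > gap_domain_threshold:
        domains.append([1, lead])
        domains.append([first_start, aligned[0][1]])
    else:
        domains.append([1, aligned[0][1]])
    # internal gaps
    for (prev_s, prev_e), (next_s, next_e) in zip(aligned, aligned[1:]):
        gap = next_s - prev_e - 1
        if gap > gap_domain_threshold:
            domains.append([prev_e + 1, next_s - 1])
            domains.append([next_s, next_e])
        else:
            split = prev_e + gap // 2
            domains[-1][1] = split
            domains.append([split + 1, next_e])
    # trailing gap
    trail = target_length - aligned[-1][1]
    if trail > gap_domain_threshold:
        domains.append([aligned[-1][1] + 1, target_length])
    else:
        domains[-1][1] = target_length

    boundaries = [d[1] for d in domains[:-1]]
    if disorder is not None:
        if len(disorder) != target_length:
            raise ArgumentError(
                f"disorder track length {len(disorder)} != target {target_length}"
            )
        runs = disorder.runs(min_length=disorder_run_min)
        boundaries = _refine_boundaries(boundaries, runs, target_length)

    out: list[tuple[int, int]] = []
    prev = 0
    for b in [*boundaries, target_length]:
        out.append((prev + 1, b))
        prev = b
    seg = DomainSegmentation(target_length, out)
    seg.validate()
    return seg


def _refine_boundaries(
    boundaries: list[int], runs: list[tuple[int, int]], target_length: int
) -> list[int]:
    """Move boundaries strictly inside a disordered run to its midpoint.

    A boundary b (cut between residues b and b+1) is inside run [s, e]
    when s <= b < e.  Moves that would reorder boundaries or create an
    empty domain are discarded."""
    refined = list(boundaries)
    for i, b in enumerate(boundaries):
        for s, e in runs:
            if s <= b < e:
                candidate = (s + e) // 2
                lo = refined[i - 1] if i > 0 else 0
                hi = refined[i + 1] if i + 1 < len(refined) else target_length
                if lo < candidate < hi:
                    refined[i] = candidate
                break
    return refined


# ---------------------------------------------------------------------------
# Pairing, padding, assembly of domain-based MSAs
# ---------------------------------------------------------------------------

@dataclass
class PairedAlignments:
    """Result of identifier-based pairing across domain alignments."""

    #: full-length (concatenated across domains) paired rows
    paired: list[SequenceRecord] = field(default_factory=list)
    #: per-domain rows that could not be paired, in input order
    unpaired: list[list[SequenceRecord]] = field(default_factory=list)


def pair_domain_alignments(domain_msas: Sequence[Msa]) -> PairedAlignments:
    """Pair rows across domain MSAs by shared (range-stripped) identifier.

    A sequence identifier present in every domain MSA yields one paired
    row: the first occurrence in each MSA, concatenated in domain
    order.  All remaining rows are reported per domain as unpaired.
    """
    if len(domain_msas) < 2:
        raise ArgumentError("pairing requires at least two domain MSAs")
    first_occurrence: list[dict[str, int]] = []
    for msa in domain_msas:
        seen: dict[str, int] = {}
        for i, row in enumerate(msa.rows):
            seen.setdefault(row.base_identifier, i)
        first_occurrence.append(seen)
    shared = [
        ident
        for ident in first_occurrence[0]  # insertion-ordered: first-MSA row order
        if all(ident in occ for occ in first_occurrence[1:])
    ]
    paired = [
        SequenceRecord(
            identifier=ident,
            residues="".join(
                msa.rows[occ[ident]].residues
                for msa, occ in zip(domain_msas, first_occurrence)
            ),
        )
        for ident in shared
    ]
    consumed = [
        {occ[ident] for ident in shared} for occ in first_occurrence
    ]
    unpaired = [
        [row for i, row in enumerate(msa.rows) if i not in used]
        for msa, used in zip(domain_msas, consumed)
    ]
    return PairedAlignments(paired=paired, unpaired=unpaired)


def pad_unpaired(
    row: SequenceRecord, domain: tuple[int, int], target_length: int
) -> SequenceRecord:
    """Embed a domain-local row into full-length coordinates with gaps."""
    start, end = domain
    if len(row.residues) != end - start + 1:
        raise ArgumentError(
            f"{row.identifier}: row length {len(row.residues)} != "
            f"domain length {end - start + 1}"
        )
    return SequenceRecord(
        identifier=row.identifier,
        residues="-" * (start - 1) + row.residues + "-" * (target_length - end),
        description=row.description,
    )


def build_domain_msa(
    full: Msa,
    domain_msas: Sequence[Msa],
    segmentation: DomainSegmentation,
) -> Msa:
    """Assemble a full-length domain-based MSA.

    The output stacks three components under the query: the rows of the
    full-length MSA, the paired domain rows, and the gap-padded
    unpaired domain rows (domain order, input order within a domain).
    Exact duplicates — same identifier and same residue string as an
    earlier row — are dropped.  Insertion states of domain alignments
    are discarded; only match columns are carried to full length.
    """
    segmentation.validate()
    if full.n_columns != segmentation.target_length:
        raise ArgumentError(
            f"full-length MSA has {full.n_columns} columns, "
            f"segmentation target is {segmentation.target_length}"
        )
    if len(domain_msas) != len(segmentation.domains):
        raise ArgumentError(
            f"{len(domain_msas)} domain MSAs for "
            f"{len(segmentation.domains)} domains"
        )
    for msa, (start, end) in zip(domain_msas, segmentation.domains):
        if msa.n_columns != end - start + 1:
            raise ArgumentError(
                f"domain MSA {msa.query.identifier!r} has {msa.n_columns} "
                f"columns for domain [{start}, {end}]"
            )

    if len(domain_msas) >= 2:
        pairing = pair_domain_alignments(domain_msas)
    else:
        pairing = PairedAlignments(
            paired=[], unpaired=[list(m.rows) for m in domain_msas]
        )

    candidates: list[tuple[SequenceRecord, dict[int, str]]] = []
    for row, ins in zip(full.rows, full.insertions):
        candidates.append((row, ins))
    for row in pairing.paired:
        candidates.append((row, {}))
    for domain, residual in zip(segmentation.domains, pairing.unpaired):
        for row in residual:
            candidates.append(
                (pad_unpaired(row, domain, segmentation.target_length), {})
            )

    seen = {(full.query.identifier, full.query.residues)}
    rows: list[SequenceRecord] = []
    insertions: list[dict[int, str]] = []
    for row, ins in candidates:
        key = (row.identifier, row.residues)
        if key in seen:
            continue
        seen.add(key)
        rows.append(row)
        insertions.append(ins)
    out = Msa(
        query=full.query, rows=rows, insertions=insertions, source_tag=full.source_tag
    )
    out.validate()
    return out


def combine_domain_msas(
    full_msas: Sequence[Msa],
    segmented_domain_msas: Sequence[tuple[DomainSegmentation, Sequence[Msa]]],
) -> list[Msa]:
    """Cross every segmentation's domain MSAs with every full-length MSA.

    Four segmentation strategies times two full-length sources gives the
    eight domain-based MSAs used alongside the full-length ones."""
    return [
        build_domain_msa(full, domain_msas, seg)
        for seg, domain_msas in segmented_domain_msas
        for full in full_msas
    ]


# ---------------------------------------------------------------------------
# Profile-based augmentation
# ---------------------------------------------------------------------------

ProfilePredictor = Callable[[Msa], list[list[tuple[str, float]]]]


def _column_profile(msa: Msa) -> list[list[tuple[str, float]]]:
    """Per column: non-query residues ranked by frequency among aligned
    residues (gaps and X excluded), ties broken alphabetically."""
    records = msa.all_records()
    out: list[list[tuple[str, float]]] = []
    for c in range(msa.n_columns):
        query_res = msa.query.residues[c]
        counts: Counter[str] = Counter()
        depth = 0
        for rec in records:
            ch = rec.residues[c].upper()
            if ch == "-":
                continue
            depth += 1
            if ch != query_res and ch in AA20:
                counts[ch] += 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        out.append([(res, n / depth) for res, n in ranked] if depth else [])
    return out


def augment_with_profile(
    msa: Msa,
    n_sequences: int = 2,
    threshold: float = 0.3,
    predictor: ProfilePredictor | None = None,
) -> Msa:
    """Append synthetic sequences derived from confident substitutions.

    Synthetic row ``k`` (1-based) replaces the query residue at each
    position by the k-th most confident substitution proposed by
    ``predictor`` when its confidence exceeds ``threshold``, keeping the
    query residue otherwise.  The default predictor is the alignment's
    own column profile; a masked-language-model scorer can be plugged in
    through the same interface.
    """
    if n_sequences < 1:
        raise ArgumentError("n_sequences must be >= 1")
    profile = (predictor or _column_profile)(msa)
    if len(profile) != msa.n_columns:
        raise ArgumentError("predictor returned wrong number of columns")
    new_rows: list[SequenceRecord] = []
    for k in range(n_sequences):
        chars = []
        for c, query_res in enumerate(msa.query.residues):
            ranked = profile[c]
            if len(ranked) > k and ranked[k][1] > threshold:
                chars.append(ranked[k][0])
            else:
                chars.append(query_res)
        new_rows.append(
            SequenceRecord(identifier=f"synthetic_profile_{k + 1}",
                           residues="".join(chars))
        )
    out = Msa(
        query=msa.query,
        rows=[*msa.rows, *new_rows],
        insertions=[*msa.insertions, *({} for _ in new_rows)],
        source_tag=msa.source_tag,
    )
    out.validate()
    return out
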