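"""Core in-memory containers shared across the toolkit.

The containers are deliberately light: plain dataclasses wrapping numpy
arrays (coordinates, score columns) or strings (alignment rows), with
``validate()`` enforcing the structural invariants each downstream
operation relies on.  All residue numbering is 1-based and inclusive,
following PDB author numbering and CASP convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError, ConfigError, IntegrityError

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: residues legal in a match column (gap and unknown included)
MATCH_ALPHABET = frozenset(AA20 + "X-")

_RANGE_SUFFIX = re.compile(r"^(?P<base>.+)/(?P<start>\d+)-(?P<end>\d+)$")


def split_range_suffix(identifier: str) -> tuple[str, tuple[int, int] | None]:
    """Strip a trailing ``/start-end`` range from a sequence identifier.

    HH-suite tools emit identifiers like ``UniRef100_Q9X2F4/23-180``;
    pairing of domain alignments is done on the base identifier.
    """
    m = _RANGE_SUFFIX.match(identifier)
    if m is None:
        return identifier, None
    return m.group("base"), (int(m.group("start")), int(m.group("end")))


@dataclass
class SequenceRecord:
    """One aligned (or unaligned) sequence.

    ``residues`` holds match-column characters only (upper case plus
    ``-``); insertion states of the A3M dialect are stored on the
    owning :class:`Msa`, not here.
    """

    identifier: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.identifier or any(c.isspace() for c in self.identifier):
            raise ArgumentError(
                f"sequence identifier must be a non-empty token, got {self.identifier!r}"
            )

    @property
    def base_identifier(self) -> str:
        return split_range_suffix(self.identifier)[0]

    @property
    def range(self) -> tuple[int, int] | None:
        return split_range_suffix(self.identifier)[1]

    def validate(self) -> None:
        bad = set(self.residues.upper()) - MATCH_ALPHABET
        if bad:
            raise ArgumentError(
                f"{self.identifier}: illegal residue characters {sorted(bad)}"
            )


MSA_SOURCES = (
    "colabfold",
    "deepmsa_dmsa",
    "deepmsa_qmsa",
    "default_af2",
    "esm_msa",
    "dhr",
    "other",
)


@dataclass
class Msa:
    """Query-anchored multiple sequence alignment (match columns only).

    ``insertions[i]`` maps a match-column index (0-based, insertion
    occurs *after* that column; -1 for an N-terminal insertion) to the
    lowercase inserted residues of row ``i``, mirroring the A3M dialect
    where lowercase letters are not match states.
    """

    query: SequenceRecord
    rows: list[SequenceRecord] = field(default_factory=list)
    insertions: list[dict[int, str]] = field(default_factory=list)
    source_tag: str = "other"

    def __post_init__(self) -> None:
        if not self.insertions:
            self.insertions = [{} for _ in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.query.residues)

    @property
    def n_rows(self) -> int:
        """Total sequences including the query."""
        return 1 + len(self.rows)

    def validate(self) -> None:
        if self.source_tag not in MSA_SOURCES:
            raise ArgumentError(f"unknown MSA source tag {self.source_tag!r}")
        if "-" in self.query.residues:
            raise ArgumentError("query sequence must not contain gaps")
        self.query.validate()
        if len(self.insertions) != len(self.rows):
            raise ArgumentError("insertions list does not match rows")
        for row in self.rows:
            row.validate()
            if len(row.residues) != self.n_columns:
                raise ArgumentError(
                    f"row {row.identifier}: match-column length "
                    f"{len(row.residues)} != query length {self.n_columns}"
                )

    def all_records(self) -> list[SequenceRecord]:
        return [self.query, *self.rows]


GENERATORS = ("af2", "af3", "esmfold", "other")


@dataclass
class StructureModel:
    """Single-chain CA trace with optional per-residue confidence.

    Coordinates are in Angstrom.  ``residue_ids`` are strictly
    increasing author numbers; correspondence between two models is
    established by intersecting them.
    """

    model_id: str
    residue_ids: np.ndarray  # (L,) int
    ca_coords: np.ndarray  # (L, 3) float
    sequence: str
    plddt: np.ndarray | None = None  # (L,) in [0, 100]
    generator: str = "other"
    ranking_score: float | None = None

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=np.int64)
        self.ca_coords = np.asarray(self.ca_coords, dtype=np.float64)
        if self.plddt is not None:
            self.plddt = np.asarray(self.plddt, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.residue_ids)

    def validate(self) -> None:
        L = len(self.residue_ids)
        if self.ca_coords.shape != (L, 3):
            raise ArgumentError(
                f"{self.model_id}: ca_coords shape {self.ca_coords.shape} "
                f"!= ({L}, 3)"
            )
        if len(self.sequence) != L:
            raise ArgumentError(f"{self.model_id}: sequence length != {L}")
        if L and np.any(np.diff(self.residue_ids) <= 0):
            raise ArgumentError(f"{self.model_id}: residue_ids not strictly increasing")
        if not np.all(np.isfinite(self.ca_coords)):
            raise ArgumentError(f"{self.model_id}: non-finite coordinates")
        if self.plddt is not None:
            if self.plddt.shape != (L,):
                raise ArgumentError(f"{self.model_id}: plddt length != {L}")
            if np.any((self.plddt < 0) | (self.plddt > 100)):
                raise ArgumentError(f"{self.model_id}: plddt outside [0, 100]")
        if self.generator not in GENERATORS:
            raise ArgumentError(f"{self.model_id}: unknown generator {self.generator!r}")

    def subset(self, residue_ids: np.ndarray) -> StructureModel:
        """Restrict to the given residue numbers (must all be present)."""
        idx = np.searchsorted(self.residue_ids, residue_ids)
        if np.any(idx >= len(self.residue_ids)) or np.any(
            self.residue_ids[np.minimum(idx, len(self.residue_ids) - 1)] != residue_ids
        ):
            raise ArgumentError(f"{self.model_id}: residues not present in model")
        return StructureModel(
            model_id=self.model_id,
            residue_ids=self.residue_ids[idx],
            ca_coords=self.ca_coords[idx],
            sequence="".join(self.sequence[i] for i in idx),
            plddt=None if self.plddt is None else self.plddt[idx],
            generator=self.generator,
            ranking_score=self.ranking_score,
        )


@dataclass
class TemplateHit:
    """One template alignment interval on the target sequence."""

    template_id: str
    target_start: int
    target_end: int
    evalue: float
    template_length: int
    coverage: float  # aligned length / template length, in [0, 1]

    def __post_init__(self) -> None:
        if self.target_start > self.target_end:
            raise ArgumentError(
                f"{self.template_id}: target_start > target_end "
                f"({self.target_start} > {self.target_end})"
            )
        if self.evalue < 0 or self.template_length <= 0:
            raise ArgumentError(f"{self.template_id}: bad evalue/template_length")

    @property
    def aligned_length(self) -> int:
        return self.target_end - self.target_start + 1


@dataclass
class DomainSegmentation:
    """Ordered, non-overlapping domain intervals covering the target."""

    target_length: int
    domains: list[tuple[int, int]]

    def validate(self) -> None:
        if self.target_length < 1:
            raise ArgumentError("target_length must be >= 1")
        prev_end = 0
        for start, end in self.domains:
            if start != prev_end + 1 or end < start:
                raise ArgumentError(
                    f"domains do not partition 1..{self.target_length}: "
                    f"{self.domains}"
                )
            prev_end = end
        if prev_end != self.target_length:
            raise ArgumentError(
                f"domains cover 1..{prev_end}, target length is {self.target_length}"
            )

    def __len__(self) -> int:
        return len(self.domains)


@dataclass
class DisorderTrack:
    """Per-residue disorder labels (True = predicted disordered)."""

    labels: np.ndarray  # (target_length,) bool

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)

    def __len__(self) -> int:
        return len(self.labels)

    def runs(self, min_length: int = 1) -> list[tuple[int, int]]:
        """1-based inclusive [start, end] intervals of disordered runs."""
        out: list[tuple[int, int]] = []
        start = None
        for i, lab in enumerate(self.labels, start=1):
            if lab and start is None:
                start = i
            elif not lab and start is not None:
                if i - start >= min_length:
                    out.append((start, i - 1))
                start = None
        if start is not None and len(self.labels) - start + 1 >= min_length:
            out.append((start, len(self.labels)))
        return out


class ScoreTable:
    """Per-model QA score columns with explicit missing values (NaN).

    Columns are free-form score names (``plddt_global``, ``af3_ranking``,
    ``gate``, ``enqa``, ``gcpnet_ema``, ``pss`` ...).  Global plDDT is on
    the predictor's native 0-100 scale; everything else is whatever scale
    the producing method emits — consumers normalise.
    """

    def __init__(self, model_ids: list[str], columns: dict[str, np.ndarray] | None = None):
        if len(set(model_ids)) != len(model_ids):
            dupes = sorted({m for m in model_ids if model_ids.count(m) > 1})
            raise IntegrityError(f"duplicate model_id(s): {dupes}")
        self.model_ids = list(model_ids)
        self.columns: dict[str, np.ndarray] = {}
        for name, values in (columns or {}).items():
            self.add_column(name, values)

    def add_column(self, name: str, values) -> None:
        arr = np.asarray(values, dtype=np.float64)
        if arr.shape != (len(self.model_ids),):
            raise ArgumentError(
                f"column {name!r}: length {arr.shape} != {len(self.model_ids)} models"
            )
        if name == "plddt_global":
            present = arr[np.isfinite(arr)]
            if present.size and (present.min() < 0 or present.max() > 100):
                raise ArgumentError("plddt_global outside [0, 100]")
        self.columns[name] = arr

    def __contains__(self, name: str) -> bool:
        return name in self.columns

    def column(self, name: str) -> np.ndarray:
        try:
            return self.columns[name]
        except KeyError:
            raise ConfigError(
                f"unknown score column {name!r}; available: {sorted(self.columns)}"
            ) from None

    def index_of(self, model_id: str) -> int:
        return self.model_ids.index(model_id)


@dataclass
class EvalTable:
    """Predictor x domain accuracy matrix (GDT-TS in [0,1]; NaN = no submission)."""

    predictors: list[str]
    domains: list[str]
    gdt: np.ndarray  # (n_predictors, n_domains) float with NaN

    def __post_init__(self) -> None:
        self.gdt = np.asarray(self.gdt, dtype=np.float64)
        if self.gdt.shape != (len(self.predictors), len(self.domains)):
            raise ArgumentError(
                f"gdt shape {self.gdt.shape} != "
                f"({len(self.predictors)}, {len(self.domains)})"
            )
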