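"""Readers and writers for the external formats the toolkit touches.

Sequence alignments use the HH-suite A3M dialect: the first record is
the query (defines the match columns), lowercase letters in later rows
are insertion states relative to the query and are excluded from every
column-indexed computation.  Structures are single-chain PDB files read
through gemmi (CA atoms only).  Score, template-hit, disorder and
evaluation tables are comma- or tab-delimited text with a header line;
the delimiter is sniffed from the header.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .containers import (
    DisorderTrack,
    DomainSegmentation,
    EvalTable,
    Msa,
    ScoreTable,
    SequenceRecord,
    StructureModel,
    TemplateHit,
)
from .errors import ChainNotFoundError, IntegrityError, ParseError

__all__ = [
    "read_a3m",
    "write_a3m",
    "read_fasta",
    "read_pdb_chain",
    "write_pdb",
    "read_score_table",
    "write_score_table",
    "read_hit_table",
    "write_hit_table",
    "read_disorder_track",
    "read_segmentation",
    "write_segmentation",
    "read_eval_table",
    "write_eval_table",
]


# ---------------------------------------------------------------------------
# FASTA / A3M
# ---------------------------------------------------------------------------

def _iter_fasta_records(text: str, origin: str):
    """Yield (identifier, description, sequence, line_number) tuples."""
    header = None
    header_line = 0
    chunks: list[str] = []
    n_records = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                yield (*header, "".join(chunks), header_line)
            token = line[1:].split(None, 1)
            if not token or not token[0]:
                raise ParseError(f"{origin}:{lineno}: empty FASTA header")
            header = (token[0], token[1] if len(token) > 1 else "")
            header_line = lineno
            chunks = []
            n_records += 1
        else:
            if header is None:
                raise ParseError(
                    f"{origin}:{lineno}: sequence data before any '>' header"
                )
            chunks.append(line.replace(" ", ""))
    if header is not None:
        yield (*header, "".join(chunks), header_line)
    if n_records == 0:
        raise ParseError(f"{origin}: no FASTA records found")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read plain (already upper-case) FASTA records."""
    text = Path(path).read_text()
    return [
        SequenceRecord(identifier=ident, residues=seq, description=desc)
        for ident, desc, seq, _ in _iter_fasta_records(text, str(path))
    ]


def _split_a3m_row(seq: str, n_columns: int, origin: str, lineno: int):
    """Split an A3M row into match-column string and insertion map."""
    match_chars: list[str] = []
    insertions: dict[int, str] = {}
    for ch in seq:
        if ch.islower():
            col = len(match_chars) - 1  # -1 => N-terminal insertion
            insertions[col] = insertions.get(col, "") + ch
        elif ch == "." :
            continue  # '.' is a null insertion state in some emitters
        else:
            match_chars.append(ch)
    matched = "".join(match_chars)
    if len(matched) != n_columns:
        raise ParseError(
            f"{origin}:{lineno}: row has {len(matched)} match columns, "
            f"query has {n_columns} (A3M dialect violation)"
        )
    return matched, insertions


def read_a3m(path: str | Path, source_tag: str = "other") -> Msa:
    """Read a query-anchored A3M (or aligned FASTA) alignment.

    The first record must be the query and contain neither gaps nor
    lowercase insertion states.
    """
    text = Path(path).read_text()
    records = list(_iter_fasta_records(text, str(path)))
    q_ident, q_desc, q_seq, q_line = records[0]
    if any(c.islower() or c == "-" for c in q_seq):
        raise ParseError(
            f"{path}:{q_line}: first record (query) must contain no "
            "gaps or lowercase insertion states"
        )
    query = SequenceRecord(identifier=q_ident, residues=q_seq, description=q_desc)
    rows: list[SequenceRecord] = []
    insertions: list[dict[int, str]] = []
    for ident, desc, seq, lineno in records[1:]:
        matched, ins = _split_a3m_row(seq, len(q_seq), str(path), lineno)
        rows.append(SequenceRecord(identifier=ident, residues=matched, description=desc))
        insertions.append(ins)
    msa = Msa(query=query, rows=rows, insertions=insertions, source_tag=source_tag)
    msa.validate()
    return msa


def write_a3m(msa: Msa, path: str | Path) -> None:
    """Write the alignment back out, reinserting lowercase states."""
    with open(path, "w") as fh:
        _write_record(fh, msa.query, {})
        for row, ins in zip(msa.rows, msa.insertions):
            _write_record(fh, row, ins)


def _write_record(fh, record: SequenceRecord, insertions: dict[int, str]) -> None:
    desc = f" {record.description}" if record.description else ""
    fh.write(f">{record.identifier}{desc}\n")
    if not insertions:
        fh.write(record.residues + "\n")
        return
    parts = [insertions.get(-1, "")]
    for col, ch in enumerate(record.residues):
        parts.append(ch)
        parts.append(insertions.get(col, ""))
    fh.write("".join(parts) + "\n")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb_chain(
    path: str | Path,
    chain: str = "A",
    bfactor_is_plddt: bool = False,
    model_id: str | None = None,
    generator: str = "other",
) -> StructureModel:
    """Read one chain's CA trace from a PDB file.

    Altloc duplicates are resolved by highest occupancy, then first
    seen.  Residues lacking a CA atom are skipped with a warning.
    Insertion codes are rejected: CASP models use plain numbering.
    """
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ParseError(f"{path}: no models in PDB file")
    gchain = st[0].find_chain(chain)
    if gchain is None:
        available = [c.name for c in st[0]]
        raise ChainNotFoundError(
            f"{path}: chain {chain!r} not found (available: {available})"
        )
    residue_ids: list[int] = []
    coords: list[list[float]] = []
    sequence: list[str] = []
    bfactors: list[float] = []
    n_skipped = 0
    for res in gchain:
        if res.het_flag == "H":
            continue
        if res.seqid.icode not in (" ", "\x00", ""):
            raise ParseError(
                f"{path}: residue {res.seqid.num}{res.seqid.icode} has an "
                "insertion code; renumber the chain first"
            )
        cas = [a for a in res if a.name == "CA"]
        if not cas:
            n_skipped += 1
            continue
        # stable sort keeps first-seen on occupancy ties
        ca = max(cas, key=lambda a: a.occ)
        residue_ids.append(res.seqid.num)
        coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
        info = gemmi.find_tabulated_residue(res.name)
        sequence.append(info.one_letter_code.upper() if info else "X")
        bfactors.append(ca.b_iso)
    if n_skipped:
        warnings.warn(
            f"{path}: skipped {n_skipped} residue(s) without a CA atom",
            stacklevel=2,
        )
    order = np.argsort(residue_ids, kind="stable")
    residue_ids_arr = np.asarray(residue_ids)[order]
    if len(residue_ids_arr) != len(set(residue_ids)):
        raise ParseError(f"{path}: duplicate residue numbers in chain {chain}")
    model = StructureModel(
        model_id=model_id or Path(path).stem,
        residue_ids=residue_ids_arr,
        ca_coords=np.asarray(coords)[order],
        sequence="".join(sequence[i] for i in order),
        plddt=np.asarray(bfactors)[order] if bfactor_is_plddt else None,
        generator=generator,
    )
    model.validate()
    return model


_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def write_pdb(model: StructureModel, path: str | Path, chain: str = "A") -> None:
    """Write a CA-only chain; plDDT (if any) goes in the B-factor column."""
    model.validate()
    st = gemmi.Structure()
    st.name = model.model_id
    gmodel = gemmi.Model("1")
    gchain = gemmi.Chain(chain)
    for i, (rid, xyz) in enumerate(zip(model.residue_ids, model.ca_coords)):
        res = gemmi.Residue()
        res.name = _ONE_TO_THREE.get(model.sequence[i], "UNK")
        res.seqid = gemmi.SeqId(int(rid), " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        atom.occ = 1.0
        atom.b_iso = float(model.plddt[i]) if model.plddt is not None else 0.0
        res.add_atom(atom)
        gchain.add_residue(res)
    gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------

def _read_delimited(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=None, engine="python",
                           na_values=["NA", "na", ""], **kwargs)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_score_table(path: str | Path) -> ScoreTable:
    """Read per-model QA scores; first column is the model id."""
    df = _read_delimited(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected model_id plus >=1 score column")
    ids = df.iloc[:, 0].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({m for m in ids if ids.count(m) > 1})
        raise IntegrityError(f"{path}: duplicate model_id(s): {dupes}")
    table = ScoreTable(ids)
    for name in df.columns[1:]:
        values = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        table.add_column(str(name), values)
    return table


def write_score_table(table: ScoreTable, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame({"model_id": table.model_ids, **table.columns})
    df.to_csv(path, sep=sep, index=False, na_rep="NA")


_HIT_COLUMNS = ["template_id", "target_start", "target_end",
                "evalue", "template_length", "coverage"]


def read_hit_table(path: str | Path) -> list[TemplateHit]:
    df = _read_delimited(path)
    missing = [c for c in _HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing hit-table columns {missing}")
    return [
        TemplateHit(
            template_id=str(r.template_id),
            target_start=int(r.target_start),
            target_end=int(r.target_end),
            evalue=float(r.evalue),
            template_length=int(r.template_length),
            coverage=float(r.coverage),
        )
        for r in df.itertuples(index=False)
    ]


def write_hit_table(hits: list[TemplateHit], path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        [(h.template_id, h.target_start, h.target_end,
          h.evalue, h.template_length, h.coverage) for h in hits],
        columns=_HIT_COLUMNS,
    )
    df.to_csv(path, sep=sep, index=False)


def read_disorder_track(path: str | Path) -> DisorderTrack:
    """Two-column text (residue number, 0/1 disorder label), with header."""
    df = _read_delimited(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (residue, label)")
    resnum = df.iloc[:, 0].to_numpy(dtype=int)
    labels = df.iloc[:, 1].to_numpy(dtype=int)
    if not np.array_equal(resnum, np.arange(1, len(resnum) + 1)):
        raise ParseError(f"{path}: residue numbers must run 1..N without gaps")
    if not np.isin(labels, [0, 1]).all():
        raise ParseError(f"{path}: disorder labels must be 0 or 1")
    return DisorderTrack(labels=labels.astype(bool))


def read_segmentation(path: str | Path, target_length: int) -> DomainSegmentation:
    """Delimited intervals (columns start, end) forming a partition."""
    df = _read_delimited(path)
    if not {"start", "end"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns 'start' and 'end'")
    seg = DomainSegmentation(
        target_length=target_length,
        domains=[(int(r.start), int(r.end)) for r in df.itertuples(index=False)],
    )
    seg.validate()
    return seg


def write_segmentation(seg: DomainSegmentation, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(seg.domains, columns=["start", "end"]).to_csv(path, sep=sep, index=False)


def read_eval_table(path: str | Path) -> EvalTable:
    """Predictor x domain GDT-TS matrix; 'NA' marks missing submissions."""
    df = _read_delimited(path, index_col=0)
    gdt = df.to_numpy(dtype=float)
    finite = gdt[np.isfinite(gdt)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ParseError(f"{path}: GDT-TS values must lie in [0, 1]")
    return EvalTable(
        predictors=[str(p) for p in df.index],
        domains=[str(d) for d in df.columns],
        gdt=gdt,
    )


def write_eval_table(table: EvalTable, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(table.gdt, index=table.predictors, columns=table.domains)
    df.to_csv(path, sep=sep, na_rep="NA", index_label="predictor")
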