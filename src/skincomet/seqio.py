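"""Readers and writers for the external formats the pipeline touches.

Everything downstream works on three carriers: :class:`ProteinRecord` for
annotated coding sequences, :class:`LabeledMatrix` for samples x features
tables with an explicit normalization state, and :class:`ModuleDef` for the
curated pathway -> gene-model catalog.  All tabular I/O is UTF-8
tab-separated text with '.' decimals; lines starting with '#' are treated
as provenance comments and skipped on read.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, alphabetical one-letter codes.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA20_SET = frozenset(AA20)

#: Ambiguity codes folded into 'X' on read (B=D/N, Z=E/Q, J=I/L, U=Sec).
AMBIGUOUS_TO_X = {"B": "X", "Z": "X", "U": "X", "J": "X"}


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates a contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """One annotated protein-coding sequence from a reference genome or
    gene catalog.  ``sequence`` is uppercase over the 20-letter alphabet,
    with 'X' tolerated for ambiguous residues."""

    protein_id: str
    genome_id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"protein {self.protein_id!r}: empty sequence")
        if any(c.isspace() for c in self.protein_id):
            raise ValidationError(f"protein id {self.protein_id!r} contains whitespace")


@dataclass(frozen=True)
class SeedGene:
    """One row of the curated seed-gene table: a literature-derived gene
    symbol (and optional locus tag / organism) assigned to a pathway."""

    gene_symbol: str
    locus_tag: str
    organism: str
    pathway: str


@dataclass(frozen=True)
class ModuleDef:
    """A named co-metabolism pathway and the gene models that belong to it."""

    pathway: str
    module_id: str
    member_models: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.member_models:
            raise ValidationError(f"module {self.module_id!r} has no member models")


class NormState(str, Enum):
    raw_counts = "raw_counts"
    sample_relative = "sample_relative"
    module_max = "module_max"
    row_max = "row_max"


@dataclass
class LabeledMatrix:
    """A labelled non-negative matrix with a declared normalization state.

    Thin wrapper around a :class:`pandas.DataFrame`; the ``norm_state``
    field records which of the pipeline's normalizations have been applied
    so downstream operations can refuse tables in the wrong state.
    """

    df: pd.DataFrame
    norm_state: NormState = NormState.raw_counts

    def __post_init__(self) -> None:
        self.norm_state = NormState(self.norm_state)
        vals = self.df.to_numpy(dtype=float)
        if vals.size and not (vals >= 0).all():
            raise ValidationError("matrix contains negative values")
        if vals.size and not pd.notna(vals).all():
            raise ValidationError("matrix contains missing values")
        if vals.size and not (abs(vals) < math.inf).all():
            raise ValidationError("matrix contains non-finite values")
        if self.df.index.duplicated().any() or self.df.columns.duplicated().any():
            raise ValidationError("duplicate row or column labels")

    @property
    def row_ids(self) -> list[str]:
        return [str(i) for i in self.df.index]

    @property
    def col_ids(self) -> list[str]:
        return [str(c) for c in self.df.columns]


def _clean_sequence(raw: str, protein_id: str) -> str:
    seq = raw.upper().rstrip("*")
    mapped = []
    for pos, c in enumerate(seq, start=1):
        if c in AA20_SET or c == "X":
            mapped.append(c)
        elif c in AMBIGUOUS_TO_X:
            logger.warning(
                "protein %s: ambiguous residue %r at position %d mapped to X",
                protein_id, c, pos,
            )
            mapped.append("X")
        else:
            raise ValidationError(
                f"protein {protein_id!r}: invalid character {c!r} at position {pos}"
            )
    seq = "".join(mapped)
    if not seq:
        raise ValidationError(f"protein {protein_id!r}: empty sequence")
    return seq


def read_fasta(path: str | Path, genome_id: str | None = None) -> list[ProteinRecord]:
    """Read a protein FASTA file into validated :class:`ProteinRecord`\\ s.

    ``genome_id`` defaults to the file's stem.  Sequences are uppercased,
    terminal '*' stop characters stripped, ambiguity codes folded into 'X'
    with a logged warning, and any other non-amino-acid character rejected
    with its position.  Duplicate ids within the file are an error.
    """
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = entry.id
        if pid in seen:
            raise ValidationError(f"duplicate protein id {pid!r} in {path}")
        seen.add(pid)
        seq = _clean_sequence(str(entry.seq), pid)
        records.append(
            ProteinRecord(protein_id=pid, genome_id=gid, sequence=seq,
                          description=entry.description)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n{rec.sequence}\n")


def read_manifest(path: str | Path) -> dict[str, str]:
    """Read a genome manifest TSV (columns: genome_id, fasta_path)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("genome_id", "fasta_path"):
        if col not in df.columns:
            raise ValidationError(f"manifest missing column {col!r}")
    if df["genome_id"].duplicated().any():
        dup = df["genome_id"][df["genome_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate genome_id {dup!r} in manifest")
    return dict(zip(df["genome_id"], df["fasta_path"]))


def read_matrix_tsv(path: str | Path,
                    norm_state: NormState | str = NormState.raw_counts) -> LabeledMatrix:
    """Read a labelled numeric TSV (first row column ids, first column row
    ids).  Ragged rows are rejected with their line number; negative or
    missing cells are rejected."""
    path = Path(path)
    header: list[str] | None = None
    row_ids: list[str] = []
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                continue
            line = line.rstrip("\n")
            if line == "":
                continue
            cells = line.split("\t")
            if header is None:
                header = cells[1:]
                if not header:
                    raise ValidationError(f"{path}:{lineno}: header has no columns")
                continue
            if len(cells) != len(header) + 1:
                raise ValidationError(
                    f"{path}:{lineno}: ragged row ({len(cells)} cells, "
                    f"expected {len(header) + 1})"
                )
            row_ids.append(cells[0])
            values = []
            for j, cell in enumerate(cells[1:]):
                if cell == "":
                    raise ValidationError(f"{path}:{lineno}: missing cell in column {j + 1}")
                try:
                    v = float(cell)
                except ValueError as exc:
                    raise ValidationError(f"{path}:{lineno}: non-numeric cell {cell!r}") from exc
                if not math.isfinite(v):
                    raise ValidationError(f"{path}:{lineno}: non-finite value {cell!r}")
                if v < 0:
                    raise ValidationError(f"{path}:{lineno}: negative value {cell!r}")
                values.append(v)
            rows.append(values)
    if header is None:
        raise ValidationError(f"{path}: empty file")
    if not rows:
        raise ValidationError(f"{path}: no rows")
    df = pd.DataFrame(rows, index=row_ids, columns=header)
    return LabeledMatrix(df, NormState(norm_state))


def write_matrix_tsv(matrix: LabeledMatrix, path: str | Path,
                     provenance: Mapping[str, object] | None = None) -> None:
    """Write a :class:`LabeledMatrix` as TSV, preserving values to 12
    significant digits so that read -> write -> read round-trips.  Optional
    ``provenance`` pairs are written as leading '#' comment lines."""
    for label in list(matrix.row_ids) + list(matrix.col_ids):
        if "\t" in label or "\n" in label:
            raise ValidationError(f"label {label!r} contains a tab or newline")
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("\t".join([""] + matrix.col_ids) + "\n")
        for rid, row in zip(matrix.row_ids, matrix.df.to_numpy(dtype=float)):
            cells = [f"{v:.12g}" for v in row]
            fh.write("\t".join([rid] + cells) + "\n")


def read_module_catalog(path: str | Path) -> list[ModuleDef]:
    """Read a module catalog TSV (columns: pathway, module_id, model_name).

    A model name may belong to exactly one module; duplicates across
    modules are an error because module scores are sums over members and a
    shared member would be double-counted.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("pathway", "module_id", "model_name"):
        if col not in df.columns:
            raise ValidationError(f"module catalog missing column {col!r}")
    owner: dict[str, str] = {}
    for _, row in df.iterrows():
        model = row["model_name"]
        if model in owner and owner[model] != row["module_id"]:
            raise ValidationError(
                f"model {model!r} listed under two modules "
                f"({owner[model]!r} and {row['module_id']!r})"
            )
        owner[model] = row["module_id"]
    modules: list[ModuleDef] = []
    for (pathway, module_id), grp in df.groupby(["pathway", "module_id"], sort=False):
        models = tuple(dict.fromkeys(grp["model_name"]))
        modules.append(ModuleDef(pathway=pathway, module_id=module_id,
                                 member_models=models))
    return modules


def default_module_catalog() -> list[ModuleDef]:
    """The shipped catalog of ten skin-aging co-metabolism pathways and
    their literature-derived bacterial gene models."""
    with resources.as_file(
        resources.files("skincomet").joinpath("data/modules_table1.tsv")
    ) as p:
        return read_module_catalog(p)


def read_seed_genes(path: str | Path,
                    catalog: Sequence[ModuleDef] | None = None) -> list[SeedGene]:
    """Read a seed-gene table TSV (columns: gene_symbol, locus_tag,
    organism, pathway).  When ``catalog`` is given, every pathway must
    appear in it."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    for col in ("gene_symbol", "locus_tag", "organism", "pathway"):
        if col not in df.columns:
            raise ValidationError(f"seed gene table missing column {col!r}")
    known = {m.pathway for m in catalog} if catalog is not None else None
    out = []
    for i, row in df.iterrows():
        if not row["gene_symbol"] or not row["pathway"]:
            raise ValidationError(f"seed gene row {i}: empty gene_symbol or pathway")
        if known is not None and row["pathway"] not in known:
            raise ValidationError(
                f"seed gene row {i}: pathway {row['pathway']!r} not in catalog"
            )
        out.append(SeedGene(row["gene_symbol"], row["locus_tag"],
                            row["organism"], row["pathway"]))
    return out
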