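"""Readers, writers and the typed containers shared by every analysis stage.

External representations handled here: FASTA (via Bio.SeqIO, 60-column wrap on
write), tab-separated tables (expression matrices, per-residue score tracks,
span files), Newick trees (leaf-label validation via dendropy) and the JSON
analysis report. Downstream modules only ever see the types defined in this
module.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
DNA_ALPHABET = set("ACGT")
GAP = "-"

FASTA_WRAP = 60


class FormatError(ValueError):
    """An input file violates its declared format; the message locates the problem."""


class ConfigurationError(ValueError):
    """Metadata (roles, spans, config) is inconsistent with the data it describes."""


# ---------------------------------------------------------------------------
# Sequences


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence over a declared alphabet.

    ``alphabet`` is ``"protein"`` (20 canonical residues + X unknown) or
    ``"dna"`` (ACGT + N unknown). The gap character ``-`` is tolerated so the
    same type can carry alignment rows.
    """

    id: str
    description: str
    residues: str
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record has an empty id")
        if not self.residues:
            raise FormatError(f"sequence {self.id!r}: empty sequence")
        if self.alphabet not in ("protein", "dna"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        allowed = PROTEIN_ALPHABET | {"X"} if self.alphabet == "protein" else DNA_ALPHABET | {"N"}
        allowed = allowed | {GAP}
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in allowed:
                raise FormatError(
                    f"sequence {self.id!r}: illegal {self.alphabet} character "
                    f"{ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects, order preserved.

    Record ids are the first whitespace-delimited token of the header; the
    remainder is kept as the description. Empty files, duplicate ids and
    characters outside the declared alphabet raise :class:`FormatError`.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(
            SequenceRecord(
                id=rec.id,
                description=desc,
                residues=str(rec.seq).upper(),
                alphabet=alphabet,
            )
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Expression tables

SPECIES_ROLES = ("glue", "nonglue")
GENE_CLASSES = ("reference", "focal")


@dataclass
class ExpressionTable:
    """Genes x species TPM matrix with species roles and gene classes.

    ``species_role`` maps every species to ``glue`` or ``nonglue``;
    ``gene_class`` maps every gene to ``reference`` (single-copy null gene) or
    ``focal`` (candidate glue gene).
    """

    genes: list[str]
    species: list[str]
    values: np.ndarray  # shape (n_genes, n_species), TPM
    species_role: dict[str, str]
    gene_class: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.species)):
            raise ValueError("values shape does not match gene/species lists")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate gene ids in expression table")
        if len(set(self.species)) != len(self.species):
            raise FormatError("duplicate species ids in expression table")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression table contains non-finite values")
        if np.any(self.values < 0):
            g, s = map(int, np.argwhere(self.values < 0)[0])
            raise FormatError(
                f"negative TPM at gene {self.genes[g]!r}, species {self.species[s]!r}"
            )
        for sp in self.species:
            role = self.species_role.get(sp)
            if role is None:
                raise ConfigurationError(f"species {sp!r} missing from roles")
            if role not in SPECIES_ROLES:
                raise ConfigurationError(f"species {sp!r}: unknown role {role!r}")
        roles = {self.species_role[sp] for sp in self.species}
        if roles != set(SPECIES_ROLES):
            raise ConfigurationError("table needs at least one glue and one non-glue species")
        for g in self.genes:
            cls = self.gene_class.setdefault(g, "reference")
            if cls not in GENE_CLASSES:
                raise ConfigurationError(f"gene {g!r}: unknown class {cls!r}")
        self._gi = {g: i for i, g in enumerate(self.genes)}
        self._si = {s: i for i, s in enumerate(self.species)}

    def tpm(self, gene: str, species: str) -> float:
        return float(self.values[self._gi[gene], self._si[species]])

    @property
    def nonglue_species(self) -> list[str]:
        return [s for s in self.species if self.species_role[s] == "nonglue"]

    @property
    def reference_genes(self) -> list[str]:
        return [g for g in self.genes if self.gene_class[g] == "reference"]

    @property
    def focal_genes(self) -> list[str]:
        return [g for g in self.genes if self.gene_class[g] == "focal"]


def read_roles(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Parse a roles TSV: lines ``kind<TAB>id<TAB>value`` with kind species|gene."""
    species_role: dict[str, str] = {}
    gene_class: dict[str, str] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
            kind, ident, value = parts
            if kind == "species":
                species_role[ident] = value
            elif kind == "gene":
                gene_class[ident] = value
            else:
                raise FormatError(f"{path}:{lineno}: unknown kind {kind!r}")
    return species_role, gene_class


def read_expression_table(path: str | Path, roles_path: str | Path) -> ExpressionTable:
    """Read a TPM matrix (genes in rows, species in columns) plus its roles file."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise FormatError(f"{path}: missing value in row {row!r}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    if np.any(values < 0):
        g, s = map(int, np.argwhere(values < 0)[0])
        raise FormatError(
            f"{path}: negative TPM at row {df.index[g]!r}, column {df.columns[s]!r}"
        )
    species_role, gene_class = read_roles(roles_path)
    for sp in df.columns:
        if sp not in species_role:
            raise ConfigurationError(f"{path}: species {sp!r} absent from roles file")
    return ExpressionTable(
        genes=[str(g) for g in df.index],
        species=[str(s) for s in df.columns],
        values=values,
        species_role=species_role,
        gene_class={g: gene_class.get(str(g), "reference") for g in df.index},
    )


def write_expression_table(table: ExpressionTable, path: str | Path, roles_path: str | Path | None = None) -> None:
    df = pd.DataFrame(table.values, index=table.genes, columns=table.species)
    df.index.name = "gene"
    df.to_csv(path, sep="\t")
    if roles_path is not None:
        with open(roles_path, "w") as fh:
            for sp in table.species:
                fh.write(f"species\t{sp}\t{table.species_role[sp]}\n")
            for g in table.genes:
                fh.write(f"gene\t{g}\t{table.gene_class[g]}\n")


# ---------------------------------------------------------------------------
# Per-residue tracks

TRACK_KINDS = ("disorder", "glyco", "secstruct")
SECSTRUCT_STATES = set("HEC")


@dataclass
class ResidueTrack:
    """Per-residue scores or states for one sequence, 1-based and contiguous.

    ``values`` holds floats in [0, 1] for ``disorder``/``glyco`` tracks and
    single characters from {H, E, C} for ``secstruct`` tracks.
    """

    sequence_id: str
    kind: str
    values: list

    def __post_init__(self) -> None:
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")
        if not self.values:
            raise FormatError(f"track for {self.sequence_id!r}: empty")
        if self.kind == "secstruct":
            for pos, v in enumerate(self.values, start=1):
                if v not in SECSTRUCT_STATES:
                    raise FormatError(
                        f"track {self.sequence_id!r}: state {v!r} at position {pos} "
                        "not in {H, E, C}"
                    )
        else:
            for pos, v in enumerate(self.values, start=1):
                v = float(v)
                if math.isnan(v) or not (0.0 <= v <= 1.0):
                    raise FormatError(
                        f"track {self.sequence_id!r}: value {v} at position {pos} "
                        "outside [0, 1]"
                    )
            self.values = [float(v) for v in self.values]

    def __len__(self) -> int:
        return len(self.values)

    def slice(self, start: int, end: int) -> list:
        """Values over the 1-based inclusive span [start, end]."""
        if not (1 <= start <= end <= len(self.values)):
            raise ValueError(f"span ({start}, {end}) outside track of length {len(self)}")
        return self.values[start - 1 : end]


def read_residue_track(path: str | Path, kind: str, sequence_id: str | None = None) -> ResidueTrack:
    """Read a ``position<TAB>value`` TSV; positions must run 1, 2, ... n."""
    path = Path(path)
    values: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("position"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'position<TAB>value'")
            pos = int(parts[0])
            if pos != len(values) + 1:
                raise FormatError(
                    f"{path}:{lineno}: position {pos} breaks 1-based contiguity "
                    f"(expected {len(values) + 1})"
                )
            values.append(parts[1] if kind == "secstruct" else float(parts[1]))
    if sequence_id is None:
        sequence_id = path.stem
    return ResidueTrack(sequence_id=sequence_id, kind=kind, values=values)


def write_residue_track(track: ResidueTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pos, v in enumerate(track.values, start=1):
            if isinstance(v, float):
                fh.write(f"{pos}\t{v:.6g}\n")
            else:
                fh.write(f"{pos}\t{v}\n")


# ---------------------------------------------------------------------------
# Codon alignments


@dataclass
class CodonAlignmentSet:
    """Aligned coding sequences (length divisible by 3) with an optional tree.

    Gaps must occupy whole codons; a triplet mixing gap and nucleotide
    characters is a format error because every downstream operation works
    codon-wise. ``tree`` is a Newick string whose leaf labels match record ids.
    """

    records: list[SequenceRecord]
    tree: str | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("codon alignment: no records")
        length = len(self.records[0].residues)
        if length % 3 != 0:
            raise FormatError(f"alignment length {length} not divisible by 3")
        ids = set()
        for rec in self.records:
            if rec.alphabet != "dna":
                raise FormatError(f"record {rec.id!r}: codon alignment must be DNA")
            if len(rec.residues) != length:
                raise FormatError(
                    f"record {rec.id!r}: length {len(rec.residues)} != {length}"
                )
            if rec.id in ids:
                raise FormatError(f"duplicate record id {rec.id!r}")
            ids.add(rec.id)
            for c in range(0, length, 3):
                codon = rec.residues[c : c + 3]
                if GAP in codon and codon != GAP * 3:
                    raise FormatError(
                        f"record {rec.id!r}: partial-codon gap {codon!r} at codon "
                        f"{c // 3 + 1}"
                    )
        if self.tree is not None:
            t = dendropy.Tree.get(data=self.tree, schema="newick")
            leaves = {lf.taxon.label.replace(" ", "_") for lf in t.leaf_node_iter()}
            if leaves != ids:
                raise ConfigurationError(
                    f"tree leaves {sorted(leaves)} do not match record ids {sorted(ids)}"
                )

    @property
    def n_codons(self) -> int:
        return len(self.records[0].residues) // 3

    def codon(self, record_index: int, site: int) -> str:
        """Codon at 1-based site for the given record."""
        s = (site - 1) * 3
        return self.records[record_index].residues[s : s + 3]


def read_codon_alignment(path: str | Path, tree_path: str | Path | None = None) -> CodonAlignmentSet:
    records = read_fasta(path, alphabet="dna")
    tree = None
    if tree_path is not None:
        tree = Path(tree_path).read_text().strip()
    return CodonAlignmentSet(records=records, tree=tree)


# ---------------------------------------------------------------------------
# Span files


def read_spans_tsv(path: str | Path) -> dict[str, list[tuple[int, int, str]]]:
    """Read labelled spans: ``seq_id<TAB>start<TAB>end<TAB>label``, 1-based inclusive."""
    path = Path(path)
    out: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("seq_id"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 'seq_id start end label'")
            seq_id, start, end, label = parts
            start, end = int(start), int(end)
            if not (1 <= start <= end):
                raise FormatError(f"{path}:{lineno}: bad span ({start}, {end})")
            out.setdefault(seq_id, []).append((start, end, label))
    return out


# ---------------------------------------------------------------------------
# Analysis report

REPORT_SCHEMA_VERSION = "1"


@dataclass
class AnalysisReport:
    """Nested, JSON-serialisable record of every stage's outputs and provenance."""

    content: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.content.setdefault("schema_version", REPORT_SCHEMA_VERSION)

    def __getitem__(self, key: str):
        return self.content[key]

    def __contains__(self, key: str) -> bool:
        return key in self.content


def _jsonify(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_report(report: AnalysisReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonify(report.content), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> AnalysisReport:
    with open(path) as fh:
        return AnalysisReport(content=json.load(fh))
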