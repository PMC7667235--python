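"""Readers and writers for the external formats the pipeline touches.

Sequence data lives in :class:`SequenceSet` / :class:`Alignment`, trees are
dendropy objects parsed from newick, and orthogroup membership tables follow
the tab-separated ``Orthogroups.tsv`` dialect produced by standard orthology
tools (first column orthogroup id, one column per species, cells holding
comma-separated sequence identifiers).

Conventions
-----------
* Residues are uppercased on read; ``?`` and ``.`` are normalized to the gap
  character ``-``.
* Internal column indices are 0-based half-open; 1-based inclusive coordinates
  appear only in partition files, converted at the I/O boundary.
* Relaxed PHYLIP is written (long taxon names, single-space separator); the
  strict 10-character dialect is not supported.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"
_NUC_CHARS = set("ACGTUN-")

__all__ = [
    "SequenceSet",
    "Alignment",
    "Partition",
    "PartitionedMatrix",
    "Orthogroup",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "read_newick",
    "write_newick",
    "read_orthogroup_table",
    "write_supermatrix",
    "read_partition_file",
]


def _normalize_residues(seq: str) -> str:
    return seq.upper().replace("?", GAP).replace(".", GAP)


@dataclass
class SequenceSet:
    """An ordered collection of named sequences.

    ``alphabet`` is ``"nucleotide"`` or ``"protein"``; when omitted it is
    inferred from the residue characters (gaps allowed in both).
    """

    ids: list[str]
    seqs: list[str]
    descriptions: list[str] = field(default_factory=list)
    alphabet: str | None = None

    def __post_init__(self) -> None:
        if not self.descriptions:
            self.descriptions = [""] * len(self.ids)
        if len(self.ids) != len(self.seqs) or len(self.ids) != len(self.descriptions):
            raise ValueError("ids, seqs and descriptions must have equal length")
        seen: set[str] = set()
        for sid in self.ids:
            if sid in seen:
                raise ValueError(f"duplicate sequence identifier: {sid!r}")
            seen.add(sid)
        for sid, s in zip(self.ids, self.seqs):
            if not s:
                raise ValueError(f"empty sequence for {sid!r}")
        if self.alphabet is None:
            chars = set("".join(self.seqs))
            self.alphabet = "nucleotide" if chars <= _NUC_CHARS else "protein"
        elif self.alphabet not in ("nucleotide", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.seqs))

    def get(self, seq_id: str) -> str:
        try:
            return self.seqs[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(seq_id) from None

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.ids


@dataclass
class Alignment(SequenceSet):
    """A SequenceSet whose rows all span the same number of columns."""

    def __post_init__(self) -> None:
        super().__post_init__()
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError(f"alignment rows differ in length: {sorted(lengths)}")

    @property
    def column_count(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def column(self, j: int) -> str:
        return "".join(s[j] for s in self.seqs)

    def slice_columns(self, start: int, end: int) -> "Alignment":
        """Rows restricted to columns [start, end) (0-based half-open)."""
        return Alignment(
            ids=list(self.ids),
            seqs=[s[start:end] for s in self.seqs],
            descriptions=list(self.descriptions),
            alphabet=self.alphabet,
        )


@dataclass(frozen=True)
class Partition:
    name: str
    start: int  # 1-based inclusive
    end: int  # inclusive
    datatype: str = "DNA"

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass
class PartitionedMatrix:
    """A concatenated alignment with contiguous named partitions.

    Partitions are 1-based inclusive, must tile columns 1..column_count in
    order without gaps or overlap.
    """

    alignment: Alignment
    partitions: list[Partition]

    def __post_init__(self) -> None:
        expected_start = 1
        for p in self.partitions:
            if p.start != expected_start:
                raise ValueError(
                    f"partition {p.name!r} starts at {p.start}, expected {expected_start}"
                )
            if p.end < p.start:
                raise ValueError(f"partition {p.name!r} has end < start")
            expected_start = p.end + 1
        if self.partitions and expected_start - 1 != self.alignment.column_count:
            raise ValueError(
                f"partitions cover {expected_start - 1} columns, "
                f"alignment has {self.alignment.column_count}"
            )

    def partition_alignment(self, name: str) -> Alignment:
        for p in self.partitions:
            if p.name == name:
                return self.alignment.slice_columns(p.start - 1, p.end)
        raise KeyError(name)


@dataclass
class Orthogroup:
    """Per-species sequence membership for one orthogroup.

    ``members`` maps species name to the (possibly empty) list of sequence
    identifiers that species contributes. A protein alignment may be attached
    later by the supermatrix stage.
    """

    og_id: str
    members: dict[str, list[str]]
    alignment: Alignment | None = None

    @property
    def species_present(self) -> list[str]:
        return [sp for sp, seqs in self.members.items() if seqs]

    @property
    def multicopy_species(self) -> list[str]:
        return [sp for sp, seqs in self.members.items() if len(seqs) > 1]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, alphabet: str | None = None) -> SequenceSet:
    """Read a FASTA file into a SequenceSet.

    Identifiers are the first whitespace token of each header; the rest is
    kept as the description. Residues are uppercased and ``?``/``.`` mapped
    to ``-``. Duplicate identifiers and empty files are errors.
    """
    records = list(SeqIO.parse(os.fspath(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids, seqs, descs = [], [], []
    for rec in records:
        ids.append(rec.id)
        # rec.description includes the id; strip it for the stored description
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        descs.append(desc)
        seqs.append(_normalize_residues(str(rec.seq)))
    return SequenceSet(ids=ids, seqs=seqs, descriptions=descs, alphabet=alphabet)


def write_fasta(seqset: SequenceSet, path, width: int = 60) -> None:
    """Write FASTA with line wrapping normalized to ``width`` columns."""
    with open(path, "w") as fh:
        for sid, seq, desc in zip(seqset.ids, seqset.seqs, seqset.descriptions):
            header = f">{sid} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignment(path, alphabet: str | None = None) -> Alignment:
    ss = read_fasta(path, alphabet=alphabet)
    return Alignment(ids=ss.ids, seqs=ss.seqs, descriptions=ss.descriptions, alphabet=ss.alphabet)


# ---------------------------------------------------------------------------
# Newick


def read_newick(path_or_string) -> dendropy.Tree:
    """Parse a newick tree (from a path or a literal string).

    Rooted and unrooted (basal trifurcation) trees are supported; branch
    lengths are optional. Duplicate leaf labels and malformed newick raise
    ValueError.
    """
    src = os.fspath(path_or_string) if not isinstance(path_or_string, str) else path_or_string
    if isinstance(src, str) and ("(" in src or ";" in src) and not os.path.exists(src):
        data = src
    else:
        with open(src) as fh:
            data = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=data,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"could not parse newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=os.fspath(path), schema="newick", unquoted_underscores=True)


# ---------------------------------------------------------------------------
# Orthogroup tables


def read_orthogroup_table(path) -> list[Orthogroup]:
    """Parse a tab-separated orthogroup membership table.

    First column: orthogroup id; remaining header columns: species names.
    Cells are empty or comma-separated sequence identifiers (whitespace
    around identifiers is stripped). Ragged rows raise with the row number.
    """
    ogs: list[Orthogroup] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"empty orthogroup table: {path}")
        cols = header.split("\t")
        species = cols[1:]
        if not species:
            raise ValueError("orthogroup table has no species columns")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(cols):
                raise ValueError(
                    f"row {lineno}: expected {len(cols)} columns, got {len(cells)}"
                )
            members = {
                sp: [tok.strip() for tok in cell.split(",") if tok.strip()]
                for sp, cell in zip(species, cells[1:])
            }
            ogs.append(Orthogroup(og_id=cells[0], members=members))
    return ogs


def write_orthogroup_table(ogs: list[Orthogroup], path, species: list[str] | None = None) -> None:
    if species is None:
        species = sorted({sp for og in ogs for sp in og.members})
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(species) + "\n")
        for og in ogs:
            cells = [", ".join(og.members.get(sp, [])) for sp in species]
            fh.write(og.og_id + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Supermatrix output


def write_supermatrix(matrix: PartitionedMatrix, basepath) -> dict[str, str]:
    """Emit a partitioned supermatrix as FASTA + relaxed PHYLIP + partitions.

    Writes ``<basepath>.fasta``, ``<basepath>.phy`` (header "ntaxa ncols")
    and ``<basepath>.partitions`` with one ``DATATYPE, name = start-end``
    line per partition. Returns the paths written.
    """
    base = os.fspath(basepath)
    aln = matrix.alignment
    paths = {
        "fasta": base + ".fasta",
        "phylip": base + ".phy",
        "partitions": base + ".partitions",
    }
    write_fasta(aln, paths["fasta"])
    with open(paths["phylip"], "w") as fh:
        fh.write(f"{len(aln)} {aln.column_count}\n")
        for sid, seq in aln:
            fh.write(f"{sid} {seq}\n")
    with open(paths["partitions"], "w") as fh:
        for p in matrix.partitions:
            fh.write(f"{p.datatype}, {p.name} = {p.start}-{p.end}\n")
    return paths


_PARTITION_RE = re.compile(r"^\s*(\S+)\s*,\s*(\S+)\s*=\s*(\d+)\s*-\s*(\d+)\s*$")


def read_partition_file(path) -> list[Partition]:
    parts: list[Partition] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            m = _PARTITION_RE.match(line)
            if not m:
                raise ValueError(f"line {lineno}: cannot parse partition {line!r}")
            datatype, name, start, end = m.groups()
            parts.append(Partition(name=name, start=int(start), end=int(end), datatype=datatype))
    return parts
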