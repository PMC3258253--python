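"""Core containers and readers/writers for the formats the pipeline touches.

Sequence data move through four standard text formats: protein FASTA in,
Newick trees and relaxed-PHYLIP supermatrices (plus RAxML-style partition
tables) out.  Sequence ids follow ``<taxon><delim><gene>`` with ``|`` as
the default delimiter.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import dendropy
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .tree import Node, PhyloTree

logger = logging.getLogger("orthomat")

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
UNKNOWN = "X"
ID_DELIMITER = "|"

_VALID_UNALIGNED = set(AMINO_ACIDS + UNKNOWN)
_VALID_ALIGNED = set(AMINO_ACIDS + UNKNOWN + GAP)


# ---------------------------------------------------------------------- #
# containers
# ---------------------------------------------------------------------- #
@dataclass
class SeqRecord:
    """One protein sequence; ``id`` is ``<taxon>|<gene_id>``."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("empty sequence id")
        if not self.residues:
            raise ValueError(f"empty sequence for id {self.id!r}")

    @property
    def taxon(self) -> str:
        return split_id(self.id)[0]

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Proteome:
    """Ordered protein records for a single taxon."""

    taxon: str
    records: list[SeqRecord] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate id {rec.id!r} in proteome {self.taxon}")
            seen.add(rec.id)
            if rec.taxon != self.taxon:
                raise ValueError(
                    f"record {rec.id!r} does not carry taxon prefix {self.taxon!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, rec_id: str) -> SeqRecord:
        for rec in self.records:
            if rec.id == rec_id:
                return rec
        raise KeyError(rec_id)


class MultipleAlignment:
    """Equal-length gapped protein rows keyed by taxon (or sequence id)."""

    def __init__(self, rows: dict[str, str]):
        if not rows:
            raise ValueError("alignment needs at least one row")
        lengths = {len(s) for s in rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        for name, seq in rows.items():
            bad = set(seq) - _VALID_ALIGNED
            if bad:
                raise ValueError(f"illegal characters {sorted(bad)} in row {name!r}")
        self.rows: dict[str, str] = dict(rows)
        self.length: int = lengths.pop()

    @property
    def names(self) -> list[str]:
        return list(self.rows)

    def column(self, i: int) -> str:
        return "".join(seq[i] for seq in self.rows.values())

    def subset_columns(self, mask: Iterable[int]) -> "MultipleAlignment":
        idx = list(mask)
        return MultipleAlignment(
            {name: "".join(seq[i] for i in idx) for name, seq in self.rows.items()}
        )

    def ungapped(self, name: str) -> str:
        return self.rows[name].replace(GAP, "")

    def __len__(self) -> int:
        return len(self.rows)

    def __repr__(self) -> str:  # pragma: no cover
        return f"MultipleAlignment({len(self.rows)} rows x {self.length} cols)"


@dataclass
class Supermatrix:
    """Concatenated alignment plus a 1-based inclusive partition table."""

    alignment: MultipleAlignment
    partitions: list[tuple[str, int, int]]

    def __post_init__(self):
        expected_start = 1
        for gene, start, end in self.partitions:
            if start != expected_start or end < start:
                raise ValueError(
                    f"partition {gene!r} = {start}-{end} breaks the tiling "
                    f"(expected start {expected_start})"
                )
            expected_start = end + 1
        if self.partitions and expected_start - 1 != self.alignment.length:
            raise ValueError(
                f"partitions cover {expected_start - 1} columns but alignment "
                f"has {self.alignment.length}"
            )

    @property
    def genes(self) -> list[str]:
        return [g for g, _, _ in self.partitions]

    def gene_slice(self, gene: str) -> tuple[int, int]:
        """0-based half-open column range of ``gene``."""
        for name, start, end in self.partitions:
            if name == gene:
                return start - 1, end
        raise KeyError(gene)


# ---------------------------------------------------------------------- #
# id scheme
# ---------------------------------------------------------------------- #
def split_id(seq_id: str, delimiter: str = ID_DELIMITER) -> tuple[str, str]:
    """Split ``<taxon><delim><gene>`` into its parts."""
    taxon, _, gene = seq_id.partition(delimiter)
    if not gene:
        raise ValueError(f"id {seq_id!r} lacks the {delimiter!r} taxon delimiter")
    return taxon, gene


def make_id(taxon: str, gene: str, delimiter: str = ID_DELIMITER) -> str:
    return f"{taxon}{delimiter}{gene}"


# ---------------------------------------------------------------------- #
# FASTA
# ---------------------------------------------------------------------- #
def read_fasta(path: str | Path, taxon: Optional[str] = None) -> Proteome:
    """Read a protein FASTA file into a :class:`Proteome`.

    Residues are uppercased and ``*`` stop symbols stripped.  The taxon is
    taken from the id prefix of the first record unless given explicitly.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            rec_id = header.split()[0]
            description = header[len(rec_id):].strip()
            if rec_id in seen:
                raise ValueError(f"duplicate id {rec_id!r} in {path}")
            seen.add(rec_id)
            residues = seq.upper().replace("*", "").replace(" ", "")
            for pos, ch in enumerate(residues):
                if ch not in _VALID_UNALIGNED:
                    raise ValueError(
                        f"illegal residue {ch!r} at position {pos + 1} of record "
                        f"{rec_id!r} in {path}"
                    )
            records.append(SeqRecord(rec_id, residues, description))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if taxon is None:
        taxon = split_id(records[0].id)[0]
    return Proteome(taxon=taxon, records=records)


def read_alignment_fasta(path: str | Path) -> MultipleAlignment:
    """Read a gapped FASTA alignment; rows keyed by the full header id."""
    rows: dict[str, str] = {}
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            name = header.split()[0]
            if name in rows:
                raise ValueError(f"duplicate row {name!r} in {path}")
            rows[name] = seq.upper().replace(" ", "")
    if not rows:
        raise ValueError(f"no FASTA records in {path}")
    return MultipleAlignment(rows)


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as out:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            out.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                out.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------- #
# Newick
# ---------------------------------------------------------------------- #
def read_newick(text: str) -> PhyloTree:
    """Parse one Newick tree (string or path-free text)."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise ValueError(f"Newick parse error: {exc}") from exc

    def convert(dnode) -> Node:
        name = dnode.taxon.label if dnode.taxon is not None else None
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        support = None
        if dnode.label is not None:
            try:
                support = float(dnode.label)
            except ValueError:
                name = name or dnode.label
        node = Node(name=name, length=length, support=support)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.length = 0.0
    return PhyloTree(root)


def write_newick(tree: PhyloTree, path: Optional[str | Path] = None, precision: int = 6) -> str:
    text = tree.newick(precision=precision)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------- #
# supermatrix serialization (relaxed PHYLIP + RAxML partition table)
# ---------------------------------------------------------------------- #
def write_supermatrix(
    matrix: Supermatrix,
    outdir: str | Path,
    name: str = "supermatrix",
    model: str = "LG",
) -> tuple[Path, Path]:
    """Write ``<name>.phy`` and ``<name>.partitions`` under ``outdir``.

    Partition lines use the RAxML dialect ``<model>, <gene> = <start>-<end>``
    with 1-based inclusive coordinates.
    """
    if matrix.alignment.length == 0 or not matrix.partitions:
        raise ValueError("refusing to serialize an empty supermatrix")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phy = outdir / f"{name}.phy"
    parts = outdir / f"{name}.partitions"
    rows = matrix.alignment.rows
    with open(phy, "w") as out:
        out.write(f" {len(rows)} {matrix.alignment.length}\n")
        for taxon, seq in rows.items():
            out.write(f"{taxon}  {seq}\n")
    with open(parts, "w") as out:
        for gene, start, end in matrix.partitions:
            out.write(f"{model}, {gene} = {start}-{end}\n")
    return phy, parts


_PARTITION_RE = re.compile(r"^\s*\S+\s*,\s*(\S+)\s*=\s*(\d+)\s*-\s*(\d+)\s*$")


def read_supermatrix(phy_path: str | Path, partition_path: str | Path) -> Supermatrix:
    rows: dict[str, str] = {}
    with open(phy_path) as handle:
        header = handle.readline().split()
        n_rows, n_cols = int(header[0]), int(header[1])
        for line in handle:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            rows[name] = seq.replace(" ", "").strip()
    if len(rows) != n_rows or any(len(s) != n_cols for s in rows.values()):
        raise ValueError(f"PHYLIP header disagrees with contents in {phy_path}")
    partitions: list[tuple[str, int, int]] = []
    with open(partition_path) as handle:
        for line in handle:
            if not line.strip():
                continue
            m = _PARTITION_RE.match(line)
            if not m:
                raise ValueError(f"bad partition line: {line.strip()!r}")
            partitions.append((m.group(1), int(m.group(2)), int(m.group(3))))
    return Supermatrix(MultipleAlignment(rows), partitions)


# ---------------------------------------------------------------------- #
# funnel logging
# ---------------------------------------------------------------------- #
def log_stage(stage: str, n_in: int, n_out: int, detail: str = "") -> None:
    """Log an input/output count pair so the selection funnel is auditable."""
    msg = f"[{stage}] {n_in} -> {n_out}"
    if detail:
        msg += f" ({detail})"
    logger.info(msg)
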