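"""Readers and writers for the pipeline's plain-text formats.

Everything flows through ordinary text so any stage can be swapped for an
external producer: FASTA with ``taxon|gene`` headers in, 12-column BLAST
tabular (m8) between search and inference, a relation TSV between inference
and clustering, and OrthoMCL-style group lines out.
"""

from __future__ import annotations

import os
from typing import Iterable, List, TextIO, Union

from Bio import SeqIO

from .clustering import OrthoGroup
from .inference import OrthologyRelation
from .search import HomologyHit, SequenceRecord

__all__ = [
    "read_fasta_taxa",
    "write_fasta",
    "write_m8",
    "read_m8",
    "write_relations",
    "read_relations",
    "read_groups",
]

PathLike = Union[str, os.PathLike]


def read_fasta_taxa(
    path: PathLike, delimiter: str = "|"
) -> List[SequenceRecord]:
    """Read protein FASTA whose headers carry taxon identity.

    The header's first whitespace-delimited token is split at the first
    ``delimiter`` into taxon and gene id.  Duplicate (taxon, gene) pairs,
    missing delimiters and empty sequences are rejected.  Sequences are
    uppercased; a terminal stop ``*`` is stripped.
    """
    records: List[SequenceRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        taxon, sep, gene_id = header.partition(delimiter)
        if not sep or not taxon or not gene_id:
            raise ValueError(
                f"record {header!r}: header must be 'taxon{delimiter}gene_id'"
            )
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise ValueError(f"record {header!r}: empty sequence")
        key = (taxon, gene_id)
        if key in seen:
            raise ValueError(f"duplicate sequence id {header!r}")
        seen.add(key)
        records.append(SequenceRecord(gene_id=gene_id, taxon=taxon, residues=seq))
    return records


def write_fasta(
    records: Iterable[SequenceRecord],
    sink: TextIO,
    delimiter: str = "|",
    width: int = 60,
) -> None:
    for rec in records:
        sink.write(f">{rec.full_id(delimiter)}\n")
        seq = rec.residues
        for i in range(0, len(seq), width):
            sink.write(seq[i : i + width] + "\n")


def write_m8(hits: Iterable[HomologyHit], sink: TextIO) -> None:
    for hit in hits:
        sink.write(hit.to_m8_line() + "\n")


def read_m8(path: PathLike) -> List[HomologyHit]:
    """Parse a 12-column BLAST tabular file."""
    hits: List[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(parts)}"
                )
            try:
                hits.append(
                    HomologyHit(
                        query_id=parts[0],
                        subject_id=parts[1],
                        pct_identity=float(parts[2]),
                        aln_length=int(parts[3]),
                        mismatches=int(parts[4]),
                        gap_opens=int(parts[5]),
                        q_start=int(parts[6]),
                        q_end=int(parts[7]),
                        s_start=int(parts[8]),
                        s_end=int(parts[9]),
                        evalue=float(parts[10]),
                        bit_score=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def write_relations(
    relations: Iterable[OrthologyRelation], sink: TextIO
) -> None:
    for rel in relations:
        sink.write(rel.to_tsv_line() + "\n")


def read_relations(path: PathLike) -> List[OrthologyRelation]:
    out: List[OrthologyRelation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ValueError(
                    f"{path}: line {lineno}: expected 5 columns, got {len(parts)}"
                )
            out.append(
                OrthologyRelation(
                    gene_a=parts[0],
                    gene_b=parts[1],
                    rel_type=parts[2],
                    bit_score=float(parts[3]),
                    weight=float(parts[4]),
                )
            )
    return out


def read_edge_list(path: PathLike) -> List[tuple]:
    """Generic ``a b w`` (ABC) edge list; also accepts the relation TSV."""
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) == 5 and parts[2] in (
                "ortholog", "co-ortholog", "in-paralog"
            ):
                edges.append((parts[0], parts[1], float(parts[4])))
            elif len(parts) >= 3:
                edges.append((parts[0], parts[1], float(parts[2])))
            else:
                raise ValueError(
                    f"{path}: line {lineno}: need 'a b weight' columns"
                )
    return edges


def read_groups(path: PathLike) -> List[OrthoGroup]:
    """Read OrthoMCL-style group lines ``<id>: member1 member2 ...``."""
    groups: List[OrthoGroup] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            head, sep, tail = line.partition(":")
            if not sep:
                raise ValueError(f"{path}: line {lineno}: missing ':' separator")
            members = frozenset(tail.split())
            if not members:
                raise ValueError(f"{path}: line {lineno}: empty group")
            groups.append(OrthoGroup(group_id=head.strip(), members=members))
    return groups
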