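"""Mapping-reference catalogs: pathway genes and the rplB housekeeping gene.

Nucleotide sequences of pathway genes from pathway-positive genomes are
compiled into a nonredundant catalog (exact sequence-identity
deduplication, byte-identical sequences merged with the union of their
source genomes). rplB — the near-universal single-copy 50S ribosomal
protein L2 gene used as the community depth proxy — gets its own catalog,
admitting only candidates with homology scores ≥400.

Catalog ids are deterministic (gene symbol + content hash) so repeated
builds over the same sequences produce identical references.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import GenomePathwayProfile
from .schema import PathwayRegistry

__all__ = [
    "CatalogEntry",
    "HousekeepingEntry",
    "build_catalog",
    "build_rplb_catalog",
    "catalog_to_frame",
    "rplb_to_frame",
    "write_catalog",
    "write_rplb_catalog",
    "read_catalog_tsv",
    "read_rplb_tsv",
]

RPLB_MIN_SCORE = 400.0


@dataclass(frozen=True)
class CatalogEntry:
    entry_id: str
    gene: str
    pathways: tuple[str, ...]
    length: int
    sequence: str
    sources: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.length != len(self.sequence):
            raise ValueError(f"{self.entry_id}: length field != sequence length")
        if not self.pathways:
            raise ValueError(f"{self.entry_id}: entry belongs to no pathway")


@dataclass(frozen=True)
class HousekeepingEntry:
    entry_id: str
    length: int
    sequence: str
    sources: tuple[str, ...]
    score: float

    def __post_init__(self) -> None:
        if self.score < RPLB_MIN_SCORE:
            raise ValueError(
                f"{self.entry_id}: qualifying score {self.score} < {RPLB_MIN_SCORE}"
            )


def _content_id(prefix: str, sequence: str) -> str:
    return f"{prefix}_{hashlib.sha1(sequence.encode()).hexdigest()[:10]}"


def build_catalog(
    sequences: Iterable[tuple[str, str, str]],
    registry: PathwayRegistry,
    profiles: Sequence[GenomePathwayProfile] | None = None,
) -> list[CatalogEntry]:
    """Compile ``(genome_id, gene, nucleotide sequence)`` records into a
    nonredundant catalog.

    When ``profiles`` are given, only genomes with at least one assigned
    pathway contribute, and each genome contributes only genes belonging to
    its assigned pathways. Pathway membership of an entry is the full set of
    registry pathways containing the gene — shared genes stay shared so
    that read counts can be apportioned downstream.
    """
    allowed: dict[str, frozenset[str]] | None = None
    if profiles is not None:
        allowed = {}
        for p in profiles:
            genes = frozenset(
                g for pid in p.assigned_pathways for g in registry[pid].required_genes
            )
            if genes:
                allowed[p.genome_id] = genes

    merged: dict[str, dict] = {}
    order: list[str] = []
    for genome_id, gene, seq in sequences:
        if allowed is not None:
            genes = allowed.get(genome_id)
            if genes is None or gene not in genes:
                continue
        pathways = registry.pathways_for_gene(gene)
        if not pathways:
            raise ValueError(f"gene {gene!r} is not in any registry pathway")
        seq = seq.upper()
        key = f"{gene}\x00{seq}"
        if key not in merged:
            merged[key] = {"gene": gene, "seq": seq, "sources": set(), "pathways": pathways}
            order.append(key)
        merged[key]["sources"].add(genome_id)

    entries = [
        CatalogEntry(
            entry_id=_content_id(rec["gene"], rec["seq"]),
            gene=rec["gene"],
            pathways=tuple(
                sorted(rec["pathways"], key=registry.pathway_ids.index)
            ),
            length=len(rec["seq"]),
            sequence=rec["seq"],
            sources=tuple(sorted(rec["sources"])),
        )
        for rec in (merged[k] for k in sorted(order))
    ]
    entries.sort(key=lambda e: (e.gene, e.entry_id))
    if not entries:
        warnings.warn("catalog is empty: no pathway-positive sequences supplied")
    return entries


def build_rplb_catalog(
    candidates: Iterable[tuple[str, str, float]],
    min_score: float = RPLB_MIN_SCORE,
) -> list[HousekeepingEntry]:
    """Compile ``(genome_id, sequence, score)`` rplB candidates, retaining
    scores ≥ ``min_score`` and deduplicating exactly like :func:`build_catalog`.
    The qualifying score of a merged entry is the best among its sources."""
    merged: dict[str, dict] = {}
    for genome_id, seq, score in candidates:
        if score < min_score:
            continue
        seq = seq.upper()
        if seq not in merged:
            merged[seq] = {"sources": set(), "score": float(score)}
        merged[seq]["sources"].add(genome_id)
        merged[seq]["score"] = max(merged[seq]["score"], float(score))
    entries = [
        HousekeepingEntry(
            entry_id=_content_id("rplB", seq),
            length=len(seq),
            sequence=seq,
            sources=tuple(sorted(rec["sources"])),
            score=rec["score"],
        )
        for seq, rec in merged.items()
    ]
    entries.sort(key=lambda e: e.entry_id)
    return entries


# ---------------------------------------------------------------------------
# i/o

def catalog_to_frame(entries: Iterable[CatalogEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "entry": e.entry_id,
                "gene": e.gene,
                "pathways": ";".join(e.pathways),
                "length": e.length,
                "sources": ";".join(e.sources),
            }
            for e in entries
        ],
        columns=["entry", "gene", "pathways", "length", "sources"],
    )


def rplb_to_frame(entries: Iterable[HousekeepingEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "entry": e.entry_id,
                "length": e.length,
                "score": e.score,
                "sources": ";".join(e.sources),
            }
            for e in entries
        ],
        columns=["entry", "length", "score", "sources"],
    )


def _write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=entry_id, description="") for entry_id, seq in records),
        str(path),
        "fasta",
    )


def write_catalog(
    entries: Sequence[CatalogEntry], fasta_path: str | Path, tsv_path: str | Path
) -> None:
    """Write the catalog as FASTA plus a sidecar TSV
    (entry, gene, pathways, length, sources)."""
    _write_fasta(((e.entry_id, e.sequence) for e in entries), fasta_path)
    catalog_to_frame(entries).to_csv(tsv_path, sep="\t", index=False)


def write_rplb_catalog(
    entries: Sequence[HousekeepingEntry], fasta_path: str | Path, tsv_path: str | Path
) -> None:
    _write_fasta(((e.entry_id, e.sequence) for e in entries), fasta_path)
    rplb_to_frame(entries).to_csv(tsv_path, sep="\t", index=False)


def read_catalog_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"entry": str, "gene": str, "pathways": str})
    required = {"entry", "gene", "pathways", "length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: catalog TSV missing column(s) {sorted(missing)}")
    return df


def read_rplb_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"entry": str})
    missing = {"entry", "length"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: rplB TSV missing column(s) {sorted(missing)}")
    return df
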