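"""File-backed reference stores: sequences, transcripts, gene normalization.

The production mapping service relies on network-bound infrastructure (a
sequence repository, a transcript archive, a gene normalizer).  This module
defines three narrow contracts and plain-file implementations (FASTA + TSV)
so the whole pipeline runs offline and deterministically.  Production
adapters wrapping the live services can implement the same contracts.

Coordinates are interbase (0-based, half-open) everywhere in this module.
"""

from __future__ import annotations

import hashlib
import base64
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .errors import NoLinkageError, NotFoundError, RangeError


def sha512t24u(data: bytes) -> str:
    """GA4GH truncated digest: SHA-512, first 24 bytes, base64url, no padding."""
    return base64.urlsafe_b64encode(hashlib.sha512(data).digest()[:24]).decode("ascii")


def sequence_digest_id(seq: str) -> str:
    """``ga4gh:SQ.``-prefixed digest identifier for an uppercased sequence."""
    return "ga4gh:SQ." + sha512t24u(seq.upper().encode("ascii"))


@dataclass(frozen=True)
class GeneContext:
    """Normalized gene: consensus symbol plus genomic span."""

    symbol: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene span start {self.start} >= end {self.end}")


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript row from the transcript table.

    ``pub_order`` is an ordinal standing in for first-publication date, used
    only to break length ties during transcript selection.  ``exons`` are
    genomic interbase spans in genomic order.
    """

    tx_accession: str
    protein_accession: str | None
    is_coding: bool
    mane_status: str            # "MANE Select" | "MANE Plus Clinical" | "none"
    length: int
    pub_order: int
    chromosome: str
    gene: str
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.is_coding and not self.protein_accession:
            raise ValueError(f"coding transcript {self.tx_accession} lacks a protein accession")

    @property
    def span(self) -> tuple[int, int]:
        if not self.exons:
            return (0, 0)
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))


# GRC chromosome label -> GRCh38 RefSeq accession (NCBI assembly report).
GRCH38_REFSEQ = {
    **{f"chr{i}": f"NC_0000{i:02d}.{v}" for i, v in zip(
        range(1, 23),
        [11, 12, 12, 12, 10, 12, 14, 11, 12, 11, 10, 12, 11, 9, 10, 10, 11, 10, 10, 11, 9, 11],
    )},
    "chrX": "NC_000023.11",
    "chrY": "NC_000024.10",
    "chrM": "NC_012920.1",
}


class SequenceStore:
    """In-memory sequence store addressable by accession or digest identifier.

    Loads FASTA files; every sequence is uppercased and also registered under
    its ``ga4gh:SQ.`` digest so digest-identified locations resolve without a
    second lookup table.
    """

    def __init__(self) -> None:
        self._seqs: dict[str, str] = {}

    @classmethod
    def from_fasta(cls, *paths: str | Path) -> "SequenceStore":
        store = cls()
        for path in paths:
            for rec in SeqIO.parse(str(path), "fasta"):
                store.add(rec.id, str(rec.seq))
        return store

    def add(self, accession: str, seq: str) -> str:
        seq = seq.upper()
        self._seqs[accession] = seq
        digest = sequence_digest_id(seq)
        self._seqs[digest] = seq
        return digest

    def __contains__(self, accession: str) -> bool:
        return accession in self._seqs

    def length(self, accession: str) -> int:
        return len(self._full(accession))

    def _full(self, accession: str) -> str:
        try:
            return self._seqs[accession]
        except KeyError:
            raise NotFoundError(f"unknown sequence accession {accession!r}") from None

    def get_sequence(
        self, accession: str, start: int | None = None, end: int | None = None
    ) -> str:
        """Uppercase interbase slice ``[start, end)``; omitted bounds = whole sequence."""
        seq = self._full(accession)
        if start is None and end is None:
            return seq
        start = 0 if start is None else start
        end = len(seq) if end is None else end
        if not (0 <= start <= end <= len(seq)):
            raise RangeError(
                f"slice [{start}, {end}) outside {accession!r} (length {len(seq)})"
            )
        return seq[start:end]


class GeneStore:
    """Gene-normalization contract backed by a TSV table.

    Table columns: ``symbol  uniprot  chromosome  start  end``.  A row whose
    chromosome field is empty models a UniProt accession with no usable gene
    linkage (a whole-score-set failure mode).
    """

    def __init__(self, rows: list[dict[str, str]]) -> None:
        self._by_symbol: dict[str, dict[str, str]] = {}
        self._by_uniprot: dict[str, dict[str, str]] = {}
        for row in rows:
            self._by_symbol[row["symbol"]] = row
            if row.get("uniprot"):
                self._by_uniprot[row["uniprot"]] = row

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneStore":
        return cls(_read_tsv(path))

    def normalize_gene(self, query: str) -> GeneContext:
        """Resolve a ``uniprot:``-CURIE or bare symbol to a :class:`GeneContext`."""
        if query.startswith("uniprot:"):
            row = self._by_uniprot.get(query.split(":", 1)[1])
            if row is None:
                raise NotFoundError(f"unknown UniProt accession {query!r}")
        else:
            row = self._by_symbol.get(query)
            if row is None:
                raise NotFoundError(f"unknown gene symbol {query!r}")
        if not row.get("chromosome"):
            raise NoLinkageError(f"{query!r} has no linked gene/protein record")
        return GeneContext(
            symbol=row["symbol"],
            chromosome=row["chromosome"],
            start=int(row["start"]),
            end=int(row["end"]),
        )


class IdentifierStore:
    """Chromosome-label -> versioned RefSeq accession translation.

    Ships the standard GRCh38 table; fixture namespaces extend it via TSV
    rows ``label  assembly  accession``.
    """

    def __init__(self, extra_rows: list[dict[str, str]] | None = None) -> None:
        self._table: dict[tuple[str, str], str] = {
            (label, "GRCh38"): acc for label, acc in GRCH38_REFSEQ.items()
        }
        for row in extra_rows or []:
            self._table[(row["label"], row["assembly"])] = row["accession"]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IdentifierStore":
        return cls(_read_tsv(path))

    def translate_identifier(self, label: str, assembly: str = "GRCh38") -> str:
        try:
            return self._table[(label, assembly)]
        except KeyError:
            raise NotFoundError(
                f"no accession for chromosome {label!r} on assembly {assembly!r}"
            ) from None


class TranscriptStore:
    """Transcript-archive contract backed by a TSV table.

    Table columns: ``tx_accession  protein_accession  is_coding  mane_status
    length  pub_order  chromosome  gene  strand  exons`` with exons encoded
    ``start-end;start-end;...`` in genomic interbase coordinates.
    """

    def __init__(self, records: list[TranscriptRecord]) -> None:
        self._records = list(records)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TranscriptStore":
        records = []
        for row in _read_tsv(path):
            exons = tuple(
                tuple(int(x) for x in part.split("-"))
                for part in row["exons"].split(";")
                if part
            )
            records.append(
                TranscriptRecord(
                    tx_accession=row["tx_accession"],
                    protein_accession=row["protein_accession"] or None,
                    is_coding=row["is_coding"].lower() in ("1", "true", "yes"),
                    mane_status=row["mane_status"] or "none",
                    length=int(row["length"]),
                    pub_order=int(row["pub_order"]),
                    chromosome=row["chromosome"],
                    gene=row["gene"],
                    strand=row.get("strand", "+"),
                    exons=exons,  # type: ignore[arg-type]
                )
            )
        return cls(records)

    @property
    def records(self) -> list[TranscriptRecord]:
        return list(self._records)

    def transcripts_in_region(
        self, chromosome: str, start: int, end: int, gene: str | None = None
    ) -> list[TranscriptRecord]:
        """Every transcript of ``gene`` overlapping ``[start, end)`` on ``chromosome``.

        ``chromosome`` may be a label (``chrT``) or its RefSeq accession as
        recorded in the table.  Empty result lists are permitted.
        """
        out = []
        for rec in self._records:
            if rec.chromosome != chromosome:
                continue
            if gene is not None and rec.gene != gene:
                continue
            s, e = rec.span
            if s < end and start < e:
                out.append(rec)
        return out


@dataclass
class ReferenceStores:
    """Bundle of the four store contracts loaded from one directory.

    Layout: ``genome.fa``, ``proteins.fa`` (may include ``uniprot:``-namespaced
    canonical sequences), ``transcripts.tsv``, ``genes.tsv``, and optional
    ``identifiers.tsv`` extending the built-in GRCh38 table.
    """

    sequences: SequenceStore = field(default_factory=SequenceStore)
    genes: GeneStore = field(default_factory=lambda: GeneStore([]))
    transcripts: TranscriptStore = field(default_factory=lambda: TranscriptStore([]))
    identifiers: IdentifierStore = field(default_factory=IdentifierStore)

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceStores":
        d = Path(directory)
        fastas = [p for p in (d / "genome.fa", d / "proteins.fa") if p.exists()]
        ident_path = d / "identifiers.tsv"
        return cls(
            sequences=SequenceStore.from_fasta(*fastas),
            genes=GeneStore.from_tsv(d / "genes.tsv"),
            transcripts=TranscriptStore.from_tsv(d / "transcripts.tsv"),
            identifiers=(
                IdentifierStore.from_tsv(ident_path) if ident_path.exists() else IdentifierStore()
            ),
        )


def _read_tsv(path: str | Path) -> list[dict[str, str]]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        return []
    header = lines[0].rstrip("\n").split("\t")
    rows = []
    for line in lines[1:]:
        if not line.strip():
            continue
        values = line.split("\t")
        rows.append(dict(zip(header, values)))
    return rows
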