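"""Typed RNase P RNA reference database: parsing, validation, k-mer indexing.

The scanner is driven by a curated set of RNase P RNA (rnpB) sequences, each
labelled with one of the five recognised secondary-structure classes
(A, B, C, M, T) and a taxonomic domain (bacteria or archaea).  The database
is plain FASTA whose headers carry whitespace-separated ``key=value`` tags::

    >my_record type=A domain=bacteria source=curated_2020
    ACGT...

Sequences are stored DNA-side (uppercase, U mapped to T); IUPAC ambiguity
codes are retained in the records but never indexed as alignment seeds.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from Bio import SeqIO

STRUCTURAL_TYPES = frozenset({"A", "B", "C", "M", "T"})
DOMAINS = frozenset({"bacteria", "archaea"})

#: IUPAC nucleotide one-letter codes accepted after U->T normalisation.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

# Default length bounds: the typical gene is 250-550 nt, but the minimal
# T-class runs shorter (~200 nt), so the accepted window brackets both.
MIN_REF_LENGTH = 150
MAX_REF_LENGTH = 700

DEFAULT_K = 12


class ReferenceDBError(ValueError):
    """Raised when a reference database fails validation."""


def normalize_sequence(raw: str) -> str:
    """Normalise a nucleotide string to uppercase DNA.

    U is mapped to T (references are RNA genes, targets are genomic DNA);
    IUPAC ambiguity codes are kept as-is.

    Raises
    ------
    ReferenceDBError
        If the input is empty or contains a non-IUPAC character; the error
        message names the 1-based position and the offending character.
    """
    if not raw:
        raise ReferenceDBError("empty sequence")
    seq = raw.upper().replace("U", "T")
    for pos, ch in enumerate(seq, start=1):
        if ch not in IUPAC_DNA:
            raise ReferenceDBError(
                f"illegal character {ch!r} at position {pos}"
            )
    return seq


@dataclass(frozen=True)
class ReferenceRecord:
    """One curated RNase P RNA sequence with its class and domain labels."""

    id: str
    sequence: str
    structural_type: str
    domain: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.structural_type not in STRUCTURAL_TYPES:
            raise ReferenceDBError(
                f"record {self.id!r}: unknown structural type "
                f"{self.structural_type!r}; allowed: "
                f"{sorted(STRUCTURAL_TYPES)}"
            )
        if self.domain not in DOMAINS:
            raise ReferenceDBError(
                f"record {self.id!r}: unknown domain {self.domain!r}; "
                f"allowed: {sorted(DOMAINS)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def build_kmer_index(
    records: Iterable[ReferenceRecord], k: int
) -> dict[str, list[tuple[int, int]]]:
    """Map every unambiguous k-mer of every record to (record index, offset).

    k-mers containing IUPAC ambiguity codes are skipped: an ambiguous word
    cannot act as an exact seed against an unambiguous genome.
    """
    if not 8 <= k <= 16:
        raise ReferenceDBError(f"k must be in [8, 16], got {k}")
    index: dict[str, list[tuple[int, int]]] = {}
    acgt = frozenset("ACGT")
    for ri, rec in enumerate(records):
        seq = rec.sequence
        for off in range(len(seq) - k + 1):
            kmer = seq[off : off + k]
            if not acgt.issuperset(kmer):
                continue
            index.setdefault(kmer, []).append((ri, off))
    return index


class ReferenceDB:
    """Validated, k-mer-indexed collection of reference records.

    ``total_length`` (the summed reference length) is the search-space size
    *n* used by the E-value statistics downstream.
    """

    def __init__(
        self,
        records: list[ReferenceRecord],
        k: int = DEFAULT_K,
        min_length: int = MIN_REF_LENGTH,
        max_length: int = MAX_REF_LENGTH,
        validate_lengths: bool = True,
    ) -> None:
        if not records:
            raise ReferenceDBError("no reference records")
        seen: set[str] = set()
        for rec in records:
            if rec.id in seen:
                raise ReferenceDBError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            if validate_lengths and not min_length <= len(rec) <= max_length:
                raise ReferenceDBError(
                    f"record {rec.id!r}: length {len(rec)} outside "
                    f"[{min_length}, {max_length}]"
                )
        self.records: list[ReferenceRecord] = list(records)
        self.by_id: dict[str, ReferenceRecord] = {r.id: r for r in records}
        self.k = k
        self.kmer_index = build_kmer_index(self.records, k)
        self.total_length = sum(len(r) for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _open_text(path) -> io.TextIOBase:
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def _parse_header_tags(description: str) -> tuple[str, dict[str, str]]:
    """Split a FASTA description into the record id and key=value tags.

    Keys are case-insensitive.  A ``source=`` tag, if present, captures the
    remainder of the line so provenance text may contain spaces.
    """
    parts = description.split(None, 1)
    rec_id = parts[0]
    tags: dict[str, str] = {}
    rest = parts[1] if len(parts) > 1 else ""
    tokens = rest.split()
    for tok in tokens:
        if "=" not in tok:
            continue
        key, val = tok.split("=", 1)
        key = key.lower()
        if key == "source":
            # source swallows the rest of the line
            idx = rest.lower().find("source=")
            tags["source"] = rest[idx + len("source=") :].strip()
            break
        tags[key] = val
    return rec_id, tags


def parse_reference_fasta(
    path,
    k: int = DEFAULT_K,
    min_length: int = MIN_REF_LENGTH,
    max_length: int = MAX_REF_LENGTH,
    permissive: bool = False,
) -> ReferenceDB:
    """Load a tagged reference FASTA into a validated :class:`ReferenceDB`.

    Every header must carry ``type=`` (one of A/B/C/M/T) and ``domain=``
    (bacteria or archaea) tags.  With ``permissive=True`` invalid records are
    skipped instead of aborting the load (the database must still end up
    non-empty).
    """
    records: list[ReferenceRecord] = []
    with _open_text(path) as fh:
        for sr in SeqIO.parse(fh, "fasta"):
            try:
                rec_id, tags = _parse_header_tags(sr.description)
                if "type" not in tags:
                    raise ReferenceDBError(
                        f"record {rec_id!r}: missing type tag; allowed: "
                        f"{sorted(STRUCTURAL_TYPES)}"
                    )
                if "domain" not in tags:
                    raise ReferenceDBError(
                        f"record {rec_id!r}: missing domain tag; allowed: "
                        f"{sorted(DOMAINS)}"
                    )
                seq = normalize_sequence(str(sr.seq))
                if not min_length <= len(seq) <= max_length:
                    raise ReferenceDBError(
                        f"record {rec_id!r}: length {len(seq)} outside "
                        f"[{min_length}, {max_length}]"
                    )
                records.append(
                    ReferenceRecord(
                        id=rec_id,
                        sequence=seq,
                        structural_type=tags["type"].upper(),
                        domain=tags["domain"].lower(),
                        source=tags.get("source", ""),
                    )
                )
            except ReferenceDBError:
                if not permissive:
                    raise
    if not records:
        raise ReferenceDBError("no reference records")
    return ReferenceDB(
        records, k=k, min_length=min_length, max_length=max_length
    )


def write_reference_fasta(db_or_records, path, width: int = 70) -> None:
    """Write records back to the tagged-header FASTA dialect (round-trips)."""
    records = list(db_or_records)
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} type={rec.structural_type} domain={rec.domain}"
            if rec.source:
                header += f" source={rec.source}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def db_length_stats(db: ReferenceDB) -> pd.DataFrame:
    """Per-structural-type length summary (count, mean, min, max).

    One row per type present in the database, ordered A, B, C, M, T.
    """
    rows = []
    for t in sorted(STRUCTURAL_TYPES):
        lengths = [len(r) for r in db.records if r.structural_type == t]
        if not lengths:
            continue
        rows.append(
            {
                "type": t,
                "count": len(lengths),
                "mean_len": sum(lengths) / len(lengths),
                "min_len": min(lengths),
                "max_len": max(lengths),
            }
        )
    return pd.DataFrame(rows, columns=["type", "count", "mean_len", "min_len", "max_len"])
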