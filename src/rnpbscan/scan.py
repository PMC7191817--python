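"""Whole-sequence rnpB annotation: both-strand scanning and locus calling.

Every target record is scanned forward and as its reverse complement;
surviving alignments (E-value and length thresholds) become locus calls with
1-based inclusive forward-strand coordinates — start <= end on both strands,
with the strand field carrying the orientation.  Overlapping candidates are
resolved greedily by bitscore, and each accepted locus inherits the
structural type and taxonomic domain of its best-scoring reference.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from Bio import SeqIO

from .align import (
    AlignmentResult,
    ScoringScheme,
    bit_score,
    e_value,
    reverse_complement,
    seed_and_extend,
)
from .refdb import ReferenceDB, _open_text, normalize_sequence

#: Output columns accepted by the TSV writer; "type" is the structural class.
TSV_COLUMNS = (
    "target_id",
    "type",
    "domain",
    "bitscore",
    "evalue",
    "percent_id",
    "start",
    "end",
    "strand",
    "sequence",
    "ref_id",
)

DEFAULT_TSV_COLUMNS = (
    "target_id",
    "type",
    "domain",
    "bitscore",
    "evalue",
    "percent_id",
    "start",
    "end",
    "strand",
    "sequence",
)


@dataclass
class ScanParams:
    """Tunable scan thresholds; defaults are flags on the CLI.

    evalue_max:    maximum E-value for a reported hit.
    min_aln_len:   minimum alignment length in columns (rnpB genes are
                   >~190 nt, so short spurious matches are discarded).
    band:          diagonal half-width for seed clustering and extension.
    min_raw:       minimum raw score for a seeded extension to survive.
    max_overlap_frac: fraction of the shorter interval above which two
                   candidates are considered the same locus.
    ambiguity_margin: bitscore margin within which a different-type
                   runner-up triggers a classification warning.
    """

    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    evalue_max: float = 1e-5
    min_aln_len: int = 120
    band: int = 32
    min_raw: int = 20
    max_overlap_frac: float = 0.5
    ambiguity_margin: float = 5.0

    def as_dict(self) -> dict:
        return {
            "match": self.scheme.match,
            "mismatch": self.scheme.mismatch,
            "gap_open": self.scheme.gap_open,
            "gap_extend": self.scheme.gap_extend,
            "K": self.scheme.K,
            "lambda": round(self.scheme.lam, 6),
            "evalue_max": self.evalue_max,
            "min_aln_len": self.min_aln_len,
            "band": self.band,
            "min_raw": self.min_raw,
            "max_overlap_frac": self.max_overlap_frac,
            "ambiguity_margin": self.ambiguity_margin,
        }


@dataclass
class LocusCall:
    """One annotated rnpB locus on a target sequence."""

    target_id: str
    start: int            # 1-based inclusive, forward strand
    end: int              # 1-based inclusive, forward strand
    strand: str           # "plus" | "minus"
    structural_type: str
    domain: str
    best_ref: str
    raw_score: int
    bitscore: float
    evalue: float
    percent_id: float
    sequence: str         # forward-strand slice of the target
    aln_len: int
    warnings: list[str] = field(default_factory=list)


@dataclass
class ScanReport:
    """All calls plus the target ids in which nothing was found."""

    calls: list[LocusCall]
    negatives: list[str]
    params: dict


def map_minus_coordinates(
    aln: AlignmentResult, target_length: int
) -> tuple[int, int]:
    """Map an alignment on the reverse complement to forward coordinates.

    ``start = L - end_rc + 1`` and ``end = L - start_rc + 1`` so that
    start <= end holds on both strands.
    """
    if not 1 <= aln.target_start <= aln.target_end <= target_length:
        raise ValueError(
            f"alignment span ({aln.target_start}, {aln.target_end}) outside "
            f"target of length {target_length}"
        )
    return (
        target_length - aln.target_end + 1,
        target_length - aln.target_start + 1,
    )


def _call_from_alignment(
    aln: AlignmentResult,
    target_id: str,
    target_seq: str,
    strand: str,
    db: ReferenceDB,
    params: ScanParams,
) -> LocusCall:
    L = len(target_seq)
    if strand == "plus":
        start, end = aln.target_start, aln.target_end
    else:
        start, end = map_minus_coordinates(aln, L)
    ref = db.by_id[aln.ref_id]
    return LocusCall(
        target_id=target_id,
        start=start,
        end=end,
        strand=strand,
        structural_type=ref.structural_type,
        domain=ref.domain,
        best_ref=ref.id,
        raw_score=aln.raw_score,
        bitscore=aln.bitscore,
        evalue=aln.evalue,
        percent_id=aln.percent_id,
        sequence=target_seq[start - 1 : end],
        aln_len=aln.n_columns,
    )


def _overlap(a: LocusCall, b: LocusCall) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def _same_locus(a: LocusCall, b: LocusCall, max_overlap_frac: float) -> bool:
    shorter = min(a.end - a.start + 1, b.end - b.start + 1)
    return _overlap(a, b) > max_overlap_frac * shorter


def resolve_overlaps(
    candidates: list[LocusCall], max_overlap_frac: float = 0.5,
    ambiguity_margin: float = 5.0,
) -> list[LocusCall]:
    """Greedy best-hit selection among overlapping candidate calls.

    Candidates are taken in order of descending bitscore (ties: lower
    E-value, then smaller start, then lexicographic reference id); a
    candidate overlapping an already accepted call by more than
    ``max_overlap_frac`` of the shorter interval is discarded.  When a
    discarded candidate of a *different* structural type scores within
    ``ambiguity_margin`` bits of the winner, the winner gets an ambiguity
    warning (classification still follows the best hit).
    """
    ordered = sorted(
        candidates,
        key=lambda c: (-c.bitscore, c.evalue, c.start, c.best_ref),
    )
    accepted: list[LocusCall] = []
    for cand in ordered:
        winner = None
        for acc in accepted:
            if _same_locus(cand, acc, max_overlap_frac):
                winner = acc
                break
        if winner is None:
            accepted.append(cand)
        elif (
            cand.structural_type != winner.structural_type
            and cand.bitscore >= winner.bitscore - ambiguity_margin
        ):
            winner.warnings.append(
                f"ambiguous type: runner-up {cand.best_ref} "
                f"(type {cand.structural_type}, {cand.bitscore:.1f} bits) "
                f"within {ambiguity_margin} bits of best hit"
            )
    return sorted(accepted, key=lambda c: (c.start, c.end))


def scan_sequence(
    target_id: str,
    target_seq: str,
    db: ReferenceDB,
    params: ScanParams | None = None,
) -> list[LocusCall]:
    """Scan one target sequence on both strands and return resolved calls.

    The reverse complement of the target is scanned with the same seeded
    search; minus-strand alignments are mapped back to forward coordinates.
    Alignments survive when E <= ``evalue_max`` and the alignment has at
    least ``min_aln_len`` columns.  Calls are sorted by (start, end).
    """
    params = params or ScanParams()
    m = len(target_seq)
    n = db.total_length
    scheme = params.scheme
    candidates: list[LocusCall] = []
    for strand, seq in (
        ("plus", target_seq),
        ("minus", reverse_complement(target_seq)),
    ):
        for aln in seed_and_extend(
            seq, db, scheme, band=params.band, min_raw=params.min_raw
        ):
            aln.bitscore = bit_score(aln.raw_score, scheme.lam, scheme.K)
            aln.evalue = e_value(aln.bitscore, m, n)
            if aln.evalue > params.evalue_max:
                continue
            if aln.n_columns < params.min_aln_len:
                continue
            aln.strand = strand
            candidates.append(
                _call_from_alignment(aln, target_id, target_seq, strand, db, params)
            )
    return resolve_overlaps(
        candidates, params.max_overlap_frac, params.ambiguity_margin
    )


def annotate(
    targets,
    db: ReferenceDB,
    params: ScanParams | None = None,
    threads: int = 1,
) -> ScanReport:
    """Annotate every record of a multi-FASTA (path or iterable of
    (id, sequence) pairs).

    The result is independent of worker count and of input record order:
    calls are canonically sorted by (target_id, start, end) and negatives
    listed sorted.  Raises on an empty input.
    """
    params = params or ScanParams()
    if isinstance(targets, (str, bytes)) or hasattr(targets, "__fspath__"):
        records = _read_targets(targets)
    else:
        records = [(rid, normalize_sequence(seq)) for rid, seq in targets]
    if not records:
        raise ValueError("no target sequences")

    def work(item):
        rid, seq = item
        return rid, scan_sequence(rid, seq, db, params)

    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            per_record = list(pool.map(work, records))
    else:
        per_record = [work(item) for item in records]

    calls: list[LocusCall] = []
    negatives: list[str] = []
    for rid, rcalls in per_record:
        if rcalls:
            calls.extend(rcalls)
        else:
            negatives.append(rid)
    calls.sort(key=lambda c: (c.target_id, c.start, c.end))
    negatives.sort()
    return ScanReport(calls=calls, negatives=negatives, params=params.as_dict())


def _read_targets(path) -> list[tuple[str, str]]:
    records = []
    try:
        with _open_text(path) as fh:
            for i, sr in enumerate(SeqIO.parse(fh, "fasta")):
                records.append((sr.id, normalize_sequence(str(sr.seq))))
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed FASTA
        raise ValueError(f"unreadable FASTA {path}: {exc}") from exc
    return records


def _format_field(call: LocusCall, col: str) -> str:
    if col == "target_id":
        return call.target_id
    if col == "type":
        return call.structural_type
    if col == "domain":
        return call.domain
    if col == "bitscore":
        return f"{call.bitscore:.2f}"
    if col == "evalue":
        return f"{call.evalue:.3g}"
    if col == "percent_id":
        return f"{call.percent_id:.2f}"
    if col == "start":
        return str(call.start)
    if col == "end":
        return str(call.end)
    if col == "strand":
        return call.strand
    if col == "sequence":
        return call.sequence
    if col == "ref_id":
        return call.best_ref
    raise ValueError(f"unknown column {col!r}; allowed: {TSV_COLUMNS}")


def write_tsv(
    report: ScanReport,
    path,
    columns: Iterable[str] | None = None,
) -> None:
    """Write calls as TSV with a selectable, ordered column subset.

    Parameter provenance is embedded as leading ``#`` comment lines.
    """
    columns = tuple(columns) if columns is not None else DEFAULT_TSV_COLUMNS
    for col in columns:
        if col not in TSV_COLUMNS:
            raise ValueError(f"unknown column {col!r}; allowed: {TSV_COLUMNS}")
    with open(path, "w") as fh:
        for key, val in sorted(report.params.items()):
            fh.write(f"# {key}={val}\n")
        fh.write("\t".join(columns) + "\n")
        for call in report.calls:
            fh.write("\t".join(_format_field(call, c) for c in columns) + "\n")


def classify_locus(call: LocusCall, db: ReferenceDB) -> tuple[str, str]:
    """Structural type and domain of a call, from its best-scoring reference."""
    ref = db.by_id[call.best_ref]
    return ref.structural_type, ref.domain


def read_calls_tsv(path) -> list[LocusCall]:
    """Read a calls TSV back (for evaluation); missing columns get defaults."""
    calls: list[LocusCall] = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            row = dict(zip(header, line.split("\t")))
            calls.append(
                LocusCall(
                    target_id=row.get("target_id", ""),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row.get("strand", "plus"),
                    structural_type=row.get("type", "A"),
                    domain=row.get("domain", "bacteria"),
                    best_ref=row.get("ref_id", ""),
                    raw_score=0,
                    bitscore=float(row.get("bitscore", 0.0)),
                    evalue=float(row.get("evalue", 0.0)),
                    percent_id=float(row.get("percent_id", 0.0)),
                    sequence=row.get("sequence", ""),
                    aln_len=0,
                )
            )
    return calls


def write_negatives_tsv(report: ScanReport, path) -> None:
    """Target ids with no rnpB call, one per row with reason ``no_hit``."""
    with open(path, "w") as fh:
        fh.write("target_id\treason\n")
        for tid in report.negatives:
            fh.write(f"{tid}\tno_hit\n")


def write_gff3(report: ScanReport, path) -> None:
    """Write calls as GFF3 features of type ``rnpB`` (score = bitscore)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for key, val in sorted(report.params.items()):
            fh.write(f"# {key}={val}\n")
        for i, call in enumerate(report.calls, start=1):
            strand = "+" if call.strand == "plus" else "-"
            attrs = (
                f"ID=rnpB_{i}"
                f";structural_type={call.structural_type}"
                f";domain={call.domain}"
                f";evalue={call.evalue:.3g}"
                f";percent_id={call.percent_id:.2f}"
                f";best_ref={call.best_ref}"
            )
            fh.write(
                "\t".join(
                    [
                        call.target_id,
                        "rnpbscan",
                        "rnpB",
                        str(call.start),
                        str(call.end),
                        f"{call.bitscore:.2f}",
                        strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
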