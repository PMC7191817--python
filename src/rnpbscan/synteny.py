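"""Conserved rpmH-rnpA-yidD gene-context check.

In many bacteria the RNase P protein gene *rnpA* sits immediately downstream
of *rpmH* (ribosomal protein L34) and immediately upstream of *yidD*, all on
one strand.  Genomes lacking a detectable RNase P RNA (notably the reduced
genomes of obligate insect endosymbionts) can be screened for this
arrangement from an existing annotation: its absence supports genuine gene
loss rather than a missed call.

"Immediately" is interpreted as zero intervening annotated genes, with no
distance bound by default (a ``max_gap`` in nucleotides may be supplied).
Overlapping genes count as adjacent, not intervening.  The misspelling
"rmpH" is accepted as an alias of rpmH.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import gffutils

GENE_ALIASES = {
    "rpmh": "rpmH",
    "rmph": "rpmH",  # common misspelling, treated as rpmH
    "rnpa": "rnpA",
    "yidd": "yidD",
}


@dataclass(frozen=True)
class GeneFeature:
    """A named gene with 1-based inclusive coordinates and a strand."""

    name: str
    start: int
    end: int
    strand: str  # "plus" | "minus" (also accepts "+"/"-")

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"malformed feature {self.name!r}: start {self.start} > "
                f"end {self.end}"
            )

    @property
    def norm_strand(self) -> str:
        return {"+": "plus", "-": "minus"}.get(self.strand, self.strand)


@dataclass
class SyntenyResult:
    """Outcome of the arrangement check for one genome."""

    present: dict[str, bool]
    arrangement_found: bool
    violations: list[str] = field(default_factory=list)


def _canonical(name: str) -> str | None:
    return GENE_ALIASES.get(name.lower())


def _intervening(left: GeneFeature, right: GeneFeature, others) -> list[str]:
    """Genes strictly inside the gap between two ordered features."""
    gap_lo, gap_hi = left.end + 1, right.start - 1
    if gap_lo > gap_hi:
        return []
    bad = []
    for g in others:
        overlaps_gap = g.end >= gap_lo and g.start <= gap_hi
        touches_member = (
            (g.end >= left.start and g.start <= left.end)
            or (g.end >= right.start and g.start <= right.end)
        )
        if overlaps_gap and not touches_member:
            bad.append(g.name)
    return bad


def check_rnpa_context(
    genes: list[GeneFeature], max_gap: int | None = None
) -> SyntenyResult:
    """Look for rpmH -> rnpA -> yidD on one strand with nothing in between.

    The order is taken in transcription direction: on the plus strand rpmH
    precedes rnpA precedes yidD in forward coordinates; on the minus strand
    the forward-coordinate order is mirrored.  ``arrangement_found`` is true
    iff some triple of annotated genes satisfies strand concordance, order,
    zero intervening genes, and (if given) the ``max_gap`` bound.
    """
    by_gene: dict[str, list[GeneFeature]] = {"rpmH": [], "rnpA": [], "yidD": []}
    for g in genes:
        canon = _canonical(g.name)
        if canon is not None:
            by_gene[canon].append(g)
    present = {name: bool(feats) for name, feats in by_gene.items()}
    missing = [name for name, ok in present.items() if not ok]
    if missing:
        return SyntenyResult(
            present=present,
            arrangement_found=False,
            violations=[f"missing {name}" for name in missing],
        )

    best_violations: list[str] | None = None
    triple_ids = {id(f) for feats in by_gene.values() for f in feats}
    for h, a, d in product(by_gene["rpmH"], by_gene["rnpA"], by_gene["yidD"]):
        violations: list[str] = []
        if not (h.norm_strand == a.norm_strand == d.norm_strand):
            violations.append("strand discordance")
        else:
            ordered = (
                (h, a, d) if h.norm_strand == "plus" else (d, a, h)
            )
            first, mid, last = ordered
            if not (first.start <= mid.start <= last.start):
                violations.append(
                    "wrong order: expected rpmH -> rnpA -> yidD in "
                    "transcription direction"
                )
            else:
                others = [g for g in genes if id(g) not in (id(h), id(a), id(d))]
                for left, right in ((first, mid), (mid, last)):
                    for name in _intervening(left, right, others):
                        violations.append(f"intervening gene {name}")
                    if (
                        max_gap is not None
                        and right.start - left.end - 1 > max_gap
                    ):
                        violations.append(
                            f"gap {right.start - left.end - 1} nt between "
                            f"{left.name} and {right.name} exceeds {max_gap}"
                        )
        if not violations:
            return SyntenyResult(
                present=present, arrangement_found=True, violations=[]
            )
        if best_violations is None or len(violations) < len(best_violations):
            best_violations = violations
    return SyntenyResult(
        present=present,
        arrangement_found=False,
        violations=best_violations or [],
    )


def read_gff3_genes(path) -> list[GeneFeature]:
    """Load gene features from GFF3; names from Name=, gene= or locus_tag=.

    Features of type ``gene`` are used when present, otherwise all features
    carrying a usable name attribute.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True,
        keep_order=True,
    )
    feats = list(db.features_of_type("gene"))
    if not feats:
        feats = list(db.all_features())
    genes: list[GeneFeature] = []
    for f in feats:
        name = None
        for key in ("Name", "gene", "locus_tag", "ID"):
            if key in f.attributes:
                name = f.attributes[key][0]
                break
        if name is None:
            continue
        genes.append(
            GeneFeature(name=name, start=f.start, end=f.end, strand=f.strand)
        )
    return genes


def write_synteny_tsv(result: SyntenyResult, path, genome_id: str = "genome") -> None:
    with open(path, "w") as fh:
        fh.write(
            "genome\trpmH\trnpA\tyidD\tarrangement_found\tviolations\n"
        )
        fh.write(
            "\t".join(
                [
                    genome_id,
                    str(result.present["rpmH"]).lower(),
                    str(result.present["rnpA"]).lower(),
                    str(result.present["yidD"]).lower(),
                    str(result.arrangement_found).lower(),
                    ";".join(result.violations) or ".",
                ]
            )
            + "\n"
        )
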