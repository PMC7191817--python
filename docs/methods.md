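# Methods

## Problem and approach

The rnpB gene encodes the catalytic RNA of RNase P. Its sequence *and*
secondary structure vary across prokaryotes (five recognised structural
classes, A/B/C/M/T, ~190–550 nt), so structure-aware models are expensive to
maintain. `rnpbscan` instead couples a typed reference database to a seeded
local-alignment search: every hit is scored, assigned the structural class
and taxonomic domain of its best-matching reference, and reported in
forward-strand genome coordinates.

## Alignment model

Local alignment uses affine-gap Smith–Waterman with the three-state
(match / gap-in-target / gap-in-reference) recurrence. A gap of length L
costs `gap_open + (L−1)·gap_extend`: the first gapped base pays the opening
cost. Defaults (match +2, mismatch −3, gap open 5, gap extend 2) follow
common nucleotide-search practice and suit the ~90%-identity regime in which
a same-class reference matches a true gene.

Numerical/determinism choices:

* IUPAC ambiguity codes are kept in references but always score as a
  mismatch, including against themselves (N vs N). They are never used as
  seeds. This is conservative and keeps scoring deterministic.
* With strictly positive gap costs an optimal local alignment neither starts
  nor ends in a gap column, so the optimum is taken over match-state cells.
* Traceback tie-break: diagonal over up (gap in reference) over left (gap in
  target); among equally scoring maximal cells the alignment with the
  smallest (target_start, ref_start, target_end, ref_end) is returned.
  Identical inputs therefore always produce identical output.
* The DP kernel is a numba-compiled int64 fill; scores are exact integers.

## Seeding and banded extension

Exact k-mers (default k = 12) shared between target and reference are
grouped by (reference, diagonal); seeds whose diagonals differ by at most
`band` (default 32) form one cluster, and each cluster is extended by a
banded Smith–Waterman restricted to the cluster's diagonal envelope padded
by `band` on each side. k = 12 is specific enough that a random 100 kb
genome shares only a handful of words with a ~17 kb reference set, yet a
10%-diverged 380 nt gene still retains ~100 intact 12-mers in expectation;
band 32 comfortably covers the diagonal drift produced by scattered
single-base indels. Because banding only removes paths, the heuristic score
is a lower bound on the full-DP score, with equality on exact copies — this
admissibility is the tested contract of the heuristic layer.

## Alignment statistics

λ is solved from Σᵢⱼ pᵢpⱼ e^{λsᵢⱼ} = 1 by Brent's method to 1e−9 (the
ungapped equation applied to the gapped scheme, as is common practice); the
equation has a positive root only when the expected per-position score is
negative, which the scoring-scheme constructor enforces. K defaults to 0.41
and is a documented constant rather than an estimate: deriving gapped K by
simulation is out of scope, and E-values serve as rankings and thresholds,
not calibrated probabilities. Bitscore S′ = (λS − ln K)/ln 2; E = m·n·2^(−S′)
with m the target length and n the total reference length. Percent identity
counts gap columns in its denominator: 100·matches/columns.

## Calling and classification

Both strands are scanned (the reverse complement is searched and coordinates
mapped back by start′ = L − end + 1, end′ = L − start + 1, so start ≤ end is
invariant). Hits survive at E ≤ 1e−5 and ≥ 120 alignment columns — E ≤ 1e−5
makes chance hits essentially impossible at genome scale, and 120 columns is
well below the shortest real gene (~190 nt) while excluding fragmentary
matches. Overlap resolution is greedy by descending bitscore (ties: lower
E, smaller start, lexicographic reference id); a candidate overlapping an
accepted call by more than half the shorter interval is discarded. Multiple
non-overlapping calls per target are allowed — no one-gene-per-genome cap.
Classification copies type and domain from the best reference; a discarded
overlapping candidate of a different type within 5 bits attaches an
ambiguity warning without changing the classification.

## Reference database

Plain FASTA with whitespace-separated `key=value` header tags (`type=`,
`domain=`, optional `source=` which captures the rest of the line).
Accepted lengths are 150–700 nt, bracketing the observed 250–550 nt span of
most classes and the shorter minimal T class; the bounds are configurable.
Loading is strict — any invalid record aborts the load with the offending id
— unless a permissive flag is set. Writing and re-parsing a database is an
exact round trip.

## Synteny check

In many bacteria rnpA lies immediately downstream of rpmH and immediately
upstream of yidD, all on one strand. `check_rnpa_context` reports the
arrangement as found iff all three genes are annotated on a common strand,
ordered rpmH → rnpA → yidD in transcription direction, with zero intervening
annotated genes. "Immediately" is interpreted as adjacency in the gene
order, with no distance bound by default (a `max_gap` is available);
overlapping genes count as adjacent. The misspelling "rmpH" is accepted as
an alias of rpmH. The check is annotation-based only; it does not attempt
homology search for unannotated copies.

## Synthetic benchmark

The generator replaces a genome survey that would need thousands of
downloaded assemblies and a curated reference set. It emulates the field's
observed structure: per structural type it draws independent founder
sequences with per-type length ranges (A 300–420, B 290–400, C 340–400,
M 230–260, T 190–230 nt; M and T are tagged archaeal) and derives family
members by substitution at a rate drawn from [0, 0.05], keeping within-family
divergence under ~10% while different families and types sit at the
random-DNA background (~50% identity). Plants are mutated copies of randomly
chosen references placed uniformly and non-overlapping (100 nt spacing
buffer so neighbouring plants cannot merge into one call), strand uniform;
truth records coordinates, source, type, strand and realized divergence.
Mutation applies per-base substitutions and single-base indels only — enough
to exercise affine gaps without committing to an indel length distribution.
All randomness flows from a mandatory seed; outputs are byte-reproducible.

Evaluation matches calls to truth loci at reciprocal overlap ≥ 50%, greedily
by overlap, then scores sensitivity, precision (1.0 by convention, flagged,
when there are no calls at all), boundary errors, and type/strand accuracy.

The standard benchmark conditions are 20 seeded replicates of a 100 kb
genome with three plants — one each at 0%, 5% and 10% substitution
divergence (no indels, so "divergence" is exactly the substitution rate) —
drawn from a fresh 5-type, 50-record database (2 families × 5 members per
type). These sizes keep a full run under a minute on one CPU while giving 60
planted loci per benchmark. What passing shows: the pipeline loses nothing
to seeding, banding, thresholds, strand handling or coordinate bookkeeping
in the ≤10%-divergence regime. What it does not show: performance on real
genomes, where conserved domains, skewed composition, repeats and distant
homologs (>10% divergence) matter; the degradation test (sensitivity
non-increasing over substitution rates 0–30%) probes the trend but synthetic
families cannot certify real-world sensitivity.

## Known limitations

* No covariance/secondary-structure scoring: classification is purely
  by best-matching reference, so it is only as good as the database's
  coverage of each class.
* E-values use the ungapped λ with a fixed K; absolute values are
  approximate (rankings and thresholds are what the pipeline relies on).
* Hits are not merged across contig boundaries in metagenomic input.
* The synteny check cannot distinguish "gene absent" from "gene present but
  unannotated".
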