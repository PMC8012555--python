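"""Two-stage PDE annotation: homology candidates, then domain filtering.

A protein is annotated as a polysaccharide-degrading enzyme when

1. a local-alignment search against the curated reference set yields a hit
   with e-value <= 0.001 and local identity >= 30% over the matching region
   (candidate stage);
2. the candidate shares a catalytic-domain family with its single
   best-matched reference, and for that family at least 80% of the catalytic
   domain falls inside the alignment region on *both* sides — the candidate
   domain against the query match region and the reference domain against
   the subject match region (filter stage).

The accepted protein inherits the enzyme type of its best-matched reference.
"Best" is fully deterministic: maximal bit score, then lower e-value, then
higher identity, then lexicographically smallest subject id.  Every rule
evaluation is recorded in a decision trace so acceptances and rejections are
auditable.

The filters are conjunctive, so for a fixed best hit raising either the
identity or the domain-coverage threshold can only reject more candidates.
The threshold-sweep operation exploits this: the expensive search runs once
and the cheap filters are re-applied per grid cell, reporting accepted sets
(not just counts) so monotonicity can be checked by set inclusion.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

from .align import AlignmentHit, local_align
from .refdb import DomainSpan, ReferenceEnzyme, ReferenceSet

#: Column order of the 15-field tabular hit dialect.
HIT_COLUMNS = (
    "qseqid", "stitle", "pident", "qcovs", "qlen", "slen", "length",
    "mismatch", "gapopen", "qstart", "qend", "sstart", "send",
    "evalue", "bitscore",
)


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotationThresholds:
    """Candidate and filter cutoffs; defaults are the study conditions."""

    min_identity: float = 30.0      # percent local identity, inclusive
    min_domain_coverage: float = 0.80  # fraction of domain in match region
    max_evalue: float = 0.001

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 100:
            raise AnnotationError("min_identity must be in (0, 100]")
        if not 0 < self.min_domain_coverage <= 1:
            raise AnnotationError("min_domain_coverage must be in (0, 1]")


@dataclass(frozen=True)
class PDEAnnotation:
    """An accepted enzyme call with its provenance."""

    protein_id: str
    genome_id: str
    enzyme_type: str
    best_ref_id: str
    matched_family: str
    pident: float
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0
    decision_trace: tuple[str, ...] = field(default=(), compare=False)


# ---------------------------------------------------------------------------
# tabular dialect I/O


def parse_tabular_hits(source: str | Path | TextIO) -> list[AlignmentHit]:
    """Parse a 15-column tab-separated hit table (positional mapping).

    The subject id is the first whitespace-delimited token of the ``stitle``
    field.  A row with the wrong field count, or a non-numeric value where a
    number is required, raises with its 1-based line number.
    """
    if isinstance(source, (str, Path)):
        stream: TextIO = open(source)
        close = True
    else:
        stream, close = source, False
    hits = []
    try:
        for lineno, line in enumerate(stream, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 15:
                raise AnnotationError(
                    f"line {lineno}: expected 15 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                hit = AlignmentHit(
                    query_id=fields[0],
                    stitle=fields[1],
                    pident=float(fields[2]),
                    qcovs=float(fields[3]),
                    qlen=int(fields[4]),
                    slen=int(fields[5]),
                    aln_len=int(fields[6]),
                    mismatches=int(fields[7]),
                    gap_opens=int(fields[8]),
                    qstart=int(fields[9]),
                    qend=int(fields[10]),
                    sstart=int(fields[11]),
                    send=int(fields[12]),
                    evalue=float(fields[13]),
                    bitscore=float(fields[14]),
                )
            except ValueError as exc:
                raise AnnotationError(f"line {lineno}: {exc}") from exc
            hits.append(hit)
    finally:
        if close:
            stream.close()
    return hits


def write_tabular_hits(hits: Iterable[AlignmentHit],
                       dest: str | Path | TextIO) -> None:
    """Write hits in the same 15-column dialect ``parse_tabular_hits`` reads."""
    if isinstance(dest, (str, Path)):
        stream: TextIO = open(dest, "w")
        close = True
    else:
        stream, close = dest, False
    try:
        for h in hits:
            stream.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id, h.stitle, h.pident, h.qcovs, h.qlen,
                        h.slen, h.aln_len, h.mismatches, h.gap_opens,
                        h.qstart, h.qend, h.sstart, h.send,
                        h.evalue, h.bitscore,
                    )
                )
                + "\n"
            )
    finally:
        if close:
            stream.close()


def hits_to_string(hits: Iterable[AlignmentHit]) -> str:
    buf = io.StringIO()
    write_tabular_hits(hits, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# candidate selection


def candidate_hits(hits: Iterable[AlignmentHit],
                   thresholds: AnnotationThresholds) -> list[AlignmentHit]:
    """Hits surviving the e-value and local-identity candidate cutoffs."""
    return [
        h for h in hits
        if h.evalue <= thresholds.max_evalue
        and h.pident >= thresholds.min_identity
    ]


def select_best_hit(hits: Sequence[AlignmentHit]) -> AlignmentHit | None:
    """The single best hit for one query, or None when no hit survives.

    Ranking: maximal bitscore; ties by lower evalue, then higher pident,
    then lexicographically smallest subject id — fully deterministic.
    """
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.bitscore, h.evalue, -h.pident,
                                    h.subject_id))


def domain_in_match_coverage(domain: DomainSpan, match_start: int,
                             match_end: int) -> float:
    """Fraction of a catalytic domain lying inside a match region
    (1-based inclusive overlap / domain length)."""
    overlap = max(0, min(domain.end, match_end) - max(domain.start, match_start) + 1)
    return overlap / domain.length


def decide_candidate(
    query_domains: Sequence[DomainSpan],
    ref: ReferenceEnzyme,
    best_hit: AlignmentHit,
    thresholds: AnnotationThresholds,
    genome_id: str = "",
) -> tuple[bool, PDEAnnotation | None, tuple[str, ...]]:
    """Apply the domain-consistency and coverage rules to one candidate.

    ``best_hit`` must already have passed the candidate cutoffs.  Acceptance
    requires some family F present in both the query's and the reference's
    domain lists such that the query's F-domain covers >= the coverage
    threshold of the query match region and the reference's F-domain does the
    same on the subject side.  The returned trace records every evaluation.
    """
    trace: list[str] = [
        f"best-hit={ref.ref_id} bitscore={best_hit.bitscore} "
        f"pident={best_hit.pident:.1f}"
    ]
    if not ref.domains:
        trace.append("reject: ref-no-domain")
        return False, None, tuple(trace)
    if not query_domains:
        trace.append("reject: query-no-domain")
        return False, None, tuple(trace)
    ref_families = {d.family for d in ref.domains}
    accept_family = None
    for dq in query_domains:
        if dq.family not in ref_families:
            trace.append(f"query-domain {dq.family}: no family match in reference")
            continue
        cov_q = domain_in_match_coverage(dq, best_hit.qstart, best_hit.qend)
        if cov_q < thresholds.min_domain_coverage:
            trace.append(
                f"query-domain {dq.family} ({dq.start},{dq.end}): "
                f"coverage {cov_q:.3f} < {thresholds.min_domain_coverage}"
            )
            continue
        for dr in ref.domains:
            if dr.family != dq.family:
                continue
            cov_r = domain_in_match_coverage(dr, best_hit.sstart, best_hit.send)
            trace.append(
                f"family {dq.family}: query coverage {cov_q:.3f}, "
                f"reference coverage {cov_r:.3f}"
            )
            if cov_r >= thresholds.min_domain_coverage:
                accept_family = dq.family
                break
        if accept_family:
            break
    if accept_family is None:
        trace.append("reject: no domain pair satisfies consistency+coverage")
        return False, None, tuple(trace)
    trace.append(f"accept: family {accept_family}, "
                 f"enzyme_type {ref.enzyme_type!r} transferred")
    annotation = PDEAnnotation(
        protein_id=best_hit.query_id,
        genome_id=genome_id,
        enzyme_type=ref.enzyme_type,
        best_ref_id=ref.ref_id,
        matched_family=accept_family,
        pident=best_hit.pident,
        qstart=best_hit.qstart,
        qend=best_hit.qend,
        sstart=best_hit.sstart,
        send=best_hit.send,
        decision_trace=tuple(trace),
    )
    return True, annotation, tuple(trace)


# ---------------------------------------------------------------------------
# whole-proteome annotation


def search_proteome(
    proteome: Mapping[str, str],
    refset: ReferenceSet,
    max_evalue: float | None = None,
) -> list[AlignmentHit]:
    """All-vs-all internal local-alignment search of a proteome against the
    reference set.  An ``max_evalue`` prefilter (if given) discards hopeless
    hits early; identity filtering is deliberately left to the caller so one
    search can serve a whole threshold sweep."""
    hits = []
    for pid, seq in proteome.items():
        for ref in refset:
            hit = local_align(seq, ref.sequence, query_id=pid,
                              subject_id=ref.ref_id)
            if hit is None:
                continue
            if max_evalue is not None and hit.evalue > max_evalue:
                continue
            hits.append(hit)
    return hits


def annotate_from_hits(
    hits: Iterable[AlignmentHit],
    query_domains: Mapping[str, Sequence[DomainSpan]],
    refset: ReferenceSet,
    thresholds: AnnotationThresholds | None = None,
    genome_id: str = "",
) -> list[PDEAnnotation]:
    """Run candidate selection + domain filtering over a prepared hit table."""
    thr = thresholds or AnnotationThresholds()
    per_query: dict[str, list[AlignmentHit]] = {}
    for h in candidate_hits(hits, thr):
        if h.subject_id not in refset:
            raise AnnotationError(
                f"hit subject {h.subject_id!r} not in the reference set"
            )
        per_query.setdefault(h.query_id, []).append(h)
    annotations = []
    for qid in sorted(per_query):
        best = select_best_hit(per_query[qid])
        if best is None:  # pragma: no cover - per_query only has nonempty lists
            continue
        accepted, ann, _ = decide_candidate(
            tuple(query_domains.get(qid, ())), refset[best.subject_id],
            best, thr, genome_id=genome_id,
        )
        if accepted and ann is not None:
            annotations.append(ann)
    return annotations


def annotate_genome(
    proteome: Mapping[str, str],
    refset: ReferenceSet,
    query_domains: Mapping[str, Sequence[DomainSpan]],
    thresholds: AnnotationThresholds | None = None,
    genome_id: str = "",
    hits: Iterable[AlignmentHit] | None = None,
) -> list[PDEAnnotation]:
    """Annotate one genome's proteome.

    ``hits`` may supply a pre-computed external hit table; otherwise the
    internal aligner searches every protein against every reference.  Each
    protein receives at most one enzyme type (from its single best match).
    """
    collisions = set(proteome) & set(refset.ids)
    if collisions:
        raise AnnotationError(
            f"proteome/reference id collisions: {sorted(collisions)[:5]}"
        )
    thr = thresholds or AnnotationThresholds()
    if hits is None:
        hits = search_proteome(proteome, refset, max_evalue=thr.max_evalue)
    return annotate_from_hits(hits, query_domains, refset, thr,
                              genome_id=genome_id)


def threshold_sweep(
    hits_by_genome: Mapping[str, Sequence[AlignmentHit]],
    query_domains: Mapping[str, Sequence[DomainSpan]],
    refset: ReferenceSet,
    identity_grid: Sequence[float],
    coverage_grid: Sequence[float],
    max_evalue: float = 0.001,
) -> tuple[pd.DataFrame, dict[tuple[float, float], set[tuple[str, str]]]]:
    """Accepted-annotation counts over an identity x coverage grid.

    Takes hit tables searched once per genome (identity-unfiltered) and
    re-runs only the cheap filters per cell.  Returns the count matrix
    (rows = identity, columns = coverage) and, per cell, the accepted
    (genome_id, protein_id) set so callers can verify set-inclusion
    monotonicity, not just counts.
    """
    if not identity_grid or not coverage_grid:
        raise AnnotationError("threshold grids must be non-empty")
    counts = pd.DataFrame(
        0, index=list(identity_grid), columns=list(coverage_grid), dtype=int
    )
    accepted: dict[tuple[float, float], set[tuple[str, str]]] = {}
    for ident in identity_grid:
        for cov in coverage_grid:
            thr = AnnotationThresholds(
                min_identity=ident, min_domain_coverage=cov,
                max_evalue=max_evalue,
            )
            cell: set[tuple[str, str]] = set()
            for gid, hits in hits_by_genome.items():
                for ann in annotate_from_hits(hits, query_domains, refset,
                                              thr, genome_id=gid):
                    cell.add((gid, ann.protein_id))
            accepted[(ident, cov)] = cell
            counts.loc[ident, cov] = len(cell)
    counts.index.name = "min_identity"
    counts.columns.name = "min_domain_coverage"
    return counts, accepted


def write_annotations(annotations: Iterable[PDEAnnotation],
                      path: str | Path) -> None:
    rows = [
        {
            "protein_id": a.protein_id,
            "genome_id": a.genome_id,
            "enzyme_type": a.enzyme_type,
            "best_ref_id": a.best_ref_id,
            "matched_family": a.matched_family,
            "pident": round(a.pident, 2),
            "qstart": a.qstart,
            "qend": a.qend,
            "sstart": a.sstart,
            "send": a.send,
        }
        for a in annotations
    ]
    pd.DataFrame(
        rows,
        columns=["protein_id", "genome_id", "enzyme_type", "best_ref_id",
                 "matched_family", "pident", "qstart", "qend", "sstart",
                 "send"],
    ).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> list[PDEAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [
        PDEAnnotation(
            protein_id=str(r.protein_id),
            genome_id=str(r.genome_id),
            enzyme_type=str(r.enzyme_type),
            best_ref_id=str(r.best_ref_id),
            matched_family=str(r.matched_family),
            pident=float(r.pident),
            qstart=int(r.qstart),
            qend=int(r.qend),
            sstart=int(r.sstart),
            send=int(r.send),
        )
        for r in df.itertuples()
    ]
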