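"""Genome selection and quality control.

Assemblies enter the analysis only if they look like complete, uncontaminated
genomes of marine isolates: a marine-keyword screen of the free-text
isolation source, N50 >= 50 kb, checkM-style completeness >= 95% and
contamination <= 5%, all 31 universal marker genes present, and one assembly
per strain.  Completeness, contamination and marker counts are consumed from
a metadata table (they are produced by external tools); only N50 is computed
here when contig lengths are available.

All boundary comparisons are inclusive exactly as written above: an assembly
at N50 = 50,000 / completeness = 95.0 / contamination = 5.0 / 31 markers
passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

MARKER_GENE_COUNT = 31


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class QCThresholds:
    """Quality cutoffs; defaults are the study conditions."""

    min_n50: int = 50_000
    min_completeness: float = 95.0
    max_contamination: float = 5.0
    required_markers: int = MARKER_GENE_COUNT

    def __post_init__(self) -> None:
        if min(self.min_n50, self.min_completeness,
               self.required_markers) < 0 or self.max_contamination < 0:
            raise QCError("thresholds must be non-negative")


@dataclass
class GenomeRecord:
    """One assembly with the metadata the QC filters consume."""

    assembly_id: str
    strain_id: str = ""
    isolation_source: str = ""
    completeness: float | None = None
    contamination: float | None = None
    marker_genes_found: int | None = None
    lineage: tuple[str, ...] = ()
    contig_lengths: tuple[int, ...] | None = None
    n50: int | None = None

    def __post_init__(self) -> None:
        for name in ("completeness", "contamination"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 100:
                raise QCError(f"{self.assembly_id}: {name}={v} outside [0, 100]")
        m = self.marker_genes_found
        if m is not None and not 0 <= m <= MARKER_GENE_COUNT:
            raise QCError(
                f"{self.assembly_id}: marker_genes_found={m} outside "
                f"[0, {MARKER_GENE_COUNT}]"
            )
        if self.n50 is None and self.contig_lengths:
            self.n50 = compute_n50(self.contig_lengths)


def compute_n50(contig_lengths: Sequence[int]) -> int:
    """N50 of an assembly: the length L such that contigs of length >= L
    cover at least half of the total assembly length.

    Computed by sorting contigs in descending order and returning the length
    at which the cumulative sum first reaches 50% of the total.
    """
    if not contig_lengths:
        raise QCError("compute_n50: empty contig list")
    if min(contig_lengths) <= 0:
        raise QCError("compute_n50: contig lengths must be positive")
    lengths = sorted(contig_lengths, reverse=True)
    half = sum(lengths) / 2
    acc = 0
    for length in lengths:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def default_marine_wordlist() -> tuple[str, ...]:
    """The packaged marine-keyword list (editable text file)."""
    text = (
        resources.files("marinepde").joinpath("data/marine_words.txt").read_text()
    )
    return _parse_wordlist(text.splitlines())


def load_wordlist(path: str | Path) -> tuple[str, ...]:
    """Load a user keyword list: one substring per line, '#' comments."""
    return _parse_wordlist(Path(path).read_text().splitlines())


def _parse_wordlist(lines: Iterable[str]) -> tuple[str, ...]:
    words = tuple(
        w.strip().casefold()
        for w in lines
        if w.strip() and not w.lstrip().startswith("#")
    )
    if not words:
        raise QCError("empty marine word list")
    return words


def marine_source_match(isolation_source: str | None,
                        wordlist: Sequence[str]) -> bool:
    """True iff any keyword occurs as a case-insensitive substring of the
    isolation-source string.  Empty or missing sources never match."""
    if not wordlist:
        raise QCError("marine_source_match: empty word list")
    if not isolation_source:
        return False
    source = " ".join(str(isolation_source).split()).casefold()
    if not source:
        return False
    return any(w.casefold() in source for w in wordlist)


def filter_marine(
    records: Iterable[GenomeRecord], wordlist: Sequence[str] | None = None
) -> tuple[list[GenomeRecord], list[GenomeRecord]]:
    """Split records into (marine, non-marine) by the keyword screen."""
    if wordlist is None:
        wordlist = default_marine_wordlist()
    marine, other = [], []
    for rec in records:
        (marine if marine_source_match(rec.isolation_source, wordlist)
         else other).append(rec)
    return marine, other


@dataclass(frozen=True)
class QCRejection:
    record: GenomeRecord
    reasons: tuple[str, ...]


def _evaluate(rec: GenomeRecord, thr: QCThresholds) -> tuple[str, ...]:
    reasons: list[str] = []
    if rec.n50 is None:
        reasons.append("missing-metric:n50")
    elif rec.n50 < thr.min_n50:
        reasons.append("n50")
    if rec.completeness is None:
        reasons.append("missing-metric:completeness")
    elif rec.completeness < thr.min_completeness:
        reasons.append("completeness")
    if rec.contamination is None:
        reasons.append("missing-metric:contamination")
    elif rec.contamination > thr.max_contamination:
        reasons.append("contamination")
    if rec.marker_genes_found is None:
        reasons.append("missing-metric:markers")
    elif rec.marker_genes_found != thr.required_markers:
        reasons.append("markers")
    return tuple(reasons)


def qc_filter(
    records: Iterable[GenomeRecord], thresholds: QCThresholds | None = None
) -> tuple[list[GenomeRecord], list[QCRejection]]:
    """Apply all quality criteria conjunctively.

    Returns ``(passed, rejections)``; each rejection lists *every* failed
    criterion, and a missing metric is itself a rejection reason.  The
    criteria are evaluated independently, so their order cannot change the
    outcome.
    """
    thr = thresholds or QCThresholds()
    passed, rejected = [], []
    for rec in records:
        reasons = _evaluate(rec, thr)
        if reasons:
            rejected.append(QCRejection(rec, reasons))
        else:
            passed.append(rec)
    return passed, rejected


def deduplicate_by_strain(records: Sequence[GenomeRecord]) -> list[GenomeRecord]:
    """Keep one assembly per strain: highest N50, ties broken by the
    lexicographically greatest assembly_id.  Records without a strain id are
    treated as singleton strains.  Idempotent and order-independent."""
    best: dict[str, GenomeRecord] = {}
    for rec in records:
        key = rec.strain_id or f"__solo__{rec.assembly_id}"
        cur = best.get(key)
        if cur is None:
            best[key] = rec
            continue
        rank = ((rec.n50 or 0), rec.assembly_id)
        cur_rank = ((cur.n50 or 0), cur.assembly_id)
        if rank > cur_rank:
            best[key] = rec
    # deterministic output order regardless of input order
    return sorted(best.values(), key=lambda r: r.assembly_id)


def read_assembly_metadata(path: str | Path) -> list[GenomeRecord]:
    """Read the assembly metadata TSV into :class:`GenomeRecord` objects.

    Columns: assembly_id, strain_id, isolation_source, n50 (or
    contig_lengths as comma-separated integers), completeness, contamination,
    marker_genes_found, lineage (semicolon-separated).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "assembly_id" not in df.columns:
        raise QCError(f"{path}: missing assembly_id column")
    out = []
    for row in df.itertuples():
        def _opt(name: str, cast):
            v = getattr(row, name, None)
            if v is None or pd.isna(v) or str(v).strip() == "":
                return None
            return cast(v)

        contigs = _opt("contig_lengths", str)
        lineage = _opt("lineage", str)
        out.append(
            GenomeRecord(
                assembly_id=str(row.assembly_id),
                strain_id=_opt("strain_id", str) or "",
                isolation_source=_opt("isolation_source", str) or "",
                completeness=_opt("completeness", float),
                contamination=_opt("contamination", float),
                marker_genes_found=_opt("marker_genes_found",
                                        lambda v: int(float(v))),
                lineage=tuple(p.strip() for p in lineage.split(";"))
                if lineage else (),
                contig_lengths=tuple(int(x) for x in contigs.split(","))
                if contigs else None,
                n50=_opt("n50", lambda v: int(float(v))),
            )
        )
    return out


def write_assembly_metadata(records: Iterable[GenomeRecord],
                            path: str | Path) -> None:
    rows = [
        {
            "assembly_id": r.assembly_id,
            "strain_id": r.strain_id,
            "isolation_source": r.isolation_source,
            "n50": r.n50 if r.n50 is not None else "",
            "contig_lengths": ",".join(map(str, r.contig_lengths))
            if r.contig_lengths else "",
            "completeness": r.completeness if r.completeness is not None else "",
            "contamination": r.contamination
            if r.contamination is not None else "",
            "marker_genes_found": r.marker_genes_found
            if r.marker_genes_found is not None else "",
            "lineage": ";".join(r.lineage),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
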