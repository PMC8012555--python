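"""Curated reference-enzyme database: data model, I/O and source summaries.

The annotation pipeline transfers enzyme labels from a manually curated set of
experimentally verified polysaccharide-degrading enzymes (PDEs).  Each
reference carries its enzyme type (one of ten controlled labels), its CAZy
family (GHnn glycoside hydrolase or PLnn polysaccharide lyase), the position
of its catalytic domain(s) as found by a profile-HMM scan, and source
metadata (environment, taxonomic group, lineage).

The on-disk representation is a protein FASTA plus two tab-separated tables:
a metadata TSV (ref_id, enzyme_type, cazy_family, environment, taxon_group,
lineage) and a domain TSV (ref_id, family, start, end, score, evalue) with
1-based inclusive residue coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The closed set of enzyme-type labels.  Hyaluronidase is retained even
#: though genome screens may annotate zero of them; the pipeline must be able
#: to report that outcome rather than assuming nine types up front.
ENZYME_TYPES: tuple[str, ...] = (
    "cellulase",
    "chitinase",
    "chitosanase",
    "agarase",
    "carrageenase",
    "alginate lyase",
    "fucoidanase",
    "hyaluronate lyase",
    "hyaluronidase",
    "ulvan lyase",
)

ENVIRONMENTS: frozenset[str] = frozenset({"marine", "other", "unknown"})
TAXON_GROUPS: frozenset[str] = frozenset(
    {"bacteria", "fungi", "other-eukaryote", "virus", "unknown"}
)

AMINO_ACIDS: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class ReferenceSetError(ValueError):
    """Raised on malformed or inconsistent reference-set inputs."""


@dataclass(frozen=True)
class DomainSpan:
    """A catalytic-domain hit on a protein, 1-based inclusive coordinates."""

    family: str
    start: int
    end: int
    score: float = 0.0
    evalue: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))
        if not (1 <= self.start <= self.end):
            raise ReferenceSetError(
                f"invalid domain span ({self.start}, {self.end}): "
                "need 1 <= start <= end"
            )
        if self.evalue < 0:
            raise ReferenceSetError(f"negative evalue {self.evalue}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ReferenceEnzyme:
    """One curated reference enzyme with sequence, domains and metadata."""

    ref_id: str
    sequence: str
    enzyme_type: str
    cazy_family: str
    domains: tuple[DomainSpan, ...] = ()
    environment: str = "unknown"
    taxon_group: str = "unknown"
    lineage: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ReferenceSetError(f"{self.ref_id}: empty sequence")
        bad = set(self.sequence.upper()) - AMINO_ACIDS
        if bad:
            raise ReferenceSetError(
                f"{self.ref_id}: non-amino-acid characters {sorted(bad)}"
            )
        if self.enzyme_type not in ENZYME_TYPES:
            raise ReferenceSetError(
                f"{self.ref_id}: unknown enzyme_type {self.enzyme_type!r}"
            )
        if self.environment not in ENVIRONMENTS:
            raise ReferenceSetError(
                f"{self.ref_id}: unknown environment {self.environment!r}"
            )
        if self.taxon_group not in TAXON_GROUPS:
            raise ReferenceSetError(
                f"{self.ref_id}: unknown taxon_group {self.taxon_group!r}"
            )
        for d in self.domains:
            if d.end > len(self.sequence):
                raise ReferenceSetError(
                    f"{self.ref_id}: domain ({d.start},{d.end}) exceeds "
                    f"sequence length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


class ReferenceSet:
    """An ordered, id-keyed collection of :class:`ReferenceEnzyme`."""

    def __init__(self, references: Iterable[ReferenceEnzyme]) -> None:
        self._refs: dict[str, ReferenceEnzyme] = {}
        for ref in references:
            if ref.ref_id in self._refs:
                raise ReferenceSetError(f"duplicate ref_id {ref.ref_id!r}")
            self._refs[ref.ref_id] = ref

    def __len__(self) -> int:
        return len(self._refs)

    def __iter__(self) -> Iterator[ReferenceEnzyme]:
        return iter(self._refs.values())

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self._refs

    def __getitem__(self, ref_id: str) -> ReferenceEnzyme:
        return self._refs[ref_id]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self._refs)

    def undomained(self) -> tuple[str, ...]:
        """Ids of references without any recorded catalytic domain.

        Such references can never satisfy the domain-consistency filter and
        therefore can never yield an accepted annotation.
        """
        return tuple(r.ref_id for r in self if not r.domains)


def _norm(value: object, allowed: frozenset[str] | None = None) -> str:
    s = str(value).strip().lower() if value is not None and not pd.isna(value) else ""
    if not s:
        return "unknown"
    if allowed is not None and s not in allowed:
        return "unknown"
    return s


def _parse_lineage(value: object) -> tuple[str, ...]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ()
    s = str(value).strip()
    if not s or s.lower() == "unknown":
        return ()
    return tuple(part.strip() for part in s.split(";") if part.strip())


def load_reference_set(fasta_path: str | Path, metadata_path: str | Path) -> ReferenceSet:
    """Load references from a protein FASTA plus a metadata TSV.

    Every FASTA id must have exactly one metadata row.  Unknown or empty
    environment / taxon_group values map to ``"unknown"``; an enzyme type
    outside the controlled vocabulary is a hard error (the label set is
    closed-world: everything annotated downstream must trace back to it).
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"ref_id", "enzyme_type", "cazy_family"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ReferenceSetError(f"metadata missing columns {sorted(missing_cols)}")
    if meta["ref_id"].duplicated().any():
        dups = meta.loc[meta["ref_id"].duplicated(), "ref_id"].tolist()
        raise ReferenceSetError(f"duplicate metadata rows for {dups}")
    rows: Mapping[str, pd.Series] = {r.ref_id: r for r in meta.itertuples()}

    refs = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if not rec.id:
            raise ReferenceSetError(f"malformed FASTA record in {fasta_path}")
        if rec.id not in rows:
            raise ReferenceSetError(
                f"FASTA id {rec.id!r} has no metadata row in {metadata_path}"
            )
        row = rows[rec.id]
        refs.append(
            ReferenceEnzyme(
                ref_id=rec.id,
                sequence=str(rec.seq).upper(),
                enzyme_type=str(row.enzyme_type).strip(),
                cazy_family=str(row.cazy_family).strip(),
                environment=_norm(getattr(row, "environment", None), ENVIRONMENTS),
                taxon_group=_norm(getattr(row, "taxon_group", None), TAXON_GROUPS),
                lineage=_parse_lineage(getattr(row, "lineage", None)),
            )
        )
    if not refs:
        raise ReferenceSetError(f"no records parsed from {fasta_path}")
    return ReferenceSet(refs)


def read_domain_table(path: str | Path) -> pd.DataFrame:
    """Read a domain TSV (ref_id, family, start, end, score, evalue)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"ref_id", "family", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ReferenceSetError(f"domain table missing columns {sorted(missing)}")
    return df


def domains_by_id(domain_table: pd.DataFrame) -> dict[str, list[DomainSpan]]:
    """Group a domain table into per-protein lists sorted by start position."""
    out: dict[str, list[DomainSpan]] = {}
    for row in domain_table.itertuples():
        span = DomainSpan(
            family=str(row.family),
            start=int(row.start),
            end=int(row.end),
            score=float(getattr(row, "score", 0.0)),
            evalue=float(getattr(row, "evalue", 0.0)),
        )
        out.setdefault(str(row.ref_id), []).append(span)
    for spans in out.values():
        spans.sort(key=lambda d: (d.start, d.end, d.family))
    return out


def attach_domains(refset: ReferenceSet, domain_table: pd.DataFrame) -> ReferenceSet:
    """Return a new set with catalytic-domain spans attached to each reference.

    Spans are stored in order of start position.  A span extending beyond its
    protein, or a row naming an unknown ref_id, is a hard error.  References
    that end up with zero domains are legal but are reported by
    :meth:`ReferenceSet.undomained` — they can never be a usable best match.
    """
    grouped = domains_by_id(domain_table)
    unknown = set(grouped) - set(refset.ids)
    if unknown:
        raise ReferenceSetError(f"domain rows for unknown ref_ids {sorted(unknown)}")
    out = []
    for ref in refset:
        spans = tuple(grouped.get(ref.ref_id, ()))
        for d in spans:
            if d.end > len(ref.sequence):
                raise ReferenceSetError(
                    f"{ref.ref_id}: domain ({d.start},{d.end}) exceeds "
                    f"sequence length {len(ref.sequence)}"
                )
        out.append(replace(ref, domains=spans))
    return ReferenceSet(out)


def summarize_sources(refset: ReferenceSet) -> dict[str, dict[str, int]]:
    """Count references by environment, taxon group, enzyme type and family.

    Each facet's counts sum to ``len(refset)``; empty metadata is counted
    under ``"unknown"``.
    """
    if len(refset) == 0:
        raise ReferenceSetError("cannot summarize an empty reference set")
    facets: dict[str, dict[str, int]] = {
        "environment": {},
        "taxon_group": {},
        "enzyme_type": {},
        "cazy_family": {},
    }
    for ref in refset:
        for facet, key in (
            ("environment", ref.environment),
            ("taxon_group", ref.taxon_group),
            ("enzyme_type", ref.enzyme_type),
            ("cazy_family", ref.cazy_family),
        ):
            facets[facet][key] = facets[facet].get(key, 0) + 1
    return facets


def write_reference_set(
    refset: ReferenceSet,
    fasta_path: str | Path,
    metadata_path: str | Path,
    domain_path: str | Path | None = None,
) -> None:
    """Write FASTA + metadata TSV (+ optional domain TSV) round-trippably."""
    records = [
        SeqRecord(Seq(r.sequence), id=r.ref_id, description="") for r in refset
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    meta = pd.DataFrame(
        {
            "ref_id": [r.ref_id for r in refset],
            "enzyme_type": [r.enzyme_type for r in refset],
            "cazy_family": [r.cazy_family for r in refset],
            "environment": [r.environment for r in refset],
            "taxon_group": [r.taxon_group for r in refset],
            "lineage": [";".join(r.lineage) for r in refset],
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)
    if domain_path is not None:
        write_domain_table(
            ((r.ref_id, d) for r in refset for d in r.domains), domain_path
        )


def write_domain_table(
    spans: Iterable[tuple[str, DomainSpan]], path: str | Path
) -> None:
    rows = [
        {
            "ref_id": rid,
            "family": d.family,
            "start": d.start,
            "end": d.end,
            "score": d.score,
            "evalue": d.evalue,
        }
        for rid, d in spans
    ]
    pd.DataFrame(
        rows, columns=["ref_id", "family", "start", "end", "score", "evalue"]
    ).to_csv(path, sep="\t", index=False)
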