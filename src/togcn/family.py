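"""Gene-family candidate identification.

The screen follows the standard genome-wide workflow for plant TF families:
an HMM profile search (domain evidence) is intersected with a BLAST search
against a reference proteome filtered at >= 30% identity and e-value <= 1e-5,
and the survivors are renamed sequentially along the chromosomes
(prefix1..prefixN, natural chromosome order, then start coordinate).

Both homology searches are run externally; this module consumes their tabular
outputs (BLAST outfmt 6 and HMMER tabular).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils

from .exceptions import FormatError, MissingRecordError, ParameterError
from .utils import natural_key


@dataclass(frozen=True)
class HomologyHit:
    """One row of a homology-search table."""

    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    source: str  # "blast" or "hmm"

    def __post_init__(self):
        if not 0.0 <= self.percent_identity <= 100.0:
            raise FormatError(
                f"percent identity {self.percent_identity} outside [0, 100]"
            )
        if self.evalue < 0:
            raise FormatError(f"negative e-value {self.evalue}")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 1-based, closed
    end: int
    strand: str


@dataclass
class GenomeAnnotation:
    """Gene models keyed by id, with chromosome lengths when known."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_gff3(cls, path: str | Path, feature_type: str = "gene") -> "GenomeAnnotation":
        _validate_gff3(path)
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        ann = cls()
        for feat in db.features_of_type(feature_type):
            gid = feat.attributes.get("ID", [feat.id])[0]
            ann.genes[gid] = GeneModel(
                gene_id=gid, chrom=feat.seqid, start=feat.start,
                end=feat.end, strand=feat.strand,
            )
        return ann

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        try:
            return self.genes[gene_id]
        except KeyError:
            raise MissingRecordError(f"gene {gene_id!r} absent from annotation") from None


def _validate_gff3(path: str | Path) -> None:
    """Cheap structural check so malformed rows fail with a line number."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(
                    f"GFF3 row has {len(parts)} columns, expected 9", line=lineno
                )
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                raise FormatError(
                    "GFF3 start/end are not integers", line=lineno
                ) from None
            if start < 1 or end < start:
                raise FormatError(
                    f"GFF3 coordinates invalid: start={start} end={end}", line=lineno
                )
            if parts[6] not in {"+", "-", ".", "?"}:
                raise FormatError(f"GFF3 strand invalid: {parts[6]!r}", line=lineno)


def parse_blast_table(path: str | Path) -> list[HomologyHit]:
    """Parse BLAST outfmt-6 TSV (qseqid sseqid pident length ... evalue bitscore)."""
    hits = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise FormatError(
                    f"BLAST outfmt-6 row has {len(parts)} columns, expected 12",
                    line=lineno,
                )
            try:
                hits.append(HomologyHit(
                    query_id=parts[0], subject_id=parts[1],
                    percent_identity=float(parts[2]), evalue=float(parts[10]),
                    source="blast",
                ))
            except (ValueError, FormatError) as exc:
                if isinstance(exc, FormatError) and exc.line is not None:
                    raise
                raise FormatError(f"malformed BLAST row: {exc}", line=lineno) from None
    return hits


def parse_hmmer_table(path: str | Path) -> list[HomologyHit]:
    """Parse HMMER-style per-target tabular output.

    Whitespace-delimited with '#' comment lines; column 1 is the target
    (gene/protein) id, column 3 the query profile, column 5 the full-sequence
    e-value — the layout of ``hmmsearch --tblout``.
    """
    hits = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise FormatError(
                    f"HMMER tabular row has {len(parts)} columns, expected >= 5",
                    line=lineno,
                )
            try:
                hits.append(HomologyHit(
                    query_id=parts[0], subject_id=parts[2],
                    percent_identity=100.0, evalue=float(parts[4]),
                    source="hmm",
                ))
            except ValueError as exc:
                raise FormatError(f"malformed HMMER row: {exc}", line=lineno) from None
    return hits


def intersect_candidates(
    hmm_hits: list[HomologyHit],
    blast_hits: list[HomologyHit],
    identity_min: float = 30.0,
    evalue_max: float = 1e-5,
) -> set[str]:
    """Ids hit by the HMM profile AND by a passing BLAST row.

    BLAST rows pass with percent identity >= identity_min (inclusive) and
    e-value <= evalue_max (inclusive); a query with several rows survives if
    any row passes.  HMM hits are filtered on e-value only.
    """
    if identity_min <= 0 or evalue_max <= 0:
        raise ParameterError("identity_min and evalue_max must be positive")
    hmm_ids = {h.query_id for h in hmm_hits if h.evalue <= evalue_max}
    blast_ids = {
        h.query_id
        for h in blast_hits
        if h.percent_identity >= identity_min and h.evalue <= evalue_max
    }
    return hmm_ids & blast_ids


def rename_by_position(
    candidates: set[str], annotation: GenomeAnnotation, prefix: str
) -> dict[str, str]:
    """Assign prefix1..prefixN along the genome.

    Order: chromosome by natural sort (chr02 < chr10), then start coordinate,
    then gene id as the tie-break.  Returns an insertion-ordered mapping
    gene_id -> family name; independent of input iteration order.
    """
    models = [annotation[g] for g in candidates]
    models.sort(key=lambda m: (natural_key(m.chrom), m.start, m.gene_id))
    return {m.gene_id: f"{prefix}{i}" for i, m in enumerate(models, start=1)}


def write_renaming(mapping: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfamily_name\n")
        for gid, name in mapping.items():
            fh.write(f"{gid}\t{name}\n")
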