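"""Promoter extraction and cis-regulatory element (CRE) scanning.

Promoters are the 2000 bp upstream of the annotated gene start, taken
strand-aware (reverse-complemented for minus-strand genes) and truncated —
never padded — at chromosome ends.  CREs are short IUPAC-encoded motifs
scanned on both strands of the promoter; matches are tallied per gene and
rolled up into three functional categories (stress, hormone, growth).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from .exceptions import MissingRecordError, ParameterError
from .family import GenomeAnnotation
from .utils import iupac_to_regex, percent_share, revcomp, validate_iupac

CATEGORIES = ("stress", "hormone", "growth")


@dataclass(frozen=True)
class CREMotif:
    element_name: str
    pattern: str  # IUPAC nucleotide string
    category: str  # stress | hormone | growth | other


@dataclass(frozen=True)
class CREMatch:
    gene_id: str
    element_name: str
    category: str
    promoter_offset: int  # 0-based, leftmost forward-strand position
    strand: str  # '+' or '-' relative to the promoter


def load_motif_table(path: str | Path | None = None) -> list[CREMotif]:
    """Load a motif TSV (element_name, iupac_pattern, category).

    With no path, the packaged default catalog is used: 38 elements in the
    standard PlantCARE-style three-way split (10 stress, 11 hormone,
    17 growth).
    """
    if path is None:
        source = resources.files("togcn.data").joinpath("cre_catalog.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    motifs = []
    for _, row in df.iterrows():
        motifs.append(
            CREMotif(
                element_name=str(row["element_name"]),
                pattern=validate_iupac(str(row["iupac_pattern"])),
                category=str(row["category"]),
            )
        )
    return motifs


def extract_promoters(
    genome_fasta: str | Path,
    annotation: GenomeAnnotation,
    upstream: int = 2000,
    gene_ids: list[str] | None = None,
) -> dict[str, str]:
    """Strand-aware upstream regions, 5'->3' relative to each gene.

    Plus-strand gene: [start - upstream, start - 1] on the forward strand.
    Minus-strand gene: [end + 1, end + upstream], reverse-complemented.
    Truncated at chromosome boundaries, never padded.
    """
    if upstream <= 0:
        raise ParameterError("upstream length must be positive")
    fasta = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    ids = gene_ids if gene_ids is not None else list(annotation.genes)
    out: dict[str, str] = {}
    for gid in ids:
        model = annotation[gid]
        if model.chrom not in fasta:
            raise MissingRecordError(f"chromosome {model.chrom!r} absent from FASTA")
        chrom_len = len(fasta[model.chrom])
        if model.strand == "-":
            lo = model.end + 1
            hi = min(model.end + upstream, chrom_len)
            seq = str(fasta[model.chrom][lo - 1:hi]) if lo <= hi else ""
            out[gid] = revcomp(seq)
        else:
            lo = max(1, model.start - upstream)
            hi = model.start - 1
            out[gid] = str(fasta[model.chrom][lo - 1:hi]) if lo <= hi else ""
    return out


def scan_cres(
    promoter: str,
    motifs: list[CREMotif],
    gene_id: str = "",
    both_strands: bool = True,
) -> list[CREMatch]:
    """All (overlapping) IUPAC matches of each motif in one promoter.

    Forward-strand matches are reported at their 0-based offset.  Reverse
    hits are found by scanning the reverse complement of the pattern on the
    forward sequence, so the reported offset is the leftmost forward-strand
    position of the site.  A palindromic site therefore appears twice, once
    per strand.
    """
    seq = promoter.upper()
    matches: list[CREMatch] = []
    for motif in motifs:
        fwd = re.compile(f"(?=({iupac_to_regex(motif.pattern)}))")
        for m in fwd.finditer(seq):
            matches.append(CREMatch(gene_id, motif.element_name, motif.category, m.start(), "+"))
        if both_strands:
            rev = re.compile(f"(?=({iupac_to_regex(revcomp(motif.pattern))}))")
            for m in rev.finditer(seq):
                matches.append(CREMatch(gene_id, motif.element_name, motif.category, m.start(), "-"))
    matches.sort(key=lambda c: (c.element_name, c.promoter_offset, c.strand))
    return matches


def scan_all(
    promoters: dict[str, str], motifs: list[CREMotif], both_strands: bool = True
) -> list[CREMatch]:
    out = []
    for gid, seq in promoters.items():
        out.extend(scan_cres(seq, motifs, gene_id=gid, both_strands=both_strands))
    return out


def categorize_cres(
    matches: list[CREMatch], category_map: dict[str, str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene category counts and a family-level summary.

    ``category_map`` overrides each element's category; elements mapping to
    anything outside the three configured categories are flagged "other" and
    excluded from the three-way totals.  The per-gene table counts
    occurrences; the family summary reports, per category, both the
    occurrence total and the number of distinct element types, with
    percentage shares of distinct types rounded to 1 decimal.
    """
    records = []
    for m in matches:
        cat = category_map.get(m.element_name, m.category) if category_map else m.category
        if cat not in CATEGORIES:
            cat = "other"
        records.append((m.gene_id, m.element_name, cat))
    df = pd.DataFrame(records, columns=["gene_id", "element_name", "category"])

    genes = sorted({m.gene_id for m in matches})
    per_gene = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    for cat in CATEGORIES:
        sub = df[df.category == cat].groupby("gene_id").size()
        per_gene[f"{cat}_count"] = sub.reindex(genes, fill_value=0).astype(int)
    per_gene["total"] = per_gene.sum(axis=1)
    per_gene = per_gene.reset_index()

    in_play = df[df.category.isin(CATEGORIES)]
    distinct = in_play.groupby("category")["element_name"].nunique()
    occurrences = in_play.groupby("category").size()
    n_distinct_total = int(distinct.sum()) if len(distinct) else 0
    rows = []
    for cat in CATEGORIES:
        d = int(distinct.get(cat, 0))
        rows.append({
            "category": cat,
            "distinct_elements": d,
            "occurrences": int(occurrences.get(cat, 0)),
            "share_pct": percent_share(d, n_distinct_total, ndigits=1)
            if n_distinct_total else 0.0,
        })
    summary = pd.DataFrame(rows)
    return per_gene, summary


def category_shares(tallies: dict[str, int], ndigits: int = 1) -> dict[str, float]:
    """Percentage shares of per-category element tallies (1-decimal default)."""
    total = sum(tallies.values())
    if total <= 0:
        raise ParameterError("tallies must sum to a positive total")
    return {cat: percent_share(n, total, ndigits=ndigits) for cat, n in tallies.items()}


def write_matches(matches: list[CREMatch], motifs: list[CREMotif], path: str | Path) -> None:
    """BED-like TSV: gene, offset, end, element, strand, category."""
    lengths = {m.element_name: len(m.pattern) for m in motifs}
    with open(path, "w") as fh:
        fh.write("gene_id\toffset\tend\telement_name\tstrand\tcategory\n")
        for m in matches:
            end = m.promoter_offset + lengths.get(m.element_name, 0)
            fh.write(
                f"{m.gene_id}\t{m.promoter_offset}\t{end}\t{m.element_name}\t"
                f"{m.strand}\t{m.category}\n"
            )
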