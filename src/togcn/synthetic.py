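"""Deterministic synthetic inputs with planted, recoverable ground truth.

Every file the pipeline consumes can be generated here: a TPM-like
expression matrix over the six NaCl treatments with planted co-expression
modules, bait genes, pattern-class members and low-expression genes; a toy
multi-chromosome genome with strand-mixed gene models and motifs planted at
known promoter offsets; and BLAST/HMMER hit tables with a known surviving
intersection.  Each generator draws from a single seeded RNG stream, so a
seed reproduces byte-identical outputs.

Expression profiles are treatment-level archetypes (monotone down/up,
interior peak, interior trough, late peak) scaled per gene with lognormal
multiplicative noise, which makes the within-module correlation, bait and
pattern-class answer keys exact by construction.  Background genes are
flat-base + jitter profiles, rejection-sampled to stay below |PCC| 0.7
against every archetype and never to peak at T0, so they cannot collide
with planted edges or baits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .expression import TREATMENTS, ExpressionMatrix
from .promoter import CREMotif, load_motif_table
from .utils import IUPAC_CODES, revcomp, validate_iupac

#: Treatment-level archetype profiles (T0..T150).  Pairwise positive PCC of
#: any two distinct archetypes stays below 0.7, so cross-module edges cannot
#: arise at a 0.9 cutoff.
ARCHETYPES: dict[str, list[float]] = {
    "down": [10.0, 7.0, 5.0, 3.5, 2.0, 1.0],       # bait module, continuous_down
    "up": [1.0, 2.0, 4.0, 6.0, 8.0, 10.0],          # continuous_up
    "peak_mid": [1.0, 4.0, 10.0, 8.0, 3.0, 1.0],    # biphasic
    "trough_mid": [9.0, 4.0, 1.0, 3.0, 7.0, 10.0],  # reverse_biphasic
    "peak_late": [1.0, 2.0, 4.0, 7.0, 10.0, 3.0],   # biphasic (late peak)
}

ARCHETYPE_LABELS = {
    "down": "continuous_down",
    "up": "continuous_up",
    "peak_mid": "biphasic",
    "trough_mid": "reverse_biphasic",
    "peak_late": "biphasic",
}

_GENE_BODY_LEN = 300
_INTERGENIC_GAP = 4500  # > 2 * upstream so promoter windows never collide
_TRUNCATION_START = 501  # first gene per chromosome: promoter truncated to 500 bp


@dataclass
class SyntheticTruth:
    """Answer key for everything a generator planted."""

    seed: int
    module_assignments: dict[str, int] = field(default_factory=dict)
    bait_ids: set[str] = field(default_factory=set)
    pattern_labels: dict[str, str] = field(default_factory=dict)
    planted_motif_positions: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    low_expression_ids: set[str] = field(default_factory=set)
    tf_ids: set[str] = field(default_factory=set)
    family_ids: set[str] = field(default_factory=set)

    def planted_edges(self) -> set[frozenset]:
        """All within-module TF / non-TF pairs, the expected edge set."""
        by_module: dict[int, list[str]] = {}
        for g, m in self.module_assignments.items():
            by_module.setdefault(m, []).append(g)
        edges = set()
        for members in by_module.values():
            tfs = [g for g in members if g in self.tf_ids]
            others = [g for g in members if g not in self.tf_ids]
            for t in tfs:
                for o in others:
                    edges.add(frozenset((t, o)))
        return edges

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["bait_ids"] = sorted(self.bait_ids)
        payload["low_expression_ids"] = sorted(self.low_expression_ids)
        payload["tf_ids"] = sorted(self.tf_ids)
        payload["family_ids"] = sorted(self.family_ids)
        payload["planted_motif_positions"] = {
            g: [list(t) for t in v] for g, v in self.planted_motif_positions.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            seed=raw["seed"],
            module_assignments={k: int(v) for k, v in raw["module_assignments"].items()},
            bait_ids=set(raw["bait_ids"]),
            pattern_labels=dict(raw["pattern_labels"]),
            planted_motif_positions={
                g: [(e, int(o), s) for e, o, s in v]
                for g, v in raw["planted_motif_positions"].items()
            },
            low_expression_ids=set(raw["low_expression_ids"]),
            tf_ids=set(raw["tf_ids"]),
            family_ids=set(raw["family_ids"]),
        )


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def generate_expression(
    n_genes: int = 500,
    n_tf: int = 30,
    n_modules: int = 5,
    reps: int = 3,
    noise_sd: float = 0.1,
    seed: int = 42,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """TPM-like matrix over 6 treatments with planted co-expression modules.

    Each module shares one archetype profile; member values are
    ``scale_g * archetype[treatment] * exp(N(0, noise_sd))``, so noiseless
    within-module pairs have PCC exactly 1 and realized pairs stay above
    0.9 at the default noise level.  ~10% of genes are planted as
    low-expression (TPM < 1 everywhere); the remainder are background.
    """
    if n_genes <= 0 or n_tf <= 0 or n_modules <= 0 or reps < 1:
        raise ParameterError("counts must be positive and reps >= 1")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be nonnegative")
    if n_tf >= n_genes:
        raise ParameterError("n_tf must be smaller than n_genes")
    if n_modules > len(ARCHETYPES):
        raise ParameterError(f"at most {len(ARCHETYPES)} modules supported")

    n_low = max(1, round(0.1 * n_genes))
    available = n_genes - n_tf - n_low
    per_module_nontf = min(20, available // n_modules)
    if per_module_nontf < 3 or n_tf < n_modules:
        raise ParameterError(
            "n_genes too small: each module needs >= 1 TF and >= 3 non-TF genes"
        )
    n_background = n_genes - n_tf - n_low - per_module_nontf * n_modules

    rng = np.random.default_rng(seed)
    arch_names = list(ARCHETYPES)[:n_modules]
    arch = np.array([ARCHETYPES[a] for a in arch_names])

    gene_ids = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    truth = SyntheticTruth(seed=seed)

    # gene roles, in id order: TFs, module non-TFs, low-expression, background
    cursor = 0
    tf_genes = gene_ids[cursor:cursor + n_tf]; cursor += n_tf
    module_nontf = gene_ids[cursor:cursor + per_module_nontf * n_modules]
    cursor += per_module_nontf * n_modules
    low_genes = gene_ids[cursor:cursor + n_low]; cursor += n_low
    background = gene_ids[cursor:]

    truth.tf_ids = set(tf_genes)
    truth.low_expression_ids = set(low_genes)
    for i, g in enumerate(tf_genes):
        truth.module_assignments[g] = i % n_modules
    for i, g in enumerate(module_nontf):
        truth.module_assignments[g] = i // per_module_nontf
    for g, m in truth.module_assignments.items():
        truth.pattern_labels[g] = ARCHETYPE_LABELS[arch_names[m]]
    truth.bait_ids = {g for g, m in truth.module_assignments.items()
                      if arch_names[m] == "down"}

    n_samples = len(TREATMENTS) * reps
    sample_ids = [f"{t}_r{j}" for t in TREATMENTS for j in range(1, reps + 1)]
    treat_idx = np.repeat(np.arange(len(TREATMENTS)), reps)

    values = np.empty((n_genes, n_samples))
    pos = {g: i for i, g in enumerate(gene_ids)}

    for g in tf_genes + module_nontf:
        base = arch[truth.module_assignments[g]]
        scale = rng.lognormal(mean=2.0, sigma=0.5)
        noise = rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0 else 0.0
        values[pos[g]] = scale * base[treat_idx] * np.exp(noise)

    for g in low_genes:
        values[pos[g]] = rng.uniform(0.01, 0.9, size=n_samples)

    centered_arch = arch - arch.mean(axis=1, keepdims=True)
    centered_arch /= np.linalg.norm(centered_arch, axis=1, keepdims=True)
    for g in background:
        base = _background_profile(rng, centered_arch)
        scale = rng.lognormal(mean=1.5, sigma=0.5)
        noise = rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0 else 0.0
        values[pos[g]] = scale * base[treat_idx] * np.exp(noise)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        sample_treatments={s: s.split("_")[0] for s in sample_ids},
    )
    return matrix, truth


def _background_profile(rng: np.random.Generator, centered_arch: np.ndarray) -> np.ndarray:
    """Flat-base + jitter treatment profile, decorrelated from all archetypes
    (|PCC| < 0.7) and never peaking at T0 (keeps the bait key exact)."""
    n_treat = centered_arch.shape[1]
    while True:
        base = 3.0 * np.exp(rng.normal(0.0, 0.3, size=n_treat))
        if int(base.argmax()) == 0:
            continue
        c = base - base.mean()
        norm = np.linalg.norm(c)
        if norm == 0:
            continue
        if np.abs(centered_arch @ (c / norm)).max() < 0.7:
            return base


# ---------------------------------------------------------------------------
# genome + promoters
# ---------------------------------------------------------------------------

def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    """Concrete base string drawn from an IUPAC pattern."""
    return "".join(
        b if len(allowed := IUPAC_CODES[b]) == 1 else allowed[rng.integers(len(allowed))]
        for b in validate_iupac(pattern)
    )


def _naive_motif_scan(seq: str, motifs: list[CREMotif]) -> list[tuple[str, int, str]]:
    """Brute-force per-position IUPAC matcher over both strands.

    Independent of the regex scanner in :mod:`togcn.promoter`; used both to
    scrub incidental background matches and to freeze the answer key.
    """
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    arr = np.fromiter((base_idx[b] for b in seq), dtype=np.int8, count=len(seq))
    hits = []
    for motif in motifs:
        m = len(motif.pattern)
        if m > len(seq):
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, m)
        for pattern, strand in ((motif.pattern, "+"), (revcomp(motif.pattern), "-")):
            mask = np.zeros((m, 4), dtype=bool)
            for j, ch in enumerate(pattern):
                for b in IUPAC_CODES[ch]:
                    mask[j, base_idx[b]] = True
            ok = mask[np.arange(m), windows].all(axis=1)
            hits.extend((motif.element_name, int(off), strand) for off in np.nonzero(ok)[0])
    hits.sort()
    return hits


def _plant_promoter(
    length: int, motifs: list[CREMotif], rng: np.random.Generator, n_plant: int
) -> tuple[str, list[tuple[str, int, str]]]:
    """Random promoter with motifs planted at non-overlapping offsets.

    Incidental matches arising from the random background are mutated away
    so the final match set derives from planted content only; the returned
    key is the full naive both-strand scan of the final sequence.
    """
    seq = list("ACGT"[rng.integers(4)] for _ in range(length))
    spans: list[tuple[int, int]] = []
    choices = rng.permutation(len(motifs))[:n_plant]
    for mi in choices:
        motif = motifs[int(mi)]
        m = len(motif.pattern)
        if m > length:
            continue
        for _attempt in range(100):
            off = int(rng.integers(0, length - m + 1))
            if all(off + m <= s or off >= e for s, e in spans):
                seq[off:off + m] = _instantiate(motif.pattern, rng)
                spans.append((off, off + m))
                break

    protected = set()
    for s, e in spans:
        protected.update(range(s, e))
    by_name = {mo.element_name: mo.pattern for mo in motifs}
    mutations: dict[int, int] = {}  # per-position budget; exhausted -> frozen
    for _round in range(1000):
        dirty = False
        for element, off, strand in _naive_motif_scan("".join(seq), motifs):
            pattern = by_name[element] if strand == "+" else revcomp(by_name[element])
            # break the match at an informative (non-N) background position,
            # substituting a base outside the pattern's allowed set
            candidates = sorted(
                (
                    (len(IUPAC_CODES[pattern[p - off]]), p)
                    for p in range(off, off + len(pattern))
                    if p not in protected
                    and len(IUPAC_CODES[pattern[p - off]]) < 4
                    and mutations.get(p, 0) < 4
                ),
            )
            if not candidates:
                # caused by planted content, or unbreakable at a boundary
                # position where every base completes some motif: the final
                # naive scan records it, so the answer key stays exact
                continue
            _, p = candidates[0]
            disallowed = [b for b in "ACGT" if b not in IUPAC_CODES[pattern[p - off]]]
            seq[p] = disallowed[int(rng.integers(len(disallowed)))]
            mutations[p] = mutations.get(p, 0) + 1
            dirty = True
        if not dirty:
            break
    else:  # pragma: no cover - generator invariant
        raise RuntimeError("incidental-match scrubbing did not converge")

    final = "".join(seq)
    return final, _naive_motif_scan(final, motifs)


def generate_genome(
    outdir: str | Path,
    n_chrom: int = 3,
    genes_per_chrom: int = 8,
    promoter_motifs: list[CREMotif] | None = None,
    seed: int = 42,
    upstream: int = 2000,
) -> tuple[Path, Path, SyntheticTruth]:
    """Toy genome FASTA + GFF3 with strand-mixed genes and planted CREs.

    Genes alternate strands with intergenic spacing well above the promoter
    length; the first gene of every chromosome sits < 2000 bp from the
    chromosome start to exercise promoter truncation.  Planted motif
    occurrences are recorded with exact promoter-relative offsets.
    """
    if n_chrom <= 0 or genes_per_chrom <= 0:
        raise ParameterError("n_chrom and genes_per_chrom must be positive")
    motifs = promoter_motifs if promoter_motifs is not None else load_motif_table()
    for m in motifs:
        validate_iupac(m.pattern)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)

    fasta_path = outdir / "genome.fa"
    gff_path = outdir / "genes.gff3"
    gff_lines = ["##gff-version 3"]
    bases = np.array(list("ACGT"))

    with open(fasta_path, "w") as fa:
        for c in range(1, n_chrom + 1):
            chrom = f"chr{c:02d}"
            starts, strands = [], []
            start = _TRUNCATION_START
            for i in range(genes_per_chrom):
                starts.append(start)
                strands.append("+" if i % 2 == 0 else "-")
                start += _GENE_BODY_LEN + _INTERGENIC_GAP
            chrom_len = starts[-1] + _GENE_BODY_LEN - 1 + upstream + 500

            seq = list(rng.choice(bases, size=chrom_len))
            for i, (gstart, strand) in enumerate(zip(starts, strands)):
                gid = f"G{c:02d}g{i + 1:03d}"
                gend = gstart + _GENE_BODY_LEN - 1
                if strand == "+":
                    lo = max(1, gstart - upstream)
                    plen = gstart - lo
                else:
                    lo = gend + 1
                    plen = min(gend + upstream, chrom_len) - gend
                n_plant = int(rng.integers(2, 5))
                prom, key = _plant_promoter(plen, motifs, rng, n_plant)
                truth.planted_motif_positions[gid] = key
                segment = prom if strand == "+" else revcomp(prom)
                seq[lo - 1:lo - 1 + plen] = list(segment)
                gff_lines.append(
                    f"{chrom}\tsynth\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\tID={gid}"
                )

            fa.write(f">{chrom}\n")
            joined = "".join(seq)
            for off in range(0, len(joined), 60):
                fa.write(joined[off:off + 60] + "\n")

    gff_path.write_text("\n".join(gff_lines) + "\n")
    return fasta_path, gff_path, truth


# ---------------------------------------------------------------------------
# homology hit tables
# ---------------------------------------------------------------------------

def generate_hit_tables(
    true_family_ids: set[str],
    decoy_ids: set[str],
    outdir: str | Path,
    seed: int = 42,
) -> tuple[Path, Path, SyntheticTruth]:
    """BLAST outfmt-6 + HMMER tabular fixtures around the 30%/1e-5 filters.

    Every true member appears in both tables with identity >= 30 (one row
    pinned at exactly 30.0 to exercise the inclusive boundary) and e-value
    <= 1e-5.  Decoys cycle through the failure modes: BLAST-only, HMM-only,
    identity 29.9, e-value above the cutoff.  The intended surviving set is
    recorded in the returned truth object.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    blast_path = outdir / "blast_hits.tsv"
    hmm_path = outdir / "hmm_hits.tbl"

    def blast_row(qid: str, pident: float, evalue: float) -> str:
        length = int(rng.integers(80, 300))
        sid = f"AT{int(rng.integers(1, 6))}G{int(rng.integers(1, 80000)):05d}"
        mismatch = int(round(length * (100 - pident) / 100))
        bitscore = round(float(rng.uniform(50, 400)), 1)
        return (
            f"{qid}\t{sid}\t{pident:.1f}\t{length}\t{mismatch}\t0\t1\t{length}"
            f"\t1\t{length}\t{evalue:.2e}\t{bitscore}"
        )

    def hmm_row(qid: str, evalue: float) -> str:
        score = round(float(rng.uniform(40, 200)), 1)
        return f"{qid} - TCP PF03634.22 {evalue:.1e} {score} 0.1"

    blast_lines, hmm_lines = [], []
    hmm_lines.append("# target name  accession  query name  accession  E-value  score  bias")
    for i, qid in enumerate(sorted(true_family_ids)):
        pident = 30.0 if i == 0 else round(float(rng.uniform(30.0, 95.0)), 1)
        evalue = 1e-5 if i == 1 else 10.0 ** -float(rng.uniform(6, 40))
        blast_lines.append(blast_row(qid, pident, evalue))
        hmm_lines.append(hmm_row(qid, 10.0 ** -float(rng.uniform(6, 40))))

    for i, qid in enumerate(sorted(decoy_ids)):
        mode = i % 4
        if mode == 0:  # BLAST only, passes filters, but no domain evidence
            blast_lines.append(blast_row(qid, round(float(rng.uniform(35, 90)), 1), 1e-10))
        elif mode == 1:  # HMM only
            hmm_lines.append(hmm_row(qid, 1e-12))
        elif mode == 2:  # both tables, identity below 30
            blast_lines.append(blast_row(qid, 29.9, 1e-10))
            hmm_lines.append(hmm_row(qid, 1e-12))
        else:  # both tables, BLAST e-value fails
            blast_lines.append(blast_row(qid, 55.0, 1e-3))
            hmm_lines.append(hmm_row(qid, 1e-12))

    blast_path.write_text("\n".join(blast_lines) + "\n")
    hmm_path.write_text("\n".join(hmm_lines) + "\n")
    truth = SyntheticTruth(seed=seed, family_ids=set(true_family_ids))
    return blast_path, hmm_path, truth
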