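"""In-silico tryptic digestion and junction identifiability analysis.

Answers, independently of any actual spectra, which splice junctions could
ever be observed as junction-straddling tryptic peptides in the 6-30 aa
length range most compatible with MS/MS sequencing, and supports the
per-gene averaging and expected-yield arithmetic built on top of that
screen.

Trypsin cleaves C-terminal to K or R, suppressed when the next residue is
proline (the usual search-engine default; the no-KP variant is available via
``kp_rule=False``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Iterable, Sequence

from .genome_io import SpliceJunction
from .junctiondb import TranslatedJunctionEntry

logger = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 6
DEFAULT_MAX_LEN = 30


@dataclass(frozen=True)
class Peptide:
    """A fully tryptic fragment with coordinates in its parent sequence."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("peptide interval inconsistent with sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneIdentifiabilityStats:
    gene_id: str
    n_junctions: int
    n_identifiable_mc0: int
    n_identifiable_mc1: int
    n_known_junctions: int
    n_novel_junctions: int


def cleavage_sites(sequence: str, kp_rule: bool = True) -> list[int]:
    """Positions after which trypsin cleaves (C-terminal to K/R, not before P)."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and not (kp_rule and sequence[i + 1] == "P")
    ]


def tryptic_digest(
    sequence: str, max_missed: int = 1, kp_rule: bool = True
) -> list[Peptide]:
    """All fully tryptic peptides with 0..``max_missed`` missed cleavages.

    The concatenation of the 0-missed-cleavage peptides reconstructs the
    parent sequence; every k-missed peptide is the concatenation of k+1
    adjacent 0-missed peptides.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if not sequence:
        raise ValueError("empty sequence")
    if "*" in sequence:
        raise ValueError("sequence contains a stop character")
    bounds = [0] + cleavage_sites(sequence, kp_rule) + [len(sequence)]
    peptides = []
    for i in range(len(bounds) - 1):
        for mc in range(max_missed + 1):
            k = i + 1 + mc
            if k >= len(bounds):
                break
            s, e = bounds[i], bounds[k]
            peptides.append(Peptide(sequence[s:e], s, e, mc))
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def junction_spanning_peptides(
    entry: TranslatedJunctionEntry, max_missed: int = 1, kp_rule: bool = True
) -> list[Peptide]:
    """Tryptic peptides of the entry with at least one residue on each side
    of the junction boundary (``start < boundary_aa < end``)."""
    b = entry.boundary_aa
    return [
        p
        for p in tryptic_digest(entry.aa_sequence, max_missed, kp_rule)
        if p.start < b < p.end
    ]


def is_identifiable(
    entries: Iterable[TranslatedJunctionEntry],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    max_missed: int = 1,
    kp_rule: bool = True,
) -> bool:
    """True iff any frame of the junction yields a junction-spanning tryptic
    peptide with ``min_len <= length <= max_len`` (bounds inclusive)."""
    return any(
        min_len <= len(p) <= max_len
        for entry in entries
        for p in junction_spanning_peptides(entry, max_missed, kp_rule)
    )


def group_entries_by_junction(
    entries: Iterable[TranslatedJunctionEntry],
) -> dict[str, list[TranslatedJunctionEntry]]:
    """Group database entries by every junction they derive from (entries
    deduplicated across junctions are attributed to each of them)."""
    grouped: dict[str, list[TranslatedJunctionEntry]] = {}
    for e in entries:
        for jid in e.all_junction_ids or (e.junction_id,):
            grouped.setdefault(jid, []).append(e)
    return grouped


def per_gene_stats(
    junctions: Sequence[SpliceJunction],
    entries: Iterable[TranslatedJunctionEntry],
    gene_ids: Iterable[str] | None = None,
    subset_genes: Iterable[str] | None = None,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    kp_rule: bool = True,
) -> tuple[list[GeneIdentifiabilityStats], dict]:
    """Per-gene junction counts and identifiability, plus global averages.

    Junctions must be classified (gene assignment available).  "Distinct
    junctions" are deduplicated by intron coordinates within a gene.  The
    summary reports unweighted means over genes (each gene counts once) of
    junctions per gene and identifiable junctions per gene, at 0 and at <=1
    missed cleavages, over all genes and over ``subset_genes`` (e.g. a
    mitochondrial gene list), together with the global identifiable
    fractions.  Genes without junctions contribute zero to numerators and
    one to denominators.
    """
    by_junction = group_entries_by_junction(entries)

    genes: dict[str, dict] = {}
    seen: set[tuple] = set()
    for j in junctions:
        gid = j.gene_id or "unassigned"
        key = (gid, j.chromosome, j.strand, j.start, j.end)
        if key in seen:
            continue
        seen.add(key)
        rec = genes.setdefault(gid, {"junctions": []})
        rec["junctions"].append(j)

    universe = sorted(set(gene_ids) | set(genes) if gene_ids else set(genes))
    stats: list[GeneIdentifiabilityStats] = []
    for gid in universe:
        js = genes.get(gid, {}).get("junctions", [])
        n_mc0 = n_mc1 = 0
        for j in js:
            ent = by_junction.get(j.junction_id, [])
            if is_identifiable(ent, min_len, max_len, 0, kp_rule):
                n_mc0 += 1
            if is_identifiable(ent, min_len, max_len, 1, kp_rule):
                n_mc1 += 1
        stats.append(
            GeneIdentifiabilityStats(
                gene_id=gid,
                n_junctions=len(js),
                n_identifiable_mc0=n_mc0,
                n_identifiable_mc1=n_mc1,
                n_known_junctions=sum(1 for j in js if j.status == "known"),
                n_novel_junctions=sum(1 for j in js if j.status == "novel"),
            )
        )

    def _summarize(rows: list[GeneIdentifiabilityStats]) -> dict:
        n_genes = len(rows)
        if n_genes == 0:
            logger.warning("empty gene set; averages reported as 0")
            return {
                "n_genes": 0,
                "mean_junctions_per_gene": 0.0,
                "mean_identifiable_per_gene_mc0": 0.0,
                "mean_identifiable_per_gene_mc1": 0.0,
                "identifiable_fraction_mc0": 0.0,
                "identifiable_fraction_mc1": 0.0,
            }
        total_j = sum(r.n_junctions for r in rows)
        total0 = sum(r.n_identifiable_mc0 for r in rows)
        total1 = sum(r.n_identifiable_mc1 for r in rows)
        return {
            "n_genes": n_genes,
            "mean_junctions_per_gene": total_j / n_genes,
            "mean_identifiable_per_gene_mc0": total0 / n_genes,
            "mean_identifiable_per_gene_mc1": total1 / n_genes,
            "identifiable_fraction_mc0": total0 / total_j if total_j else 0.0,
            "identifiable_fraction_mc1": total1 / total_j if total_j else 0.0,
        }

    summary = {"all": _summarize(stats)}
    if subset_genes is not None:
        subset = set(subset_genes)
        summary["subset"] = _summarize([r for r in stats if r.gene_id in subset])
    return stats, summary


def expected_yield(
    n_genes: float,
    junctions_per_gene: float,
    class_fraction: float,
    identifiable_fraction: float,
) -> float:
    """Back-of-the-envelope expected number of identifiable junction peptides.

    The product ``n_genes x junctions/gene x class fraction x identifiable
    fraction``: e.g. 700 genes detected per tissue, ~5 junctions per gene,
    ~20% of junctions novel and ~5% identifiable gives ~35 expected novel
    junction peptides per tissue.
    """
    for v in (n_genes, junctions_per_gene, class_fraction, identifiable_fraction):
        if v < 0:
            raise ValueError("arguments must be non-negative")
    for frac in (class_fraction, identifiable_fraction):
        if frac > 1:
            raise ValueError("fractions must be <= 1")
    return n_genes * junctions_per_gene * class_fraction * identifiable_fraction


def rescale_yield_by_class(
    base_yield: float, from_fraction: float, to_fraction: float
) -> float:
    """Rescale an expected yield from one junction class to another, holding
    everything else fixed (e.g. ~50 expected novel peptides at a 20% novel
    share rescales to ~200 for the 80% known share)."""
    if from_fraction <= 0:
        raise ValueError("from_fraction must be positive")
    return base_yield * to_fraction / from_fraction
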