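"""Readers and validators for the genomic inputs of the pipeline.

Handles the genome FASTA, gene models (GTF/GFF3 or BED12) and RNA-Seq
splice-junction lists, and classifies junctions as *known* (exactly matching
an annotated intron) or *novel*.

Coordinate conventions
----------------------
All intervals are 0-based half-open (BED semantics).  GTF input (1-based,
inclusive) is converted on read.  A splice junction is represented by its
*intron* interval: ``start`` is the first intronic base, ``end`` the first
base of the downstream exon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_NT = set("ACGTN")

Interval = tuple[int, int]


@dataclass
class Genome:
    """Chromosome name -> uppercase nucleotide sequence over {A,C,G,T,N}."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r}")
            bad = set(seq) - _VALID_NT
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid characters {sorted(bad)!r}"
                )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return genome[chrom][start:end), erroring on out-of-bounds access."""
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq) or end < start:
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for {chrom} "
                f"(length {len(seq)})"
            )
        return seq[start:end]


@dataclass
class GeneModel:
    """A gene with merged exon intervals and the pooled annotated introns.

    ``exons`` are the union of all transcripts' exons, merged to a sorted,
    non-overlapping list.  ``introns`` pools the distinct intron intervals
    derived per transcript (gap between consecutive exons), which is what
    junction classification matches against.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: list[Interval]
    introns: list[Interval] = field(default_factory=list)
    transcripts: dict[str, list[Interval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")
        for (s, e) in self.exons:
            if e <= s:
                raise ValueError(f"degenerate exon [{s},{e}) in {self.gene_id}")
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if c < b:
                raise ValueError(f"overlapping/unsorted exons in {self.gene_id}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def exon_containing(self, pos: int) -> Interval | None:
        for (s, e) in self.exons:
            if s <= pos < e:
                return (s, e)
        return None


@dataclass(frozen=True)
class SpliceJunction:
    """An intron interval on a chromosome with read support and status."""

    junction_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    read_count: int
    status: str = "unclassified"  # known | novel | unclassified
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(
                f"junction {self.junction_id}: intron length must be >= 1"
            )
        if self.read_count < 0:
            raise ValueError(f"junction {self.junction_id}: negative read count")

    @property
    def intron(self) -> Interval:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genome_fasta(path: str | Path) -> Genome:
    """Read a genome FASTA into a :class:`Genome`.

    Sequences are uppercased and U is mapped to T.  Duplicate record names
    and empty files are hard errors.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate FASTA record name {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(sequences)


def _merge_intervals(intervals: list[Interval]) -> list[Interval]:
    merged: list[Interval] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _introns_of(exons: list[Interval]) -> list[Interval]:
    return [(a_end, b_start) for (_, a_end), (b_start, _) in zip(exons, exons[1:])]


def _assemble_gene_models(
    per_tx: dict[str, list[Interval]],
    tx_meta: dict[str, tuple[str, str, str]],
    genome: Genome | None,
) -> list[GeneModel]:
    """Pool transcript exon lists into per-gene models, deriving introns."""
    genes: dict[str, dict] = {}
    for tx_id, exons in per_tx.items():
        gene_id, chrom, strand = tx_meta[tx_id]
        if exons != sorted(exons):
            logger.warning("exons of transcript %s were unsorted; sorting", tx_id)
            exons = sorted(exons)
        rec = genes.setdefault(
            gene_id,
            {"chrom": chrom, "strand": strand, "exons": [], "introns": set(),
             "transcripts": {}},
        )
        if rec["chrom"] != chrom or rec["strand"] != strand:
            raise ValueError(f"gene {gene_id} spans chromosomes/strands")
        rec["exons"].extend(exons)
        rec["introns"].update(_introns_of(exons))
        rec["transcripts"][tx_id] = exons

    models = []
    for gene_id in sorted(genes):
        rec = genes[gene_id]
        exons = _merge_intervals(rec["exons"])
        if genome is not None:
            if rec["chrom"] not in genome:
                raise ValueError(
                    f"gene {gene_id} on chromosome {rec['chrom']!r} absent from genome"
                )
            if exons[-1][1] > genome.length(rec["chrom"]):
                raise ValueError(
                    f"gene {gene_id} exon exceeds chromosome {rec['chrom']} bounds"
                )
        models.append(
            GeneModel(
                gene_id=gene_id,
                chromosome=rec["chrom"],
                strand=rec["strand"],
                exons=exons,
                introns=sorted(rec["introns"]),
                transcripts=rec["transcripts"],
            )
        )
    return models


def _read_gene_models_gtf(path: str | Path, genome: Genome | None) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_tx: dict[str, list[Interval]] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}
    for ex in db.features_of_type("exon"):
        attrs = ex.attributes
        if "transcript_id" in attrs:
            tx_id = attrs["transcript_id"][0]
        elif "Parent" in attrs:  # GFF3 dialect
            tx_id = attrs["Parent"][0]
        else:
            raise ValueError(f"exon feature without transcript_id/Parent in {path}")
        gene_id = attrs["gene_id"][0] if "gene_id" in attrs else tx_id
        # gffutils keeps GTF/GFF 1-based inclusive coordinates
        per_tx.setdefault(tx_id, []).append((ex.start - 1, ex.end))
        tx_meta[tx_id] = (gene_id, ex.seqid, ex.strand)
    if not per_tx:
        raise ValueError(f"no exon features found in {path}")
    return _assemble_gene_models(per_tx, tx_meta, genome)


def _read_gene_models_bed12(path: str | Path, genome: Genome | None) -> list[GeneModel]:
    per_tx: dict[str, list[Interval]] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"BED12 line with {len(f)} fields in {path}")
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [
                (chrom_start + off, chrom_start + off + size)
                for off, size in zip(starts, sizes)
            ]
            per_tx.setdefault(name, []).extend(exons)
            # gene id: strip a transcript suffix like ".t1" when present
            gene_id = name.rsplit(".", 1)[0] if "." in name else name
            tx_meta[name] = (gene_id, chrom, strand)
    if not per_tx:
        raise ValueError(f"no records found in {path}")
    return _assemble_gene_models(per_tx, tx_meta, genome)


def read_gene_models(
    path: str | Path, format: str = "gtf", genome: Genome | None = None
) -> list[GeneModel]:
    """Read gene models from GTF/GFF3 (``format='gtf'``) or BED12.

    Exon intervals are converted to 0-based half-open coordinates; introns
    are derived per transcript and pooled per gene.  When a ``genome`` is
    supplied, exons outside its chromosome bounds are a hard error.
    """
    if format == "gtf":
        return _read_gene_models_gtf(path, genome)
    if format == "bed12":
        return _read_gene_models_bed12(path, genome)
    raise ValueError(f"unsupported gene model format {format!r}")


def write_gene_models_gtf(models: list[GeneModel], path: str | Path) -> None:
    """Write gene models back to GTF (one exon line per transcript exon)."""
    with open(path, "w") as fh:
        for m in models:
            transcripts = m.transcripts or {f"{m.gene_id}.t1": m.exons}
            for tx_id in sorted(transcripts):
                for (s, e) in transcripts[tx_id]:
                    attrs = f'gene_id "{m.gene_id}"; transcript_id "{tx_id}";'
                    fh.write(
                        f"{m.chromosome}\tjxpepdb\texon\t{s + 1}\t{e}\t.\t"
                        f"{m.strand}\t.\t{attrs}\n"
                    )


def read_junctions(path: str | Path) -> list[SpliceJunction]:
    """Read a BED6-style junction table (intron coordinates, score = reads).

    Records with non-positive intron length are rejected with a warning and
    zero-read records are dropped.  Unstranded records (strand ``.``) are
    duplicated onto both strands.  Duplicates (same chromosome, strand and
    intron) are merged with summed read counts.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    if df.empty:
        return []
    rows: list[SpliceJunction] = []
    for rec in df.itertuples(index=False):
        if rec.end <= rec.start:
            logger.warning(
                "junction %s: intron end <= start (%d <= %d); record rejected",
                rec.name, rec.end, rec.start,
            )
            continue
        count = int(rec.score)
        if count < 1:
            logger.info("junction %s: zero read count; dropped", rec.name)
            continue
        strands = [rec.strand]
        if rec.strand == ".":
            logger.warning(
                "junction %s is unstranded; duplicating onto both strands", rec.name
            )
            strands = ["+", "-"]
        for strand in strands:
            rows.append(
                SpliceJunction(
                    junction_id=str(rec.name),
                    chromosome=str(rec.chrom),
                    strand=strand,
                    start=int(rec.start),
                    end=int(rec.end),
                    read_count=count,
                )
            )
    return merge_junctions(rows)


def merge_junctions(junctions: list[SpliceJunction]) -> list[SpliceJunction]:
    """Merge junctions sharing (chromosome, strand, intron), summing reads."""
    merged: dict[tuple, SpliceJunction] = {}
    for j in junctions:
        key = (j.chromosome, j.strand, j.start, j.end)
        if key in merged:
            prev = merged[key]
            merged[key] = replace(prev, read_count=prev.read_count + j.read_count)
        else:
            merged[key] = j
    return [merged[k] for k in sorted(merged)]


def write_junctions_bed(junctions: list[SpliceJunction], path: str | Path) -> None:
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(
                f"{j.chromosome}\t{j.start}\t{j.end}\t{j.junction_id}\t"
                f"{j.read_count}\t{j.strand}\n"
            )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _assign_gene(j: SpliceJunction, candidates: list[GeneModel]) -> str | None:
    """Pick the gene whose exons flank the intron on both sides, else the
    nearest containing gene."""
    flanked, containing = [], []
    for g in candidates:
        if not (g.start <= j.start and j.end <= g.end):
            continue
        up_ok = any(e == j.start for (_, e) in g.exons) or g.exon_containing(
            j.start - 1
        )
        down_ok = any(s == j.end for (s, _) in g.exons) or g.exon_containing(j.end)
        if up_ok and down_ok:
            flanked.append(g)
        else:
            containing.append(g)
    pool = flanked or containing
    if not pool:
        return None
    # deterministic tie-break: tightest span, then gene id
    pool.sort(key=lambda g: (g.end - g.start, g.gene_id))
    return pool[0].gene_id


def classify_junction(
    j: SpliceJunction, models: list[GeneModel]
) -> SpliceJunction:
    """Classify one junction as known/novel and assign a gene.

    A junction is *known* iff its intron interval exactly matches an
    annotated intron of a gene model on the same chromosome and strand;
    everything else is *novel*.  Junctions on chromosomes absent from the
    models are novel with gene assignment ``None`` ("unassigned").
    """
    same = [
        m for m in models if m.chromosome == j.chromosome and m.strand == j.strand
    ]
    exact = sorted(
        m.gene_id for m in same if (j.start, j.end) in set(m.introns)
    )
    if exact:
        return replace(j, status="known", gene_id=exact[0])
    return replace(j, status="novel", gene_id=_assign_gene(j, same))


def classify_junctions(
    junctions: list[SpliceJunction], models: list[GeneModel]
) -> list[SpliceJunction]:
    """Vectorized-courtesy wrapper around :func:`classify_junction`."""
    intron_index: dict[tuple, list[GeneModel]] = {}
    by_loc: dict[tuple[str, str], list[GeneModel]] = {}
    for m in models:
        by_loc.setdefault((m.chromosome, m.strand), []).append(m)
        for intron in m.introns:
            intron_index.setdefault((m.chromosome, m.strand) + intron, []).append(m)

    out = []
    for j in junctions:
        hit = intron_index.get((j.chromosome, j.strand, j.start, j.end))
        if hit:
            gene = sorted(m.gene_id for m in hit)[0]
            out.append(replace(j, status="known", gene_id=gene))
        else:
            candidates = by_loc.get((j.chromosome, j.strand), [])
            out.append(
                replace(j, status="novel", gene_id=_assign_gene(j, candidates))
            )
    return out
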