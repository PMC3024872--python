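"""Translated junction-peptide database construction.

For each splice junction, a spliced nucleotide window is extracted (a fixed
flank from the upstream exon joined to a fixed flank from the downstream
exon, intron removed), translated in all six reading frames, and maximal
stop-free segments (ORFs, no initiator-methionine requirement) that span the
exon-exon boundary and reach a minimum length are emitted as database
entries.  The default flank of 75 nt per side corresponds to 25 amino acids
from each of the two joined exons, and the default minimum ORF length is
30 aa, the shortest fragment considered reliable for MS/MS database search.

Boundary bookkeeping: the residue whose codon uses any nucleotide from the
downstream flank is the boundary residue (``boundary_aa``); an entry spans
its junction iff ``0 < boundary_aa < len(entry)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .genome_io import Genome, GeneModel, SpliceJunction, classify_junctions

logger = logging.getLogger(__name__)

FRAMES = ("+0", "+1", "+2", "-0", "-1", "-2")

DEFAULT_FLANK_NT = 75   # 25 aa per side
DEFAULT_MIN_ORF_LEN = 30


@dataclass(frozen=True)
class JunctionWindow:
    """Spliced nucleotide window around one junction, 5'->3' in transcript
    orientation."""

    junction_id: str
    nt_sequence: str
    boundary_nt: int  # offset of the first nt contributed by the downstream exon
    flank_nt: int

    def __post_init__(self) -> None:
        n = len(self.nt_sequence)
        if not (1 <= self.boundary_nt <= n):
            raise ValueError(f"boundary_nt {self.boundary_nt} outside window")
        if n > 2 * self.flank_nt:
            raise ValueError("window longer than twice the flank length")


@dataclass
class TranslatedJunctionEntry:
    """One junction-spanning amino-acid ORF from one reading frame."""

    entry_id: str
    junction_id: str
    frame: str
    aa_sequence: str
    boundary_aa: int
    source_status: str  # known | novel
    all_junction_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if "*" in self.aa_sequence:
            raise ValueError(f"entry {self.entry_id} contains a stop character")
        if not (0 < self.boundary_aa < len(self.aa_sequence)):
            raise ValueError(f"entry {self.entry_id} does not span its junction")
        if not self.all_junction_ids:
            self.all_junction_ids = (self.junction_id,)


@dataclass
class BuildStats:
    n_junctions: int = 0
    n_missing_chromosome: int = 0
    n_windows: int = 0
    n_filtered_flank: int = 0
    n_orfs: int = 0
    n_entries: int = 0  # after deduplication


def extract_junction_window(
    j: SpliceJunction,
    genome: Genome,
    gene: GeneModel | None = None,
    flank_nt: int = DEFAULT_FLANK_NT,
    clip_to_exons: bool = True,
) -> JunctionWindow | None:
    """Extract the spliced window around a junction, or ``None`` if either
    flank is shorter than ``flank_nt``.

    Flanks are clipped at the boundaries of the assigned gene's flanking
    exons when a gene model is supplied (and ``clip_to_exons``), otherwise at
    chromosome bounds.  Minus-strand windows are reverse-complemented so the
    sequence reads 5'->3' in transcript orientation.
    """
    chrom_seq = genome[j.chromosome]
    up_lo, down_hi = 0, len(chrom_seq)
    if clip_to_exons and gene is not None:
        ex_up = gene.exon_containing(j.start - 1)
        if ex_up is not None:
            up_lo = ex_up[0]
        ex_down = gene.exon_containing(j.end)
        if ex_down is not None:
            down_hi = ex_down[1]

    up_start = j.start - flank_nt
    down_end = j.end + flank_nt
    if up_start < up_lo or down_end > down_hi:
        logger.info(
            "junction %s filtered: flank shorter than %d nt", j.junction_id, flank_nt
        )
        return None

    window = chrom_seq[up_start:j.start] + chrom_seq[j.end:down_end]
    if j.strand == "-":
        window = str(Seq(window).reverse_complement())
    # with both flanks complete, the downstream-exon contribution starts at
    # flank_nt on either strand
    return JunctionWindow(j.junction_id, window, flank_nt, flank_nt)


def _ceil_div(a: int, b: int) -> int:
    return -((-a) // b)


def six_frame_translate(window: JunctionWindow) -> list[tuple[str, str, int]]:
    """Translate the window in all six frames.

    Returns ``(frame, aa_with_stops, boundary_aa)`` triples.  Stop codons are
    rendered ``*`` and codons containing N render ``X``.  ``boundary_aa`` is
    the index of the first residue whose codon overlaps the junction boundary
    or later, in that frame's reading sense (for reverse frames the boundary
    maps to ``len(window) - boundary_nt``).
    """
    nt = window.nt_sequence
    n = len(nt)
    rc = str(Seq(nt).reverse_complement())
    out: list[tuple[str, str, int]] = []
    for strand_label, seq, b in (("+", nt, window.boundary_nt),
                                 ("-", rc, n - window.boundary_nt)):
        for f in range(3):
            sub = seq[f:]
            sub = sub[: len(sub) - len(sub) % 3]
            aa = str(Seq(sub).translate()) if sub else ""
            boundary_aa = max(0, _ceil_div(b - f - 2, 3))
            out.append((f"{strand_label}{f}", aa, boundary_aa))
    return out


def extract_spanning_orfs(
    translations: list[tuple[str, str, int]],
    junction_id: str,
    source_status: str = "novel",
    min_orf_len: int = DEFAULT_MIN_ORF_LEN,
) -> list[TranslatedJunctionEntry]:
    """Extract junction-spanning, stop-free ORFs of at least ``min_orf_len``.

    ORFs are maximal stop-free segments (split at ``*``; no start-codon
    requirement).  A segment is kept iff it is long enough and contains
    residues on both sides of the boundary; segments whose boundary residue
    is an ambiguous ``X`` are discarded.
    """
    entries: list[TranslatedJunctionEntry] = []
    for frame, aa, boundary_aa in translations:
        start = 0
        for seg in aa.split("*"):
            end = start + len(seg)
            if len(seg) >= min_orf_len and start < boundary_aa < end:
                if seg[boundary_aa - start] == "X":
                    logger.info(
                        "junction %s frame %s: ambiguous boundary codon; "
                        "segment discarded", junction_id, frame,
                    )
                else:
                    entries.append(
                        TranslatedJunctionEntry(
                            entry_id=f"{junction_id}:{frame}:{start}",
                            junction_id=junction_id,
                            frame=frame,
                            aa_sequence=seg,
                            boundary_aa=boundary_aa - start,
                            source_status=source_status,
                        )
                    )
            start = end + 1
    return entries


def build_junction_database(
    junctions: list[SpliceJunction],
    genome: Genome,
    models: list[GeneModel],
    flank_nt: int = DEFAULT_FLANK_NT,
    min_orf_len: int = DEFAULT_MIN_ORF_LEN,
    clip_to_exons: bool = True,
) -> tuple[list[TranslatedJunctionEntry], BuildStats]:
    """Window -> 6-frame -> ORF extraction over all junctions, deduplicated.

    Unclassified junctions are first classified against the gene models.
    Entries are deduplicated on the exact amino-acid sequence; the first-seen
    entry keeps the provenance and all contributing junction ids are recorded
    in ``all_junction_ids``.
    """
    stats = BuildStats(n_junctions=len(junctions))
    gene_by_id = {m.gene_id: m for m in models}
    if any(j.status == "unclassified" for j in junctions):
        junctions = classify_junctions(junctions, models)

    by_seq: dict[str, TranslatedJunctionEntry] = {}
    for j in junctions:
        if j.chromosome not in genome:
            stats.n_missing_chromosome += 1
            logger.warning(
                "junction %s on chromosome %s absent from genome; skipped",
                j.junction_id, j.chromosome,
            )
            continue
        gene = gene_by_id.get(j.gene_id) if j.gene_id else None
        window = extract_junction_window(
            j, genome, gene, flank_nt=flank_nt, clip_to_exons=clip_to_exons
        )
        if window is None:
            stats.n_filtered_flank += 1
            continue
        stats.n_windows += 1
        status = "known" if j.status == "known" else "novel"
        orfs = extract_spanning_orfs(
            six_frame_translate(window), j.junction_id, status, min_orf_len
        )
        stats.n_orfs += len(orfs)
        for entry in orfs:
            kept = by_seq.get(entry.aa_sequence)
            if kept is None:
                by_seq[entry.aa_sequence] = entry
            elif entry.junction_id not in kept.all_junction_ids:
                kept.all_junction_ids = kept.all_junction_ids + (entry.junction_id,)

    entries = sorted(by_seq.values(), key=lambda e: e.entry_id)
    stats.n_entries = len(entries)
    logger.info(
        "junction database: %d junctions in, %d windows kept, %d ORFs, "
        "%d entries after deduplication",
        stats.n_junctions, stats.n_windows, stats.n_orfs, stats.n_entries,
    )
    return entries, stats


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def entry_header(e: TranslatedJunctionEntry) -> str:
    return f"JXN|{e.entry_id}|{e.junction_id}|frame={e.frame}|baa={e.boundary_aa}"


def write_database_fasta(
    entries: list[TranslatedJunctionEntry], path: str | Path
) -> None:
    """Write entries as protein FASTA with provenance-tagged headers.

    Header grammar: ``>JXN|<entry_id>|<junction_id>|frame=<f>|baa=<b>`` with
    a description carrying the source status and every contributing junction
    id.  Records are sorted by entry id; 60-column wrapping.
    """
    ids = [e.entry_id for e in entries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate entry_id in database")
    records = [
        SeqRecord(
            Seq(e.aa_sequence),
            id=entry_header(e),
            description=(
                f"status={e.source_status} jxns={','.join(e.all_junction_ids)}"
            ),
        )
        for e in sorted(entries, key=lambda e: e.entry_id)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_database_fasta(path: str | Path) -> list[TranslatedJunctionEntry]:
    """Parse a junction database FASTA written by :func:`write_database_fasta`."""
    entries: list[TranslatedJunctionEntry] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tag, entry_id, junction_id, frame_f, baa_f = rec.id.split("|")
        if tag != "JXN":
            raise ValueError(f"not a junction database record: {rec.id}")
        desc = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        entries.append(
            TranslatedJunctionEntry(
                entry_id=entry_id,
                junction_id=junction_id,
                frame=frame_f.split("=", 1)[1],
                aa_sequence=str(rec.seq),
                boundary_aa=int(baa_f.split("=", 1)[1]),
                source_status=desc.get("status", "novel"),
                all_junction_ids=tuple(
                    desc.get("jxns", junction_id).split(",")
                ),
            )
        )
    return entries
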