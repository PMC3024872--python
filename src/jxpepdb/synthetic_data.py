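"""Seeded synthetic-data generators with planted ground truth.

Produce every input the pipeline consumes — a toy genome with multi-exon
genes, splice junctions with read support, a reference proteome, PSM score
mixtures over a combined target+decoy database, and per-gene expression
coupled to MS detection — so that each pipeline stage can be tested against
a known answer without any external download.

Planted truths
--------------
* Junction status: known junctions are annotated introns; novel junctions
  are alternative-acceptor shifts of an annotated intron (the intron end is
  moved into the downstream exon), emitted at ``novel_junction_fraction``.
* Tryptic identifiability is engineered, not sampled: an *identifiable*
  junction gets exon flanks written as stop-free codons with K/R placed so
  that frame +0 yields a 14-residue junction-spanning tryptic peptide; a
  *non-identifiable* junction gets a 12-nt cassette on each side of the
  boundary containing stop codons in all six frames, so no spanning ORF of
  the default minimum length can exist.
* PSM correctness labels: correct PSMs draw scores from ``Beta(8, 1)``,
  incorrect ones from ``Beta(1, 8)``; incorrect matches split evenly between
  targets and decoys, and the share of incorrect matches landing on junction
  entries is calibrated analytically so the naive false-positive rate of the
  novel-candidate subset at the global FDR threshold hits ``subset_fp_rate``
  (default 0.38) in expectation.
* Expression: log-normal RPKM, logistic-in-log10-RPKM detection, and
  spectral counts log-linear in RPKM with noise calibrated on the detected
  subpopulation to hit ``target_abundance_correlation`` (default 0.53).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import beta as beta_dist

from .genome_io import (
    Genome,
    GeneModel,
    SpliceJunction,
    write_gene_models_gtf,
    write_junctions_bed,
)
from .junctiondb import TranslatedJunctionEntry, build_junction_database
from .insilico_digest import tryptic_digest, junction_spanning_peptides
from .search_postprocess import (
    ProteinDB,
    ProteinEntry,
    assemble_combined_db,
    write_protein_fasta,
)

logger = logging.getLogger(__name__)

# codons that encode neither K/R (no tryptic site), nor P (no cleavage
# suppression), nor a stop, on the frame they are written in
_SAFE_CODONS = (
    "GCT", "GCC", "GGT", "GGC", "CTG", "GTT", "GTG", "TTC", "TAC", "GAT",
    "GAC", "GAA", "CAA", "CAT", "ACC", "AGC", "TGG", "ATG", "ATC", "AAC",
)
# 12-mer containing a stop codon in every frame on both strands
_STOP_CASSETTE = "TTAATTAATTAA"

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort (defaults mirror the real
    mouse-tissue setting: ~80% of junctions known, ~5% identifiable by
    6-30 aa tryptic peptides, novel-subset FP rate ~0.38, RPKM/spectral-count
    correlation ~0.53)."""

    seed: int = 0
    # genome / gene models
    n_genes: int = 40
    n_chromosomes: int = 2
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_len: tuple[int, int] = (200, 320)
    intron_len: tuple[int, int] = (80, 200)
    intergenic_len: tuple[int, int] = (300, 600)
    # junctions
    flank_nt: int = 75
    novel_junction_fraction: float = 0.20
    target_identifiable_fraction: float = 0.05
    # reference proteome
    n_reference_proteins: int = 40
    reference_protein_len: tuple[int, int] = (120, 400)
    # PSMs
    n_psms: int = 10_000
    incorrect_psm_fraction: float = 0.30
    correct_novel_fraction: float = 0.02
    subset_fp_rate: float = 0.38
    correct_score_beta: tuple[float, float] = (8.0, 1.0)
    incorrect_score_beta: tuple[float, float] = (1.0, 8.0)
    psm_target_fdr: float = 0.02
    # expression
    n_expression_genes: int = 2_000
    zero_expression_fraction: float = 0.05
    log10_rpkm_mean: float = 1.0
    log10_rpkm_sd: float = 1.0
    detection_logistic: tuple[float, float] = (0.5, 0.4)  # midpoint, scale
    target_abundance_correlation: float = 0.53
    spectral_count_log10_intercept: float = 1.5
    total_mapped_reads: int = 10_000_000
    exon_model_length: tuple[int, int] = (1000, 3000)

    def __post_init__(self) -> None:
        for name in (
            "novel_junction_fraction", "target_identifiable_fraction",
            "incorrect_psm_fraction", "correct_novel_fraction",
            "subset_fp_rate", "zero_expression_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("exons_per_gene", "exon_len", "intron_len",
                     "intergenic_len", "reference_protein_len",
                     "exon_model_length"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid range {name}={lo, hi}")
        if self.exon_len[0] < 3:
            raise ValueError("exons shorter than 3 nt are infeasible")
        if self.flank_nt % 3 != 0 or self.flank_nt < 30:
            raise ValueError("flank_nt must be a multiple of 3 and >= 30")
        if not (-1.0 < self.target_abundance_correlation < 1.0) or \
                self.target_abundance_correlation == 0:
            raise ValueError("target_abundance_correlation must be in (0, 1)")


def _rng(cfg: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, salt]))


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# genome and gene models
# ---------------------------------------------------------------------------

def generate_genome_and_models(cfg: SimConfig) -> tuple[Genome, list[GeneModel]]:
    """Random multi-exon genes laid out on synthetic chromosomes, both
    strands represented, all coordinates valid."""
    rng = _rng(cfg, 1)
    cursors = {f"chr{c + 1}": 0 for c in range(cfg.n_chromosomes)}
    models: list[GeneModel] = []
    for gi in range(cfg.n_genes):
        chrom = f"chr{gi % cfg.n_chromosomes + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        pos = cursors[chrom] + int(
            rng.integers(cfg.intergenic_len[0], cfg.intergenic_len[1] + 1)
        )
        exons = []
        for k in range(n_ex):
            elen = int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1))
            exons.append((pos, pos + elen))
            pos += elen
            if k < n_ex - 1:
                pos += int(
                    rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1)
                )
        cursors[chrom] = pos
        gene_id = f"g{gi:04d}"
        models.append(
            GeneModel(
                gene_id=gene_id,
                chromosome=chrom,
                strand=strand,
                exons=exons,
                introns=[
                    (a_end, b_start)
                    for (_, a_end), (b_start, _) in zip(exons, exons[1:])
                ],
                transcripts={f"{gene_id}.t1": exons},
            )
        )
    tail = 200
    genome = Genome(
        {chrom: _random_nt(rng, cursors[chrom] + tail) for chrom in cursors}
    )
    return genome, models


# ---------------------------------------------------------------------------
# junctions with planted identifiability
# ---------------------------------------------------------------------------

def _design_window(rng: np.random.Generator, identifiable: bool,
                   flank_nt: int) -> str:
    """Design the spliced window (transcript orientation) for one junction."""
    if identifiable:
        n_side = flank_nt // 3
        codons = list(rng.choice(_SAFE_CODONS, size=2 * n_side))
        codons[n_side - 9] = "CGT"  # R: cleavage 9 residues before boundary
        codons[n_side + 5] = "AAG"  # K: 14-residue spanning tryptic peptide
        return "".join(codons)
    window = list(_random_nt(rng, 2 * flank_nt))
    c = len(_STOP_CASSETTE)
    window[flank_nt - c:flank_nt] = _STOP_CASSETTE
    window[flank_nt:flank_nt + c] = _STOP_CASSETTE
    return "".join(window)


def generate_junctions(
    cfg: SimConfig, models: list[GeneModel], genome: Genome
) -> tuple[list[SpliceJunction], pd.DataFrame, Genome]:
    """One junction per annotated intron slot: the annotated intron itself
    (known) or an alternative-acceptor shift into the downstream exon
    (novel, at ``novel_junction_fraction``).

    Exon flank sequences are rewritten to plant per-junction tryptic
    identifiability (see module docstring), so an updated :class:`Genome`
    is returned along with the junction list and the truth table.
    """
    rng = _rng(cfg, 2)
    flank = cfg.flank_nt
    max_shift = cfg.exon_len[0] - 2 * flank
    if max_shift < 6:
        raise ValueError(
            "exon_len too short to host novel-acceptor shifts and full flanks"
        )
    seqs = {c: bytearray(s, "ascii") for c, s in genome.sequences.items()}
    junctions: list[SpliceJunction] = []
    truth_rows = []
    counter = 0
    for m in models:
        for (s0, e0) in m.introns:
            novel = bool(rng.random() < cfg.novel_junction_fraction)
            if novel:
                delta = int(rng.integers(6, max_shift + 1))
                s, e = s0, e0 + delta
            else:
                s, e = s0, e0
            identifiable = bool(rng.random() < cfg.target_identifiable_fraction)
            window = _design_window(rng, identifiable, flank)
            region = window if m.strand == "+" else str(
                Seq(window).reverse_complement()
            )
            seqs[m.chromosome][s - flank:s] = region[:flank].encode("ascii")
            seqs[m.chromosome][e:e + flank] = region[flank:].encode("ascii")
            jid = f"jx{counter:05d}"
            counter += 1
            junctions.append(
                SpliceJunction(
                    junction_id=jid,
                    chromosome=m.chromosome,
                    strand=m.strand,
                    start=int(s),
                    end=int(e),
                    read_count=int(rng.geometric(0.3)),
                )
            )
            truth_rows.append(
                {
                    "junction_id": jid,
                    "gene_id": m.gene_id,
                    "chromosome": m.chromosome,
                    "strand": m.strand,
                    "start": int(s),
                    "end": int(e),
                    "status": "novel" if novel else "known",
                    "identifiable": identifiable,
                }
            )
    updated = Genome({c: bytes(b).decode("ascii") for c, b in seqs.items()})
    return junctions, pd.DataFrame(truth_rows), updated


# ---------------------------------------------------------------------------
# reference proteome
# ---------------------------------------------------------------------------

def generate_reference_proteins(cfg: SimConfig) -> ProteinDB:
    """Random reference proteome (uniform residue usage, so tryptic sites
    occur at the realistic ~1-in-10 rate)."""
    rng = _rng(cfg, 3)
    entries = []
    for i in range(cfg.n_reference_proteins):
        n = int(rng.integers(cfg.reference_protein_len[0],
                             cfg.reference_protein_len[1] + 1))
        seq = "".join(rng.choice(list(_AMINO_ACIDS), size=n))
        entries.append(ProteinEntry(f"SYNREF{i:05d}", seq, "reference"))
    return ProteinDB(entries)


# ---------------------------------------------------------------------------
# PSMs
# ---------------------------------------------------------------------------

def _eligible_peptides(sequence: str, min_len: int = 6, max_len: int = 30,
                       max_missed: int = 1) -> list[str]:
    return [
        p.sequence
        for p in tryptic_digest(sequence, max_missed)
        if min_len <= len(p) <= max_len
    ]


def _calibrate_psm_mixture(cfg: SimConfig, n_cor: int, n_cor_nov: int,
                           n_inc_tgt: int, n_inc_dec: int) -> tuple[float, float]:
    """Solve for the expected global score threshold at the target FDR and
    the junction share of incorrect matches that puts the novel subset's
    naive FP rate at ``subset_fp_rate``."""
    surv_cor = lambda t: beta_dist.sf(t, *cfg.correct_score_beta)
    surv_inc = lambda t: beta_dist.sf(t, *cfg.incorrect_score_beta)

    def fdr_at(t: float) -> float:
        d = n_inc_dec * surv_inc(t)
        n_t = n_cor * surv_cor(t) + n_inc_tgt * surv_inc(t)
        return d / max(n_t, 1e-9)

    if fdr_at(1e-6) <= cfg.psm_target_fdr:
        t_star = 1e-6  # mixture clean enough that everything passes
    else:
        t_star = brentq(lambda t: fdr_at(t) - cfg.psm_target_fdr, 1e-6, 1 - 1e-9)
    r = cfg.subset_fp_rate
    denom = n_inc_tgt * surv_inc(t_star)
    gamma = 1.0
    if denom > 0 and r < 1:
        gamma = (r / (1 - r)) * n_cor_nov * surv_cor(t_star) / denom
    if gamma > 1:
        logger.warning(
            "subset_fp_rate %.2f not reachable with current mixture; "
            "junction share clipped to 1", r,
        )
        gamma = 1.0
    return t_star, gamma


def generate_psms(
    cfg: SimConfig,
    combined_db: ProteinDB,
    junction_entries: list[TranslatedJunctionEntry] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a PSM table over the combined target+decoy database.

    Returns ``(psms, truth)`` where ``psms`` has the columns the PSM reader
    expects (spectrum_id, peptide, probability, proteins, quality) and
    ``truth`` carries the hidden correct/incorrect label per spectrum.

    Correct PSMs sample tryptic peptides (6-30 aa) from target entries,
    with a small fraction (``correct_novel_fraction``) drawn from
    junction-spanning peptides of junction entries; incorrect PSMs sample
    uniformly from targets and decoys (half each), with the junction share
    of incorrect matches calibrated so the novel subset's naive FP rate at
    the global threshold approximates ``subset_fp_rate``.
    """
    rng = _rng(cfg, 4)
    by_origin: dict[str, list[ProteinEntry]] = {}
    for e in combined_db.entries:
        by_origin.setdefault(combined_db.base_origin(e.accession), []).append(e)
    for need in ("reference", "decoy_reference"):
        if need not in by_origin:
            raise ValueError(f"combined database lacks {need} entries")

    n = cfg.n_psms
    n_inc = int(round(n * cfg.incorrect_psm_fraction))
    n_cor = n - n_inc
    n_cor_nov = int(round(n_cor * cfg.correct_novel_fraction))
    n_inc_dec = n_inc // 2
    n_inc_tgt = n_inc - n_inc_dec
    _, gamma = _calibrate_psm_mixture(cfg, n_cor, n_cor_nov, n_inc_tgt, n_inc_dec)

    # junction-spanning peptide pool for correct novel PSMs, excluding
    # peptides that also occur in the reference proteome
    ref_concat = "|".join(
        e.sequence for e in by_origin.get("reference", [])
    )
    novel_pool: list[tuple[str, str]] = []  # (accession, peptide)
    if junction_entries:
        acc_by_seq = {
            e.sequence: e.accession for e in by_origin.get("junction", [])
        }
        for je in junction_entries:
            acc = acc_by_seq.get(je.aa_sequence)
            if acc is None:
                continue
            for p in junction_spanning_peptides(je, max_missed=1):
                if 6 <= len(p) <= 30 and p.sequence not in ref_concat:
                    novel_pool.append((acc, p.sequence))
    if n_cor_nov and not novel_pool:
        logger.warning(
            "no junction-spanning peptides available; correct PSMs all known"
        )
        n_cor_nov = 0

    pep_cache: dict[str, list[str]] = {}

    def peptides_of(entry: ProteinEntry) -> list[str]:
        if entry.accession not in pep_cache:
            pep_cache[entry.accession] = _eligible_peptides(entry.sequence)
        return pep_cache[entry.accession]

    def sample_from(pool: list[ProteinEntry]) -> tuple[str, str]:
        for _ in range(200):
            entry = pool[int(rng.integers(len(pool)))]
            peps = peptides_of(entry)
            if peps:
                return entry.accession, peps[int(rng.integers(len(peps)))]
        raise RuntimeError("could not sample an eligible tryptic peptide")

    rows, truth = [], []

    def emit(accession: str, peptide: str, score: float, label: str) -> None:
        rows.append(
            {
                "peptide": peptide,
                "probability": min(1.0, max(0.0, float(score))),
                "proteins": accession,
                "quality": float(rng.normal(2.0, 0.5)),
            }
        )
        truth.append({"label": label})

    for _ in range(n_cor_nov):
        acc, pep = novel_pool[int(rng.integers(len(novel_pool)))]
        emit(acc, pep, rng.beta(*cfg.correct_score_beta), "correct")
    for _ in range(n_cor - n_cor_nov):
        acc, pep = sample_from(by_origin["reference"])
        emit(acc, pep, rng.beta(*cfg.correct_score_beta), "correct")
    for is_decoy_match in [True] * n_inc_dec + [False] * n_inc_tgt:
        junction_side = (
            rng.random() < gamma
            and ("decoy_junction" if is_decoy_match else "junction") in by_origin
        )
        if is_decoy_match:
            pool = by_origin["decoy_junction" if junction_side
                             else "decoy_reference"]
        else:
            pool = by_origin["junction" if junction_side else "reference"]
        acc, pep = sample_from(pool)
        emit(acc, pep, rng.beta(*cfg.incorrect_score_beta), "incorrect")

    order = rng.permutation(len(rows))
    psm_df = pd.DataFrame([rows[i] for i in order])
    truth_df = pd.DataFrame([truth[i] for i in order])
    ids = [f"spec{i:06d}" for i in range(len(rows))]
    psm_df.insert(0, "spectrum_id", ids)
    truth_df.insert(0, "spectrum_id", ids)
    return psm_df, truth_df


# ---------------------------------------------------------------------------
# expression and detection
# ---------------------------------------------------------------------------

def generate_expression(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene expression table and MS detection/spectral-count table.

    RPKM is log-normal; detection is Bernoulli with a logistic probability
    in log10(RPKM); spectral counts are log-linear in RPKM with Gaussian
    noise whose variance is set, on the realized detected subpopulation, to
    target ``target_abundance_correlation``.  Zero-RPKM genes are never
    detected.
    """
    rng = _rng(cfg, 5)
    n = cfg.n_expression_genes
    n_zero = int(round(n * cfg.zero_expression_fraction))
    lengths = rng.integers(cfg.exon_model_length[0],
                           cfg.exon_model_length[1] + 1, size=n)
    x_target = rng.normal(cfg.log10_rpkm_mean, cfg.log10_rpkm_sd, size=n)
    reads = np.rint(
        10.0 ** x_target * cfg.total_mapped_reads * lengths / 1e9
    ).astype(int)
    reads = np.maximum(reads, 1)
    reads[:n_zero] = 0

    rpkm = 1e9 * reads / (cfg.total_mapped_reads * lengths)
    x = np.where(reads > 0, np.log10(np.where(rpkm > 0, rpkm, 1.0)), -np.inf)
    mid, scale = cfg.detection_logistic
    p_detect = expit((x - mid) / scale)
    detected = rng.random(n) < p_detect
    detected[reads == 0] = False

    xd = x[detected]
    r = cfg.target_abundance_correlation
    sigma_e = float(np.std(xd)) * math.sqrt(1.0 / r**2 - 1.0)
    y = (cfg.spectral_count_log10_intercept + xd
         + rng.normal(0.0, sigma_e, size=xd.size))
    counts = np.maximum(1, np.rint(10.0 ** y)).astype(int)

    gene_ids = np.array([f"expr{i:05d}" for i in range(n)])
    expr_df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "exon_model_length_nt": lengths,
            "mapped_reads": reads,
            "total_mapped_reads": cfg.total_mapped_reads,
        }
    )
    detect_df = pd.DataFrame(
        {"gene_id": gene_ids[detected], "spectral_count": counts}
    )
    return expr_df, detect_df


# ---------------------------------------------------------------------------
# end-to-end fixture writer
# ---------------------------------------------------------------------------

def simulate_to_dir(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the full set of pipeline inputs plus truth tables under
    ``outdir``; every file parses through the corresponding reader."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, models = generate_genome_and_models(cfg)
    junctions, jx_truth, genome = generate_junctions(cfg, models, genome)
    entries, _ = build_junction_database(junctions, genome, models,
                                         flank_nt=cfg.flank_nt)
    reference = generate_reference_proteins(cfg)
    combined = assemble_combined_db(reference, entries)
    psm_df, psm_truth = generate_psms(cfg, combined, entries)
    expr_df, detect_df = generate_expression(cfg)

    paths = {
        "genome": outdir / "genome.fa",
        "models": outdir / "models.gtf",
        "junctions": outdir / "junctions.bed",
        "reference": outdir / "reference.fa",
        "combined": outdir / "combined.fa",
        "psms": outdir / "psms.tsv",
        "expression": outdir / "expression.tsv",
        "detection": outdir / "detection.tsv",
        "junction_truth": outdir / "truth_junctions.tsv",
        "psm_truth": outdir / "truth_psms.tsv",
        "config": outdir / "sim_config.tsv",
    }
    with open(paths["genome"], "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    write_gene_models_gtf(models, paths["models"])
    write_junctions_bed(junctions, paths["junctions"])
    write_protein_fasta(reference, paths["reference"])
    write_protein_fasta(combined, paths["combined"])
    psm_df.to_csv(paths["psms"], sep="\t", index=False)
    expr_df.to_csv(paths["expression"], sep="\t", index=False)
    detect_df.to_csv(paths["detection"], sep="\t", index=False)
    jx_truth.to_csv(paths["junction_truth"], sep="\t", index=False)
    psm_truth.to_csv(paths["psm_truth"], sep="\t", index=False)
    pd.Series(asdict(cfg)).to_csv(paths["config"], sep="\t", header=False)
    return paths
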