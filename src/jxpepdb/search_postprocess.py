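"""Combined target+decoy search space and PSM post-processing.

Covers the steps downstream of the search engine: building the combined
reference + junction protein database with an equal-size reversed-decoy
complement, reading peptide-spectrum-match (PSM) tables, decoy-based FDR
estimation with q-values, class-specific (novel-subset) FDR filtering, and
a homology filter that removes candidate novel peptides lying within a few
mismatches of the reference proteome.

The score column is assumed higher-is-better (e.g. a posterior probability
in [0, 1]); the decoy machinery works with any monotone score.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .junctiondb import TranslatedJunctionEntry, entry_header

logger = logging.getLogger(__name__)

DECOY_PREFIX = "DECOY_"
DEFAULT_TARGET_FDR = 0.02
DEFAULT_MIN_MISMATCHES = 3


@dataclass
class ProteinEntry:
    accession: str
    sequence: str
    origin: str  # reference | junction | decoy


@dataclass
class ProteinDB:
    """A protein sequence collection with per-entry origin bookkeeping."""

    entries: list[ProteinEntry]

    def __post_init__(self) -> None:
        accs = [e.accession for e in self.entries]
        if len(set(accs)) != len(accs):
            raise ValueError("duplicate accessions in protein database")
        self._origin = {e.accession: e.origin for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, accession: str) -> bool:
        return accession in self._origin

    def targets(self) -> list[ProteinEntry]:
        return [e for e in self.entries if e.origin != "decoy"]

    def decoys(self) -> list[ProteinEntry]:
        return [e for e in self.entries if e.origin == "decoy"]

    def base_origin(self, accession: str) -> str:
        """Origin with decoys resolved to the class they mirror, e.g.
        ``decoy_junction`` for the reversed copy of a junction entry."""
        origin = self._origin[accession]
        if origin != "decoy":
            return origin
        base = accession[len(DECOY_PREFIX):]
        return f"decoy_{self._origin.get(base, 'unknown')}"


def generate_decoys(db: ProteinDB) -> ProteinDB:
    """Append one fully reversed decoy per target entry (``DECOY_`` prefix).

    The output has exactly twice the input entry count, and the decoy length
    distribution is by construction identical to the target distribution.
    """
    if db.decoys():
        raise ValueError("database already contains decoys")
    existing = {e.accession for e in db.entries}
    decoys = []
    for e in db.entries:
        acc = DECOY_PREFIX + e.accession
        if acc in existing:
            raise ValueError(f"decoy accession collision: {acc}")
        if e.sequence == e.sequence[::-1]:
            logger.info("palindromic sequence %s: decoy equals target", e.accession)
        decoys.append(ProteinEntry(acc, e.sequence[::-1], "decoy"))
    return ProteinDB(db.entries + decoys)


def assemble_combined_db(
    reference: ProteinDB, junction_entries: Iterable[TranslatedJunctionEntry]
) -> ProteinDB:
    """Append translated junction entries to the reference database and
    generate decoys over the union.

    Junction accessions colliding with reference accessions are suffixed
    with a warning.  A junction sequence identical to a reference sequence
    is retained: novelty is resolved at the peptide level, not here.
    """
    entries = [ProteinEntry(e.accession, e.sequence, "reference")
               for e in reference.entries]
    accs = {e.accession for e in entries}
    for je in junction_entries:
        acc = entry_header(je)
        while acc in accs:
            logger.warning("junction accession %s collides; suffixing", acc)
            acc += "_1"
        accs.add(acc)
        entries.append(ProteinEntry(acc, je.aa_sequence, "junction"))
    return generate_decoys(ProteinDB(entries))


def write_protein_fasta(db: ProteinDB, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(e.sequence), id=e.accession, description=e.origin)
        for e in db.entries
    ]
    SeqIO.write(records, str(path), "fasta")


def read_protein_fasta(path: str | Path, origin: str = "reference") -> ProteinDB:
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description.split(maxsplit=1)
        rec_origin = desc[1] if len(desc) > 1 and desc[1] in (
            "reference", "junction", "decoy") else origin
        if rec.id.startswith(DECOY_PREFIX):
            rec_origin = "decoy"
        entries.append(ProteinEntry(rec.id, str(rec.seq).upper(), rec_origin))
    if not entries:
        raise ValueError(f"no FASTA records found in {path}")
    return ProteinDB(entries)


# ---------------------------------------------------------------------------
# PSMs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSM:
    """One spectrum-to-peptide assignment."""

    spectrum_id: str
    peptide: str
    probability: float
    protein_accessions: tuple[str, ...]
    is_decoy: bool
    novelty: str  # known | novel_candidate | decoy
    quality: float | None = None
    junction_only: bool = False  # maps exclusively to junction/junction-decoy


_MOD_PATTERN = re.compile(r"\[[^\]]*\]")  # bracketed mass annotations


def clean_peptide(peptide: str) -> str:
    """Strip bracketed modification annotations and non-letter characters."""
    return re.sub(r"[^A-Za-z]", "", _MOD_PATTERN.sub("", peptide)).upper()


def _derive_psm(spectrum_id, peptide, probability, accessions, quality,
                db: ProteinDB) -> PSM:
    origins = {db.base_origin(a) for a in accessions}
    is_decoy = origins <= {"decoy_reference", "decoy_junction", "decoy_unknown"}
    if is_decoy:
        novelty = "decoy"
    elif "reference" in origins:
        novelty = "known"  # any reference hit wins: conservative novelty call
    else:
        novelty = "novel_candidate"
    junction_only = origins <= {"junction", "decoy_junction"}
    return PSM(
        spectrum_id=str(spectrum_id),
        peptide=clean_peptide(peptide),
        probability=float(probability),
        protein_accessions=tuple(accessions),
        is_decoy=is_decoy,
        novelty=novelty,
        quality=quality,
        junction_only=junction_only,
    )


def read_psm_table(path: str | Path, db: ProteinDB) -> list[PSM]:
    """Read a PSM TSV (spectrum_id, peptide, probability, proteins[, quality]).

    ``proteins`` is semicolon-separated.  Rows with probabilities outside
    [0, 1] or with accessions absent from the combined database are rejected
    with a warning.  Decoy status and novelty class are derived from the
    accessions' origins.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"spectrum_id", "peptide", "probability", "proteins"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")
    psms: list[PSM] = []
    for rec in df.itertuples(index=False):
        prob = float(rec.probability)
        if not (0.0 <= prob <= 1.0):
            logger.warning(
                "PSM %s: probability %.3f outside [0,1]; row rejected",
                rec.spectrum_id, prob,
            )
            continue
        accessions = [a for a in str(rec.proteins).split(";") if a]
        unknown = [a for a in accessions if a not in db]
        if unknown or not accessions:
            logger.warning(
                "PSM %s: unknown accession(s) %s; row rejected",
                rec.spectrum_id, unknown,
            )
            continue
        quality = float(rec.quality) if hasattr(rec, "quality") else None
        psms.append(
            _derive_psm(rec.spectrum_id, rec.peptide, prob, accessions,
                        quality, db)
        )
    return psms


def quality_filter(psms: Iterable[PSM], min_quality: float = 1.0) -> list[PSM]:
    """Optional spectrum-quality cutoff on the precomputed quality column;
    PSMs without a quality value are kept."""
    return [p for p in psms if p.quality is None or p.quality > min_quality]


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

@dataclass
class FdrCurve:
    """Decoy-based FDR curve over descending score thresholds."""

    thresholds: np.ndarray
    n_target: np.ndarray
    n_decoy: np.ndarray
    fdr: np.ndarray
    q: np.ndarray


def estimate_fdr_curve(psms: Sequence[PSM]) -> FdrCurve:
    """Estimate FDR at every distinct score threshold.

    At threshold t, ``fdr(t) = N_decoy(score >= t) / max(1, N_target(score
    >= t))``; q-values are the running minimum of fdr from the most
    permissive threshold upwards, hence monotone non-decreasing as the
    threshold decreases.
    """
    scores = np.array([p.probability for p in psms], dtype=float)
    decoy = np.array([p.is_decoy for p in psms], dtype=bool)
    if len(scores) == 0 or decoy.all():
        raise ValueError("need at least one target PSM")
    order = np.argsort(-scores, kind="stable")
    scores, decoy = scores[order], decoy[order]
    thresholds = -np.unique(-scores)  # descending distinct scores
    # index of the last PSM (inclusive) with score >= each threshold
    counts = np.searchsorted(-scores, -thresholds, side="right")
    cum_decoy = np.cumsum(decoy)
    n_decoy = cum_decoy[counts - 1]
    n_target = counts - n_decoy
    fdr = n_decoy / np.maximum(1, n_target)
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    return FdrCurve(thresholds, n_target, n_decoy, fdr, q)


def threshold_at_fdr(
    curve: FdrCurve, target_fdr: float = DEFAULT_TARGET_FDR
) -> float | None:
    """Lowest score threshold whose q-value is <= ``target_fdr`` (``None``
    if unattainable)."""
    if target_fdr <= 0:
        raise ValueError("target_fdr must be positive")
    ok = np.nonzero(curve.q <= target_fdr)[0]
    if len(ok) == 0:
        return None
    return float(curve.thresholds[ok.max()])


def filter_at_fdr(
    psms: Sequence[PSM], target_fdr: float = DEFAULT_TARGET_FDR
) -> tuple[list[PSM], float | None]:
    """Target PSMs passing the global q <= ``target_fdr`` threshold."""
    curve = estimate_fdr_curve(psms)
    thr = threshold_at_fdr(curve, target_fdr)
    if thr is None:
        return [], None
    return [p for p in psms if not p.is_decoy and p.probability >= thr], thr


def subset_fdr_filter(
    psms: Sequence[PSM], target_fdr: float = DEFAULT_TARGET_FDR
) -> tuple[list[PSM], float | None]:
    """Class-specific FDR filtering for the novel-candidate subset.

    The FDR curve is recomputed using only PSMs that map exclusively to
    junction (or junction-decoy) entries, whose error rate is typically much
    higher than the global one, and the novel PSMs passing the subset
    threshold are returned.  Returns ``([], None)`` with a warning when the
    subset has no decoys (threshold undefined) or no PSM reaches the target.
    """
    subset = [p for p in psms if p.junction_only]
    targets = [p for p in subset if not p.is_decoy]
    if not targets:
        logger.warning("novel subset empty among targets")
        return [], None
    if not any(p.is_decoy for p in subset):
        logger.warning("novel subset has no decoys; subset threshold undefined")
        return [], None
    curve = estimate_fdr_curve(subset)
    thr = threshold_at_fdr(curve, target_fdr)
    if thr is None:
        return [], None
    return [p for p in targets if p.probability >= thr], thr


# ---------------------------------------------------------------------------
# homology filter
# ---------------------------------------------------------------------------

def _encode(seq: str, il_equivalent: bool) -> np.ndarray:
    if il_equivalent:
        seq = seq.replace("L", "I")
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _reference_sequences(reference) -> list[str]:
    if isinstance(reference, ProteinDB):
        return [e.sequence for e in reference.entries if e.origin == "reference"]
    return list(reference)


def min_mismatch_distance(
    peptide: str, reference, il_equivalent: bool = True
) -> int:
    """Minimum Hamming distance between ``peptide`` and any equal-length
    substring of the reference proteome (exhaustive scan).

    I and L are treated as identical when ``il_equivalent`` (they are
    isobaric and indistinguishable by MS/MS).  Returns the peptide length
    when the reference is empty or shorter than the peptide everywhere.
    ``reference`` may be a :class:`ProteinDB` (reference entries are
    scanned) or any iterable of sequences.
    """
    if not peptide:
        raise ValueError("empty peptide")
    pep = _encode(peptide.upper(), il_equivalent)
    k = len(pep)
    best = k
    for seq in _reference_sequences(reference):
        if len(seq) < k:
            continue
        arr = _encode(seq.upper(), il_equivalent)
        windows = sliding_window_view(arr, k)
        d = int((windows != pep).sum(axis=1).min())
        if d < best:
            best = d
            if best == 0:
                return 0
    return best


def homology_filter(
    novel_psms: Sequence[PSM],
    reference,
    min_mismatches: int = DEFAULT_MIN_MISMATCHES,
    il_equivalent: bool = True,
) -> list[PSM]:
    """Retain candidate-novel PSMs whose peptide is at least
    ``min_mismatches`` substitutions away from every reference substring
    (peptides with fewer mismatches are presumed homology artifacts)."""
    kept = []
    cache: dict[str, int] = {}
    for p in novel_psms:
        d = cache.get(p.peptide)
        if d is None:
            d = min_mismatch_distance(p.peptide, reference, il_equivalent)
            cache[p.peptide] = d
        if d >= min_mismatches:
            kept.append(p)
    return kept


def write_psm_table(psms: Sequence[PSM], path: str | Path) -> None:
    rows = [
        {
            "spectrum_id": p.spectrum_id,
            "peptide": p.peptide,
            "probability": p.probability,
            "proteins": ";".join(p.protein_accessions),
            "quality": p.quality if p.quality is not None else "",
            "novelty": p.novelty,
        }
        for p in psms
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
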