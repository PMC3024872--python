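"""Transcript abundance versus MS detectability.

Relates RNA-Seq transcript abundance (RPKM: reads per kilobase of exon
model per million mapped reads) to whether and how strongly the gene's
protein product was observed by MS/MS: detection fractions in log10-RPKM
bins, and the correlation between log abundance and log spectral count over
detected genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 0.5


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene abundance plus MS detection status and spectral count."""

    gene_id: str
    exon_model_length_nt: int
    mapped_reads: int
    total_mapped_reads: int
    rpkm: float
    detected_by_ms: bool
    spectral_count: int = 0

    def __post_init__(self) -> None:
        if self.exon_model_length_nt <= 0 or self.total_mapped_reads <= 0:
            raise ValueError(f"{self.gene_id}: lengths and totals must be positive")
        if self.detected_by_ms and self.spectral_count < 1:
            raise ValueError(
                f"{self.gene_id}: detected gene must have spectral_count >= 1"
            )


def compute_rpkm(
    mapped_reads: int, exon_model_length_nt: int, total_mapped_reads: int
) -> float:
    """RPKM = 1e9 * reads / (total mapped reads * exon model length in nt)."""
    if exon_model_length_nt <= 0 or total_mapped_reads <= 0:
        raise ValueError("exon model length and total mapped reads must be positive")
    if mapped_reads < 0:
        raise ValueError("mapped_reads must be non-negative")
    return 1e9 * mapped_reads / (total_mapped_reads * exon_model_length_nt)


def load_expression_records(
    expression_path: str | Path, detection_path: str | Path
) -> list[ExpressionRecord]:
    """Join an expression TSV (gene_id, exon_model_length_nt, mapped_reads,
    total_mapped_reads) with a detection TSV (gene_id, spectral_count)."""
    expr = pd.read_csv(expression_path, sep="\t")
    det = pd.read_csv(detection_path, sep="\t")
    counts = dict(zip(det["gene_id"], det["spectral_count"]))
    records = []
    for rec in expr.itertuples(index=False):
        sc = int(counts.get(rec.gene_id, 0))
        records.append(
            ExpressionRecord(
                gene_id=str(rec.gene_id),
                exon_model_length_nt=int(rec.exon_model_length_nt),
                mapped_reads=int(rec.mapped_reads),
                total_mapped_reads=int(rec.total_mapped_reads),
                rpkm=compute_rpkm(
                    int(rec.mapped_reads),
                    int(rec.exon_model_length_nt),
                    int(rec.total_mapped_reads),
                ),
                detected_by_ms=sc >= 1,
                spectral_count=sc,
            )
        )
    return records


def detection_fraction_by_bin(
    records: Sequence[ExpressionRecord],
    bin_width_log10: float = DEFAULT_BIN_WIDTH,
) -> pd.DataFrame:
    """Fraction of genes detected by MS per log10(RPKM) bin.

    Zero-RPKM genes are collected in a dedicated ``zero`` bin; empty bins
    are omitted.  Returns columns bin, bin_low, bin_high, n_genes,
    n_detected, fraction, with bin boundaries in log10(RPKM).
    """
    if bin_width_log10 <= 0:
        raise ValueError("bin width must be positive")
    zero = [r for r in records if r.rpkm == 0]
    pos = [r for r in records if r.rpkm > 0]
    rows = []
    if zero:
        rows.append(
            {
                "bin": "zero",
                "bin_low": -math.inf,
                "bin_high": -math.inf,
                "n_genes": len(zero),
                "n_detected": sum(r.detected_by_ms for r in zero),
            }
        )
    binned: dict[int, list[ExpressionRecord]] = {}
    for r in pos:
        binned.setdefault(
            math.floor(math.log10(r.rpkm) / bin_width_log10), []
        ).append(r)
    for k in sorted(binned):
        rs = binned[k]
        lo, hi = k * bin_width_log10, (k + 1) * bin_width_log10
        rows.append(
            {
                "bin": f"[{lo:g},{hi:g})",
                "bin_low": lo,
                "bin_high": hi,
                "n_genes": len(rs),
                "n_detected": sum(r.detected_by_ms for r in rs),
            }
        )
    df = pd.DataFrame(rows)
    df["fraction"] = df["n_detected"] / df["n_genes"]
    return df


def abundance_correlation(
    records: Sequence[ExpressionRecord], method: str = "pearson"
) -> float | None:
    """Correlation between log10(RPKM) and log10(spectral count) over
    detected genes (spectral counts exist only for those).

    Returns ``None`` with a warning when either vector is constant.
    """
    detected = [
        r for r in records if r.detected_by_ms and r.spectral_count >= 1
        and r.rpkm > 0
    ]
    if len(detected) < 3:
        raise ValueError("need at least 3 detected records")
    x = np.log10([r.rpkm for r in detected])
    y = np.log10([r.spectral_count for r in detected])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant vector; correlation undefined")
        return None
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise ValueError(f"unsupported method {method!r}")


def plot_detection_fraction(table: pd.DataFrame, ax=None):
    """Bar plot of per-bin detection fractions (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.bar(range(len(table)), table["fraction"], tick_label=table["bin"])
    ax.set_xlabel("log10 RPKM bin")
    ax.set_ylabel("fraction of genes detected by MS")
    ax.tick_params(axis="x", rotation=45)
    return ax
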