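"""Density profiling of QTLs/meta-QTLs and genes along chromosomes.

Locus density is profiled as counts per bin of *distance from the
centromere*, pooling both chromosome arms (bins are half-open
[k*w, (k+1)*w) on |position − centromere|).  Gene density uses absolute
coordinates binned from zero, with each gene assigned to the bin of its
start.  Centromere positions are configuration: approximate A. thaliana
defaults ship for both the genetic (cM) and physical (Mb) frames, and any
mapping can be passed instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

#: Approximate A. thaliana centromere positions (Mb, physical frame).
CENTROMERES_MB = {"1": 15.1, "2": 3.6, "3": 13.8, "4": 4.0, "5": 11.2}
#: Approximate centromere positions on the consensus genetic map (cM),
#: placed proportionally to the physical centromeres.
CENTROMERES_CM = {"1": 56.0, "2": 19.0, "3": 40.0, "4": 20.0, "5": 46.0}


@dataclass
class DensityProfile:
    chromosome: str
    frame: str  # "genetic" (cM) or "physical" (Mb)
    bin_width: float
    counts: np.ndarray  # per-bin counts

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def density_from_centromere(
    items,
    centromere: float,
    bin_width: float,
    *,
    chromosome: str = "?",
    frame: str = "genetic",
    span: tuple[float, float] | None = None,
) -> DensityProfile:
    """Bin item positions by distance from the centromere, both arms pooled.

    ``span`` bounds the chromosome; an item outside it is counted in the
    last bin with a warning rather than dropped.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    pos = np.asarray(list(items), dtype=float)
    if span is not None and not (span[0] <= centromere <= span[1]):
        raise ValueError(f"centromere {centromere} outside chromosome span {span}")
    if pos.size == 0:
        return DensityProfile(chromosome, frame, bin_width, np.zeros(1, dtype=int))
    dist = np.abs(pos - centromere)
    idx = np.floor(dist / bin_width).astype(int)
    if span is not None:
        outside = (pos < span[0]) | (pos > span[1])
        if np.any(outside):
            log.warning("%d item(s) outside chromosome %s span; counted in last bin",
                        int(outside.sum()), chromosome)
            max_dist = max(centromere - span[0], span[1] - centromere)
            last = int(np.floor(max_dist / bin_width))
            idx[outside] = last
    counts = np.bincount(idx)
    return DensityProfile(chromosome, frame, bin_width, counts)


def gene_density(genes, bin_width_mb: float = 0.1) -> dict[str, DensityProfile]:
    """Gene-density profiles per chromosome: absolute-coordinate bins from 0,
    each gene counted once (strand ignored) in the bin of its start."""
    by_chrom: dict[str, list[float]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g.start_bp / 1e6)
    out: dict[str, DensityProfile] = {}
    for chrom, starts in sorted(by_chrom.items()):
        idx = np.floor(np.asarray(starts) / bin_width_mb).astype(int)
        out[chrom] = DensityProfile(chrom, "physical", bin_width_mb, np.bincount(idx))
    return out


def count_correlation(x, y) -> tuple[float, float]:
    """Pearson correlation between two per-chromosome count vectors,
    with the usual t-based two-sided P value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in counts")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
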