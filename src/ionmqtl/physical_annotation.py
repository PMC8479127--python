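"""Physical anchoring of meta-QTLs, candidate-gene extraction and GWAS overlap.

Genetic meta-QTL intervals are anchored to the genome through a marker →
(chromosome, bp interval) table: the physical interval runs from the left
flanking marker's start to the right flanking marker's end.  A flanking
marker without an anchor is substituted by the nearest anchored marker on
the consensus map and the interval is flagged.  Candidate genes are the
GFF3 ``gene`` features overlapping the interval (any overlap, strand
ignored).  GWAS SNPs are intersected with the physical intervals either by
strict containment or by nearest trait-matched interval.

Coordinates: GFF3 and anchor tables are 1-based inclusive bp; internally
everything is 0-based half-open; user-facing output is Mb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .consensus_map import ConsensusMap
from .metaqtl_model import MQTL
from .qtl_database import GWASHit, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarkerAnchor:
    marker_name: str
    chromosome: str
    start_bp: int  # 1-based inclusive
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValidationError(f"anchor {self.marker_name!r}: start_bp > end_bp")


@dataclass(frozen=True)
class PhysicalInterval:
    chromosome: str
    lo: float  # Mb
    hi: float  # Mb
    anchoring: str  # "flanking" | "closest-marker fallback"
    mqtl_id: str | None = None
    traits: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi):
            raise ValidationError(f"bad physical interval [{self.lo}, {self.hi}]")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chromosome: str
    start_bp: int  # 1-based inclusive
    end_bp: int
    strand: str = "."
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValidationError(f"gene {self.gene_id!r}: start_bp > end_bp")


def read_gff3_genes(path: str | Path, feature_type: str = "gene") -> list[GeneRecord]:
    """Read ``gene`` features from a GFF3 file; malformed lines are skipped
    with a warning."""
    genes: list[GeneRecord] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                log.warning("%s:%d: malformed GFF line skipped", path, lineno)
                continue
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != feature_type:
                continue
            try:
                start_bp, end_bp = int(start), int(end)
            except ValueError:
                log.warning("%s:%d: non-integer coordinates skipped", path, lineno)
                continue
            gene_id = ""
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
            genes.append(GeneRecord(
                gene_id=gene_id or f"{seqid}:{start_bp}-{end_bp}",
                chromosome=seqid.removeprefix("Chr").removeprefix("chr"),
                start_bp=start_bp, end_bp=end_bp, strand=strand,
            ))
    return genes


def read_anchor_table(path: str | Path) -> list[MarkerAnchor]:
    anchors: list[MarkerAnchor] = []
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["marker", "chromosome", "start_bp", "end_bp"]
        if header != expected:
            raise ValidationError(f"{path}: bad anchor header {header!r}; expected {expected!r}")
        for line in fh:
            if not line.strip():
                continue
            marker, chrom, start, end = line.rstrip("\n").split("\t")
            anchors.append(MarkerAnchor(marker, chrom, int(start), int(end)))
    return anchors


def anchor_mqtl(
    mqtl: MQTL,
    anchors: list[MarkerAnchor],
    consensus: ConsensusMap | None = None,
    *,
    mqtl_id: str | None = None,
) -> PhysicalInterval:
    """Anchor one meta-QTL's genetic interval to physical coordinates.

    An unanchored flanking marker is replaced by the nearest anchored
    consensus marker (flagging the interval "closest-marker fallback").
    """
    by_name = {a.marker_name: a for a in anchors}
    chrom_anchors = [a for a in anchors if a.chromosome == mqtl.chromosome]
    if not chrom_anchors:
        raise ValidationError(f"no anchored marker on chromosome {mqtl.chromosome}")

    fallback = False

    def resolve(marker: str | None, edge: float) -> MarkerAnchor:
        nonlocal fallback
        if marker is not None and marker in by_name:
            a = by_name[marker]
            if a.chromosome == mqtl.chromosome:
                return a
        fallback = True
        if consensus is not None and mqtl.chromosome in consensus.linkage_groups:
            cands = [m for m in consensus.group(mqtl.chromosome) if m.marker_name in by_name
                     and by_name[m.marker_name].chromosome == mqtl.chromosome]
            if cands:
                nearest = min(cands, key=lambda m: abs(m.position - edge))
                return by_name[nearest.marker_name]
        # no consensus available: nearest anchored marker by physical midpoint
        return min(chrom_anchors, key=lambda a: (a.start_bp + a.end_bp) / 2)

    left = resolve(mqtl.flanking_markers[0], mqtl.ci_lo)
    right = resolve(mqtl.flanking_markers[1], mqtl.ci_hi)
    lo_bp = min(left.start_bp, right.start_bp)
    hi_bp = max(left.end_bp, right.end_bp)
    return PhysicalInterval(
        chromosome=mqtl.chromosome,
        lo=lo_bp / 1e6, hi=hi_bp / 1e6,
        anchoring="closest-marker fallback" if fallback else "flanking",
        mqtl_id=mqtl_id,
        traits=mqtl.traits,
    )


def genes_in_interval(genes: list[GeneRecord], interval: PhysicalInterval) -> list[GeneRecord]:
    """Genes overlapping the interval (closed-interval overlap, any extent),
    sorted by start."""
    lo_bp = interval.lo * 1e6
    hi_bp = interval.hi * 1e6
    hits = [
        g for g in genes
        if g.chromosome == interval.chromosome
        and g.start_bp <= hi_bp and g.end_bp >= lo_bp
    ]
    return sorted(hits, key=lambda g: g.start_bp)


@dataclass(frozen=True)
class GWASOverlap:
    mqtl_id: str | None
    interval: PhysicalInterval
    hit: GWASHit
    distance_mb: float  # 0 when the SNP lies inside the interval


def gwas_overlap(
    intervals: list[PhysicalInterval],
    hits: list[GWASHit],
    *,
    trait_matched: bool = True,
    mode: str = "within",
) -> list[GWASOverlap]:
    """Intersect meta-QTL physical intervals with GWAS SNPs.

    mode="within": every (interval, SNP) pair with lo <= position <= hi.
    mode="nearest": each SNP is assigned to the single nearest eligible
    interval on its chromosome (distance 0 when contained) — the pairing a
    study reports when it lists one collinear meta-QTL per SNP.

    With ``trait_matched`` the SNP's trait must be in the interval's trait set.
    """
    if mode not in ("within", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")
    out: list[GWASOverlap] = []
    for hit in hits:
        eligible = [
            iv for iv in intervals
            if iv.chromosome == hit.chromosome
            and (not trait_matched or hit.trait in iv.traits)
        ]
        if not eligible:
            continue

        def distance(iv: PhysicalInterval) -> float:
            return max(iv.lo - hit.position, hit.position - iv.hi, 0.0)

        if mode == "within":
            for iv in eligible:
                if distance(iv) == 0.0:
                    out.append(GWASOverlap(iv.mqtl_id, iv, hit, 0.0))
        else:
            best = min(eligible, key=lambda iv: (distance(iv), iv.lo))
            out.append(GWASOverlap(best.mqtl_id, best, hit, distance(best)))
    return out


def per_trait_counts(overlaps: list[GWASOverlap]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for ov in overlaps:
        counts[ov.hit.trait] = counts.get(ov.hit.trait, 0) + 1
    return dict(sorted(counts.items()))


def intervals_from_records(records) -> list[PhysicalInterval]:
    """Physical intervals straight from a published meta-QTL table."""
    return [
        PhysicalInterval(
            chromosome=r.chromosome, lo=r.phys_lo, hi=r.phys_hi,
            anchoring="flanking", mqtl_id=r.mqtl_id, traits=frozenset(r.traits),
        )
        for r in records
    ]


def write_bed(intervals: list[PhysicalInterval], path: str | Path) -> None:
    """BED output (0-based half-open, bp)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for iv in intervals:
            start = int(round(iv.lo * 1e6)) - 1
            end = int(round(iv.hi * 1e6))
            fh.write(f"{iv.chromosome}\t{max(start, 0)}\t{end}\t{iv.mqtl_id or '.'}\n")
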