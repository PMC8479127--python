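"""Projection of published QTLs onto the consensus map.

Each QTL is transferred by the local affine transform defined by the
flanking markers shared between its source map and the consensus (nearest
shared marker on each side of the peak; the two nearest shared markers when
the peak falls outside the shared span).  The 95% CI moves with the same
transform, and the positional standard deviation sd = CI width / 3.92
treats the reported interval as a 95% Gaussian interval — the meta-model
downstream needs a per-QTL variance and the 95% CI is what studies report.

Studies that report no CI get a proxy width 530 / (N * R^2) (population
size N, R^2 in percent), the standard expectation for RIL designs; such
records are flagged in the projection report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .consensus_map import ConsensusMap
from .qtl_database import GeneticMap, QTLRecord, ValidationError

log = logging.getLogger(__name__)

#: 95% two-sided normal interval spans 2 * 1.96 standard deviations.
CI95_TO_SD = 3.92


class ProjectionError(ValueError):
    """The QTL cannot be transferred onto the consensus map."""


@dataclass(frozen=True)
class ProjectedQTL:
    source: QTLRecord
    peak_c: float  # cM on consensus
    ci_lo_c: float
    ci_hi_c: float
    sd: float  # positional standard deviation, cM
    ci_estimated: bool = False  # CI came from the 530/(N*R^2) proxy

    def __post_init__(self) -> None:
        if not (self.ci_lo_c <= self.peak_c <= self.ci_hi_c):
            raise ValidationError(
                f"projected QTL {self.source.qtl_id!r}: CI does not bracket peak"
            )
        if self.sd <= 0:
            raise ValidationError(f"projected QTL {self.source.qtl_id!r}: sd must be > 0")


@dataclass
class ProjectionReport:
    projected: dict[str, int] = field(default_factory=dict)  # population -> count
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (qtl_id, reason)

    @property
    def n_projected(self) -> int:
        return sum(self.projected.values())


def estimate_ci_width(n_individuals: int, r2_pct: float) -> float:
    """Expected 95% CI width (cM) of a QTL in a RIL population: 530/(N*R^2)."""
    if n_individuals <= 0 or r2_pct <= 0:
        raise ValidationError("need positive population size and R^2 to estimate a CI")
    return 530.0 / (n_individuals * r2_pct)


def _shared_anchors(
    source_map: GeneticMap, consensus: ConsensusMap, lg: str
) -> list[tuple[str, float, float]]:
    cons_pos = {m.marker_name: m.position for m in consensus.group(lg)}
    anchors = [
        (m.marker_name, m.position, cons_pos[m.marker_name])
        for m in source_map.group(lg)
        if m.marker_name in cons_pos
    ]
    anchors.sort(key=lambda a: a[1])
    return anchors


def _flanking_pair(
    anchors: list[tuple[str, float, float]], peak: float
) -> tuple[tuple[str, float, float], tuple[str, float, float]]:
    """Nearest shared anchor on each side of the peak; at the ends, the two
    nearest anchors overall."""
    left = [a for a in anchors if a[1] <= peak]
    right = [a for a in anchors if a[1] >= peak]
    if left and right and left[-1][1] != right[0][1]:
        return left[-1], right[0]
    # peak outside the shared span (or sitting exactly on one anchor):
    # use the two anchors nearest to the peak with distinct source positions
    ranked = sorted(anchors, key=lambda a: abs(a[1] - peak))
    first = ranked[0]
    for other in ranked[1:]:
        if other[1] != first[1]:
            pair = sorted([first, other], key=lambda a: a[1])
            return pair[0], pair[1]
    raise ProjectionError("coincident anchors: all shared markers at one source position")


def project_qtl(
    qtl: QTLRecord,
    source_map: GeneticMap,
    consensus: ConsensusMap,
    *,
    population_size: int | None = None,
) -> ProjectedQTL:
    """Transfer one QTL onto the consensus map by a local affine transform."""
    lg = qtl.linkage_group
    if lg not in source_map.linkage_groups:
        raise ProjectionError(f"linkage group {lg!r} absent from source map")
    if lg not in consensus.linkage_groups:
        raise ProjectionError(f"linkage group {lg!r} absent from consensus map")
    anchors = _shared_anchors(source_map, consensus, lg)
    if len(anchors) < 2:
        raise ProjectionError(
            f"fewer than 2 markers shared between source map and consensus on LG {lg!r}"
        )

    ci_lo, ci_hi = qtl.ci_lo, qtl.ci_hi
    ci_estimated = False
    if ci_hi == ci_lo:
        if population_size is None or qtl.r2_pct is None or qtl.r2_pct == 0:
            raise ProjectionError(
                f"QTL {qtl.qtl_id!r}: zero-width CI and no (population size, R^2) "
                "to estimate one"
            )
        half = estimate_ci_width(population_size, qtl.r2_pct) / 2
        ci_lo, ci_hi = qtl.peak - half, qtl.peak + half
        ci_estimated = True

    (_, s_left, c_left), (_, s_right, c_right) = _flanking_pair(anchors, qtl.peak)
    if s_right == s_left:
        raise ProjectionError("coincident anchors")
    scale = (c_right - c_left) / (s_right - s_left)

    def tf(x: float) -> float:
        return c_left + (x - s_left) * scale

    span_lo, span_hi = consensus.span(lg)

    def clamp(x: float) -> float:
        return min(max(x, span_lo), span_hi)

    peak_c = clamp(tf(qtl.peak))
    lo_c, hi_c = sorted((tf(ci_lo), tf(ci_hi)))
    lo_c, hi_c = clamp(lo_c), clamp(hi_c)
    lo_c, hi_c = min(lo_c, peak_c), max(hi_c, peak_c)
    # sd reflects the transferred interval before span clamping
    width_c = abs(tf(ci_hi) - tf(ci_lo))
    sd = width_c / CI95_TO_SD
    if sd == 0:
        raise ProjectionError(f"QTL {qtl.qtl_id!r}: zero projected CI width")
    return ProjectedQTL(
        source=qtl, peak_c=peak_c, ci_lo_c=lo_c, ci_hi_c=hi_c, sd=sd,
        ci_estimated=ci_estimated,
    )


def project_all(
    qtls: list[QTLRecord],
    maps: dict[str, GeneticMap],
    consensus: ConsensusMap,
    *,
    population_sizes: dict[str, int] | None = None,
) -> tuple[list[ProjectedQTL], ProjectionReport]:
    """Project a whole QTL database; skipped QTLs are logged with a reason."""
    report = ProjectionReport()
    out: list[ProjectedQTL] = []
    for qtl in qtls:
        gmap = maps.get(qtl.population_id)
        if gmap is None:
            report.skipped.append((qtl.qtl_id, f"no map for population {qtl.population_id!r}"))
            continue
        n = (population_sizes or {}).get(qtl.population_id)
        try:
            proj = project_qtl(qtl, gmap, consensus, population_size=n)
        except ProjectionError as exc:
            log.info("QTL %s skipped: %s", qtl.qtl_id, exc)
            report.skipped.append((qtl.qtl_id, str(exc)))
            continue
        out.append(proj)
        report.projected[qtl.population_id] = report.projected.get(qtl.population_id, 0) + 1
    return out, report
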