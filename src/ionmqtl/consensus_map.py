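"""Consensus genetic-map construction and genome-length estimation.

Population maps are merged by aligning each map onto a growing consensus
with a piecewise-linear transform fitted on shared markers, then taking a
final weighted re-averaging pass over every map's aligned positions.  The
merge is deterministic: maps are visited in descending marker count, ties
broken by population id, and the final pass makes the result independent of
visit order for fully shared markers.

Genome lengths are adjusted for unobserved terminal chromosome regions by
the Hubert–Hedgecock method: with average inter-marker spacing
chi = (sum of linkage-group lengths) / (markers − linkage groups), each
linkage group gains 2*chi.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .qtl_database import GeneticMap, MarkerPosition, ValidationError

log = logging.getLogger(__name__)


@dataclass
class ConsensusMap:
    """A merged marker map; provenance records which populations place each marker."""

    markers: list[MarkerPosition]
    provenance: dict[tuple[str, str], frozenset[str]]  # (marker, LG) -> population ids

    def __post_init__(self) -> None:
        self.markers = sorted(self.markers, key=lambda m: (m.linkage_group, m.position))

    @property
    def linkage_groups(self) -> list[str]:
        return sorted({m.linkage_group for m in self.markers})

    def group(self, lg: str) -> list[MarkerPosition]:
        return [m for m in self.markers if m.linkage_group == lg]

    def span(self, lg: str) -> tuple[float, float]:
        pos = [m.position for m in self.group(lg)]
        if not pos:
            raise KeyError(f"no markers on linkage group {lg!r}")
        return min(pos), max(pos)

    def as_genetic_map(self, population_id: str = "consensus") -> GeneticMap:
        return GeneticMap(population_id=population_id, markers=list(self.markers))


@dataclass(frozen=True)
class GenomeLengthEstimate:
    chi: float  # average marker spacing, cM
    per_lg_raw: dict[str, float]
    per_lg_adjusted: dict[str, float]
    total_raw: float
    total_adjusted: float


def _piecewise_transform(src: np.ndarray, dst: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Map positions x through the piecewise-linear function anchored at (src, dst).

    Between anchors: linear interpolation. Beyond the ends: the terminal
    segment's slope, with results clamped to >= 0 cM.
    """
    order = np.argsort(src)
    src, dst = src[order], dst[order]
    if len(src) == 1:
        # single anchor: pure shift
        return np.maximum(x - src[0] + dst[0], 0.0)
    out = np.interp(x, src, dst)
    # terminal extrapolation with the nearest segment's slope
    lo_slope = (dst[1] - dst[0]) / (src[1] - src[0]) if src[1] != src[0] else 1.0
    hi_slope = (dst[-1] - dst[-2]) / (src[-1] - src[-2]) if src[-1] != src[-2] else 1.0
    below = x < src[0]
    above = x > src[-1]
    out[below] = dst[0] + (x[below] - src[0]) * lo_slope
    out[above] = dst[-1] + (x[above] - src[-1]) * hi_slope
    return np.maximum(out, 0.0)


def build_consensus(
    maps: list[GeneticMap],
    weights: dict[str, float] | None = None,
) -> ConsensusMap:
    """Merge population maps into a single consensus map.

    Default weight of a map on a linkage group is its marker count there
    (denser maps carry more positional information); ``weights`` overrides
    per population id.

    A map sharing no marker with the growing consensus on some linkage group
    contributes its markers unaligned (original coordinates) with a warning.
    A marker assigned to different linkage groups by different maps is an
    error.
    """
    if not maps:
        raise ValidationError("need at least one map")

    # conflicting linkage-group assignment check
    lg_of: dict[str, str] = {}
    for gmap in maps:
        for m in gmap.markers:
            prev = lg_of.setdefault(m.marker_name, m.linkage_group)
            if prev != m.linkage_group:
                raise ValidationError(
                    f"marker {m.marker_name!r} assigned to linkage groups "
                    f"{prev!r} and {m.linkage_group!r} by different maps"
                )

    order = sorted(maps, key=lambda g: (-len(g.markers), g.population_id))
    all_lgs = sorted({m.linkage_group for g in maps for m in g.markers})

    out_markers: list[MarkerPosition] = []
    provenance: dict[tuple[str, str], frozenset[str]] = {}

    for lg in all_lgs:
        # per-map marker dicts for this LG
        per_map: list[tuple[GeneticMap, dict[str, float]]] = []
        for gmap in order:
            d = {m.marker_name: m.position for m in gmap.group(lg)}
            if d:
                per_map.append((gmap, d))

        # aligned[marker] -> list of (position on consensus scale, weight, pop)
        aligned: dict[str, list[tuple[float, float, str]]] = {}
        consensus_pos: dict[str, float] = {}

        for gmap, d in per_map:
            w = (weights or {}).get(gmap.population_id, float(len(d)))
            names = list(d)
            x = np.array([d[n] for n in names])
            shared = [n for n in names if n in consensus_pos]
            if not consensus_pos:
                ax = x  # first map defines the scale
            elif not shared:
                log.warning(
                    "population %s shares no marker with consensus on LG %s; "
                    "appended unaligned", gmap.population_id, lg,
                )
                ax = x
            else:
                if len(shared) < 2:
                    log.warning(
                        "population %s shares only %d marker(s) with consensus on LG %s",
                        gmap.population_id, len(shared), lg,
                    )
                # a shared marker never anchors its own alignment: its new
                # placement must carry this map's independent information
                ax = np.empty(len(names))
                for i, n in enumerate(names):
                    anchors = [a for a in shared if a != n]
                    if not anchors:
                        ax[i] = x[i]
                        continue
                    src = np.array([d[a] for a in anchors])
                    dst = np.array([consensus_pos[a] for a in anchors])
                    ax[i] = _piecewise_transform(src, dst, x[i:i + 1])[0]
            for n, p in zip(names, ax):
                aligned.setdefault(n, []).append((float(p), w, gmap.population_id))
                # running consensus estimate used to align later maps
                obs = aligned[n]
                consensus_pos[n] = sum(p_ * w_ for p_, w_, _ in obs) / sum(w_ for _, w_, _ in obs)

        # final re-averaging pass over all aligned placements
        final = {
            n: sum(p * w for p, w, _ in obs) / sum(w for _, w, _ in obs)
            for n, obs in aligned.items()
        }

        # order by weighted-mean position; snap any residual inversion so the
        # listed order is monotone (minority placements yield to the majority)
        names_sorted = sorted(final, key=lambda n: (final[n], n))
        prev = -np.inf
        for n in names_sorted:
            pos = max(final[n], prev)
            prev = pos
            out_markers.append(MarkerPosition(marker_name=n, linkage_group=lg, position=pos))
            provenance[(n, lg)] = frozenset(pop for _, _, pop in aligned[n])

    return ConsensusMap(markers=out_markers, provenance=provenance)


def genome_length(gmap: GeneticMap | ConsensusMap) -> GenomeLengthEstimate:
    """Hubert–Hedgecock adjusted genome length.

    chi = total raw length / (M − G); each linkage group gains 2*chi for the
    unobserved terminal regions.
    """
    lgs = gmap.linkage_groups
    n_markers = len(gmap.markers)
    n_groups = len(lgs)
    if n_markers <= n_groups:
        raise ValidationError("no intervals: need more markers than linkage groups")
    raw = {lg: gmap.span(lg)[1] - gmap.span(lg)[0] for lg in lgs}
    total_raw = sum(raw.values())
    chi = total_raw / (n_markers - n_groups)
    adjusted = {lg: raw[lg] + 2 * chi for lg in lgs}
    return GenomeLengthEstimate(
        chi=chi,
        per_lg_raw=raw,
        per_lg_adjusted=adjusted,
        total_raw=total_raw,
        total_adjusted=sum(adjusted.values()),
    )


def map_summary(gmap: GeneticMap | ConsensusMap) -> dict:
    """Per-linkage-group marker counts and spans, plus totals."""
    lgs = gmap.linkage_groups
    per_lg = {}
    for lg in lgs:
        group = gmap.group(lg)
        lo, hi = gmap.span(lg)
        per_lg[lg] = {"n_markers": len(group), "length_cM": hi - lo}
    return {
        "per_lg": per_lg,
        "total_markers": sum(v["n_markers"] for v in per_lg.values()),
        "total_length_cM": sum(v["length_cM"] for v in per_lg.values()),
    }
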