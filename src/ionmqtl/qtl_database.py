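"""Domain types, readers/writers and packaged fixtures for the ionomic QTL database.

The atomic unit of the analysis is a published QTL: a trait code, a linkage
group, a peak position on a genetic map (cM) and a 95% confidence interval.
Trait codes are element symbols, optionally prefixed ``rs``/``ro``/``sh``
(rosette / root / shoot measurements); prefixed codes are *distinct* traits
and are never folded into the bare element.

Two fixtures ship with the package: the published table of 33 detected
meta-QTLs on the Arabidopsis thaliana consensus map, and the table of nine
GWAS SNPs for Zn/Fe/Mn used to cross-validate them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

#: Bare element symbols seen across the source mapping studies.
ELEMENTS = (
    "Al", "As", "B", "Ca", "Cd", "Co", "Cu", "Fe", "K", "Li",
    "Mg", "Mn", "Mo", "Na", "Ni", "P", "Rb", "S", "Se", "Zn",
)

#: Tissue-prefixed trait codes (rosette/root/shoot) that occur in the studies.
PREFIXED_TRAITS = (
    "rsCa", "rsFe", "rsK", "rsMg", "rsMn", "rsP", "rsZn",
    "roFe", "roZn",
    "shAl", "shCa", "shCu", "shFe", "shK", "shMg", "shMn", "shP", "shS", "shZn",
)

#: The closed controlled vocabulary of trait codes (case-sensitive).
TRAIT_VOCABULARY: frozenset[str] = frozenset(ELEMENTS) | frozenset(PREFIXED_TRAITS)

#: Fixed column order used for trait-presence matrices and reports.
TRAIT_ORDER: tuple[str, ...] = tuple(sorted(TRAIT_VOCABULARY))

# How far (cM) outside a linkage-group span a published peak may fall before
# it is an error rather than a rounding artifact to clamp.
CLAMP_TOLERANCE_CM = 0.5


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class ParseError(ValueError):
    """A file could not be parsed; carries the offending line number."""


@dataclass(frozen=True)
class MarkerPosition:
    marker_name: str
    linkage_group: str
    position: float  # cM

    def __post_init__(self) -> None:
        if not self.marker_name:
            raise ValidationError("marker_name must be non-empty")
        if self.position < 0:
            raise ValidationError(
                f"marker {self.marker_name!r}: negative position {self.position}"
            )


@dataclass
class GeneticMap:
    """Ordered marker positions of one mapping population, grouped by linkage group."""

    population_id: str
    markers: list[MarkerPosition]

    def __post_init__(self) -> None:
        self.markers = sorted(self.markers, key=lambda m: (m.linkage_group, m.position))
        seen: set[tuple[str, str]] = set()
        for m in self.markers:
            key = (m.marker_name, m.linkage_group)
            if key in seen:
                raise ValidationError(
                    f"duplicate marker {m.marker_name!r} on linkage group {m.linkage_group}"
                )
            seen.add(key)

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


@dataclass(frozen=True)
class QTLRecord:
    """One published QTL as reported by a source mapping study."""

    qtl_id: str
    population_id: str
    trait: str
    linkage_group: str
    peak: float  # cM
    ci_lo: float  # cM
    ci_hi: float  # cM
    lod: float | None = None
    r2_pct: float | None = None

    def __post_init__(self) -> None:
        if self.trait not in TRAIT_VOCABULARY:
            raise ValidationError(
                f"QTL {self.qtl_id!r}: unknown trait code {self.trait!r}; "
                f"allowed codes: {', '.join(TRAIT_ORDER)}"
            )
        if not (self.ci_lo <= self.peak <= self.ci_hi):
            raise ValidationError(
                f"QTL {self.qtl_id!r}: CI [{self.ci_lo}, {self.ci_hi}] "
                f"does not bracket peak {self.peak}"
            )
        if self.lod is not None and self.lod < 0:
            raise ValidationError(f"QTL {self.qtl_id!r}: negative LOD {self.lod}")
        if self.r2_pct is not None and not (0 <= self.r2_pct <= 100):
            raise ValidationError(f"QTL {self.qtl_id!r}: r2_pct {self.r2_pct} outside [0, 100]")

    @property
    def ci_width(self) -> float:
        return self.ci_hi - self.ci_lo


@dataclass(frozen=True)
class MQTLRecord:
    """One published meta-QTL row (the fixture mirrors the printed table)."""

    mqtl_id: str
    chromosome: str
    consensus_position: float  # cM
    ci_length: float  # cM
    phys_lo: float  # Mb
    phys_hi: float  # Mb
    n_initial_qtls: int
    n_populations: int
    traits: frozenset[str]
    n_genes: int
    flanking_markers: tuple[str, str]

    def __post_init__(self) -> None:
        if self.ci_length < 0:
            raise ValidationError(f"{self.mqtl_id}: negative CI length")
        if self.phys_lo > self.phys_hi:
            raise ValidationError(f"{self.mqtl_id}: phys_lo > phys_hi")
        if self.n_populations > self.n_initial_qtls:
            raise ValidationError(f"{self.mqtl_id}: more populations than member QTLs")
        if not self.traits:
            raise ValidationError(f"{self.mqtl_id}: empty trait set")
        unknown = self.traits - TRAIT_VOCABULARY
        if unknown:
            raise ValidationError(f"{self.mqtl_id}: unknown trait codes {sorted(unknown)}")


@dataclass(frozen=True)
class GWASHit:
    """A SNP–trait association from a genome-wide association study."""

    trait: str
    chromosome: str
    position: float  # Mb

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValidationError(f"GWAS hit {self.trait}@{self.position}: position must be > 0")


# ---------------------------------------------------------------------------
# file I/O (tab-delimited, UTF-8, '.' decimal separator)

_MAP_HEADER = ["population_id", "linkage_group", "marker", "position_cM"]
_QTL_HEADER = [
    "qtl_id", "population_id", "trait", "linkage_group",
    "peak_cM", "ci_lo_cM", "ci_hi_cM", "lod", "r2_pct",
]


def _read_rows(path: str | Path, expected_header: Sequence[str]) -> Iterable[tuple[int, list[str]]]:
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise ParseError(f"{path}: empty file (no header)")
        header = header_line.rstrip("\n").split("\t")
        if header != list(expected_header):
            raise ParseError(
                f"{path}: bad header {header!r}; expected {list(expected_header)!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(expected_header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(expected_header)} fields, got {len(fields)}"
                )
            yield lineno, fields


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read one population's genetic map from a tab-delimited file.

    Markers come back sorted by (linkage_group, position); duplicate
    (marker, linkage group) rows and negative positions are rejected.
    """
    markers: list[MarkerPosition] = []
    population_id: str | None = None
    for lineno, (pop, lg, marker, pos) in ((ln, f) for ln, f in _read_rows(path, _MAP_HEADER)):
        if population_id is None:
            population_id = pop
        elif pop != population_id:
            raise ParseError(f"{path}:{lineno}: mixed population ids ({pop!r} vs {population_id!r})")
        try:
            position = float(pos)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad position {pos!r}") from exc
        markers.append(MarkerPosition(marker_name=marker, linkage_group=lg, position=position))
    if not markers or population_id is None:
        raise ParseError(f"{path}: no markers")
    return GeneticMap(population_id=population_id, markers=markers)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_MAP_HEADER) + "\n")
        for m in gmap.markers:
            # repr gives the shortest digits that round-trip exactly
            fh.write(f"{gmap.population_id}\t{m.linkage_group}\t{m.marker_name}\t{m.position!r}\n")


def _opt_float(text: str) -> float | None:
    return None if text == "" else float(text)


def read_qtl_table(path: str | Path) -> list[QTLRecord]:
    """Read QTL records from a tab-delimited table, validating each one.

    lod / r2_pct may be blank. Records come back in file order.
    """
    records: list[QTLRecord] = []
    for lineno, fields in _read_rows(path, _QTL_HEADER):
        qtl_id, pop, trait, lg, peak, lo, hi, lod, r2 = fields
        try:
            rec = QTLRecord(
                qtl_id=qtl_id, population_id=pop, trait=trait, linkage_group=lg,
                peak=float(peak), ci_lo=float(lo), ci_hi=float(hi),
                lod=_opt_float(lod), r2_pct=_opt_float(r2),
            )
        except ValueError as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        records.append(rec)
    return records


def write_qtl_table(records: Sequence[QTLRecord], path: str | Path) -> None:
    def fmt(v: float | None) -> str:
        return "" if v is None else repr(float(v))

    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_QTL_HEADER) + "\n")
        for r in records:
            fh.write(
                f"{r.qtl_id}\t{r.population_id}\t{r.trait}\t{r.linkage_group}\t"
                f"{r.peak!r}\t{r.ci_lo!r}\t{r.ci_hi!r}\t{fmt(r.lod)}\t{fmt(r.r2_pct)}\n"
            )


def clamp_peak(qtl: QTLRecord, span: tuple[float, float]) -> QTLRecord:
    """Clamp a peak marginally outside its linkage-group span (< 0.5 cM).

    Published tables round positions; a small excursion beyond the terminal
    marker is tolerated and clamped with a warning, a larger one is an error.
    """
    lo, hi = span
    if lo <= qtl.peak <= hi:
        return qtl
    excess = max(lo - qtl.peak, qtl.peak - hi)
    if excess >= CLAMP_TOLERANCE_CM:
        raise ValidationError(
            f"QTL {qtl.qtl_id!r}: peak {qtl.peak} lies {excess:.2f} cM outside "
            f"linkage-group span [{lo}, {hi}]"
        )
    new_peak = min(max(qtl.peak, lo), hi)
    log.warning("QTL %s: peak %.3f clamped to %.3f (span [%g, %g])",
                qtl.qtl_id, qtl.peak, new_peak, lo, hi)
    return QTLRecord(
        qtl_id=qtl.qtl_id, population_id=qtl.population_id, trait=qtl.trait,
        linkage_group=qtl.linkage_group, peak=new_peak,
        ci_lo=min(max(qtl.ci_lo, lo), new_peak),
        ci_hi=max(min(qtl.ci_hi, hi), new_peak),
        lod=qtl.lod, r2_pct=qtl.r2_pct,
    )


# ---------------------------------------------------------------------------
# packaged fixtures

def _fixture_path(name: str):
    return resources.files("ionmqtl.data").joinpath(name)


def load_table3_fixture() -> list[MQTLRecord]:
    """The 33 published meta-QTLs on the A. thaliana consensus map."""
    records: list[MQTLRecord] = []
    text = _fixture_path("table3_mqtl.tsv").read_text(encoding="utf-8")
    lines = text.strip().split("\n")
    header = lines[0].split("\t")
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        records.append(MQTLRecord(
            mqtl_id=row["mqtl_id"],
            chromosome=row["chromosome"],
            consensus_position=float(row["position_cM"]),
            ci_length=float(row["ci_cM"]),
            phys_lo=float(row["phys_lo_Mb"]),
            phys_hi=float(row["phys_hi_Mb"]),
            n_initial_qtls=int(row["n_initial_qtls"]),
            n_populations=int(row["n_populations"]),
            traits=frozenset(row["traits"].split(",")),
            n_genes=int(row["n_genes"]),
            flanking_markers=(row["marker_left"], row["marker_right"]),
        ))
    if len(records) != 33:
        raise ValidationError(f"fixture must hold 33 meta-QTLs, found {len(records)}")
    return records


def load_table5_fixture() -> list[GWASHit]:
    """Nine published GWAS SNPs for Zn/Fe/Mn collinear with meta-QTLs."""
    hits: list[GWASHit] = []
    text = _fixture_path("table5_gwas.tsv").read_text(encoding="utf-8")
    lines = text.strip().split("\n")
    header = lines[0].split("\t")
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        hits.append(GWASHit(
            trait=row["trait"],
            chromosome=row["chromosome"],
            position=float(row["position_Mb"]),
        ))
    return hits


def load_table5_pairing() -> list[tuple[GWASHit, str]]:
    """GWAS hits together with the meta-QTL each was published as collinear with."""
    pairs: list[tuple[GWASHit, str]] = []
    text = _fixture_path("table5_gwas.tsv").read_text(encoding="utf-8")
    lines = text.strip().split("\n")
    header = lines[0].split("\t")
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        hit = GWASHit(trait=row["trait"], chromosome=row["chromosome"],
                      position=float(row["position_Mb"]))
        pairs.append((hit, row["mqtl_id"]))
    return pairs
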