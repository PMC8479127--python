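"""Synthetic multi-population QTL studies with planted meta-QTL structure.

The generator emulates the scale of the real study pool this kind of
meta-analysis consumes: a dozen RIL populations mapped on five chromosomes
of roughly 86–115 cM, ~30 markers per chromosome of which a fixed core is
shared by every population, three true loci per chromosome, a 60% chance
that any one population detects any one locus, detection-position noise of
2 cM and original 95% CIs averaging 10.88 cM.  Everything downstream of a
published QTL table is exercised by these studies; nothing genotype-level
(meioses, scans) is simulated because the meta-analysis never sees it.

All randomness flows through one ``numpy`` Generator seeded once per run,
with draws consumed in a fixed documented order, so a (config, seed) pair
reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consensus_map import _piecewise_transform
from .qtl_database import GeneticMap, MarkerPosition, QTLRecord
from .physical_annotation import GeneRecord, MarkerAnchor

#: Consensus-scale chromosome lengths (cM) used as defaults.
DEFAULT_CHROM_LENGTHS = (110.76, 105.64, 86.32, 96.72, 114.57)


@dataclass(frozen=True)
class SimulationConfig:
    n_populations: int = 12
    n_chromosomes: int = 5
    chromosome_lengths: tuple[float, ...] = DEFAULT_CHROM_LENGTHS
    markers_per_chromosome: int = 30
    shared_marker_fraction: float = 0.6
    marker_jitter_sd: float = 0.5  # cM
    true_mqtls_per_chromosome: int = 3
    detection_prob: float = 0.6
    position_noise_sd: float = 2.0  # cM
    ci_mean: float = 10.88  # cM, matches the source studies' mean original CI
    ci_sd: float = 4.0  # truncated below at 1 cM
    spurious_rate: float = 0.05  # per population x chromosome x locus slot
    trait_pool: tuple[str, ...] = (
        "Zn", "Fe", "Mn", "K", "P", "Ca", "Mg", "Cu", "B", "Na",
        "S", "Se", "Mo", "rsZn", "shFe", "rsMn",
    )
    cooccur_prob: float = 0.5  # P(Fe | Zn planted) etc. within the Zn/Fe/Mn trio
    extra_trait_prob: float = 0.2
    n_genes_per_chromosome: int = 1500
    bp_per_cm: float = 250_000.0
    centromere_fraction: float = 0.4  # position of the centromere along each chromosome
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.detection_prob <= 1 and 0 <= self.shared_marker_fraction <= 1
                and 0 <= self.spurious_rate <= 1 and 0 <= self.cooccur_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if min(self.position_noise_sd, self.ci_sd, self.ci_mean) <= 0 and self.position_noise_sd != 0:
            raise ValueError("scales must be positive")
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise ValueError("chromosome_lengths must match n_chromosomes")

    def chromosomes(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]


@dataclass
class SimulationTruth:
    #: chromosome -> array of true locus positions (cM)
    positions: dict[str, np.ndarray]
    #: chromosome -> list of trait sets, one per true locus
    trait_sets: dict[str, list[frozenset[str]]]
    #: qtl_id -> (chromosome, locus index) or None for spurious QTLs
    links: dict[str, tuple[str, int] | None] = field(default_factory=dict)


def _backbone(config: SimulationConfig, rng: np.random.Generator) -> dict[str, list[tuple[str, float]]]:
    """Evenly spaced backbone markers per chromosome (consumed first)."""
    backbone: dict[str, list[tuple[str, float]]] = {}
    for ci, chrom in enumerate(config.chromosomes()):
        length = config.chromosome_lengths[ci]
        m = config.markers_per_chromosome
        pos = np.linspace(0, length, m)
        backbone[chrom] = [(f"M{chrom}_{j:03d}", float(p)) for j, p in enumerate(pos)]
    return backbone


def _jitter_monotone(pos: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Jitter positions, resampling until the order is preserved (cap 100)."""
    if sd == 0:
        return pos.copy()
    for _ in range(100):
        jittered = np.maximum(pos + rng.normal(0, sd, size=len(pos)), 0.0)
        if np.all(np.diff(jittered) > 0):
            return jittered
    return np.maximum(np.sort(pos + rng.normal(0, sd, size=len(pos))), 0.0)


def simulate_maps(config: SimulationConfig) -> list[GeneticMap]:
    """Per-population genetic maps drawn from a shared backbone.

    A guaranteed ``shared_marker_fraction`` core of backbone markers appears
    in every population; each remaining marker is included per population
    with probability 0.5; positions are jittered Normal(0, marker_jitter_sd)
    preserving order.
    """
    rng = np.random.default_rng(config.seed)
    backbone = _backbone(config, rng)
    m = config.markers_per_chromosome
    n_shared = max(2, int(np.ceil(config.shared_marker_fraction * m)))
    shared_idx: dict[str, np.ndarray] = {
        chrom: np.sort(rng.choice(m, size=n_shared, replace=False))
        for chrom in config.chromosomes()
    }
    maps: list[GeneticMap] = []
    for p in range(config.n_populations):
        pop = f"pop{p + 1:02d}"
        markers: list[MarkerPosition] = []
        for chrom in config.chromosomes():
            names_pos = backbone[chrom]
            keep = set(shared_idx[chrom].tolist())
            for j in range(m):
                if j not in keep and rng.random() < 0.5:
                    keep.add(j)
            idx = sorted(keep)
            base = np.array([names_pos[j][1] for j in idx])
            jittered = _jitter_monotone(base, config.marker_jitter_sd, rng)
            for j, posn in zip(idx, jittered):
                markers.append(MarkerPosition(
                    marker_name=names_pos[j][0], linkage_group=chrom, position=float(posn),
                ))
        maps.append(GeneticMap(population_id=pop, markers=markers))
    return maps


def _plant_loci(config: SimulationConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """True locus positions: one per equal chromosome segment, drawn uniformly
    from the central 60% of its segment so neighbours stay well separated."""
    positions: dict[str, np.ndarray] = {}
    for ci, chrom in enumerate(config.chromosomes()):
        length = config.chromosome_lengths[ci]
        k = config.true_mqtls_per_chromosome
        seg = length / k
        pos = np.array([
            (i + 0.2 + 0.6 * rng.random()) * seg for i in range(k)
        ])
        positions[chrom] = pos
    return positions


def _sample_trait_set(config: SimulationConfig, rng: np.random.Generator) -> frozenset[str]:
    pool = list(config.trait_pool)
    base = pool[int(rng.integers(len(pool)))]
    traits = {base}
    trio = ("Zn", "Fe", "Mn")
    if base in trio:
        for other in trio:
            if other != base and rng.random() < config.cooccur_prob:
                traits.add(other)
    for t in pool:
        if t not in traits and rng.random() < config.extra_trait_prob:
            traits.add(t)
    return frozenset(traits)


def simulate_qtls(
    config: SimulationConfig, maps: list[GeneticMap]
) -> tuple[list[QTLRecord], SimulationTruth]:
    """Emit per-population QTLs around the planted loci.

    For each population x locus, a QTL is detected with ``detection_prob``.
    Its 95% CI width is a truncated Normal(ci_mean, ci_sd) (> 1 cM) and its
    peak is the true position plus Normal(0, sd_i) where
    sd_i = position_noise_sd * (width_i / ci_mean): a study's peak error
    scales with its own reported precision (peak and CI come from the same
    data in a real study), and the error sd averages position_noise_sd at
    the mean CI width.  The CI is centred on the peak and clamped to the
    chromosome.  Peak and CI are reported in the population's *own* map
    coordinates (through the backbone→population marker correspondence),
    as a real study reports positions on its own map.  Spurious (unlinked)
    QTLs appear per population x locus slot with probability
    ``spurious_rate``, uniform on the chromosome.
    """
    # draws must not depend on map jitter: fresh stream, offset seed
    rng = np.random.default_rng(config.seed + 1_000_003)
    truth = SimulationTruth(positions=_plant_loci(config, rng), trait_sets={})
    for chrom in config.chromosomes():
        truth.trait_sets[chrom] = [
            _sample_trait_set(config, rng)
            for _ in range(config.true_mqtls_per_chromosome)
        ]

    backbone = _backbone(config, rng)
    backbone_pos = {chrom: {name: p for name, p in backbone[chrom]}
                    for chrom in config.chromosomes()}

    qtls: list[QTLRecord] = []
    counter = 0
    for gmap in maps:
        # backbone→own-map coordinate correspondence per chromosome
        own: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in config.chromosomes():
            group = gmap.group(chrom)
            b = np.array([backbone_pos[chrom][m.marker_name] for m in group])
            p = np.array([m.position for m in group])
            order = np.argsort(b)
            own[chrom] = (b[order], p[order])
        for ci, chrom in enumerate(config.chromosomes()):
            length = config.chromosome_lengths[ci]
            b_vec, p_vec = own[chrom]

            def to_own(x: float) -> float:
                # terminal-slope extrapolation beyond the population's first/
                # last marker; plain interp would collapse outlying CIs
                return float(_piecewise_transform(b_vec, p_vec, np.array([x]))[0])
            for k in range(config.true_mqtls_per_chromosome):
                detected = rng.random() < config.detection_prob
                if detected:
                    width = 0.0
                    while width <= 1.0:
                        width = rng.normal(config.ci_mean, config.ci_sd)
                    noise_sd = config.position_noise_sd * (width / config.ci_mean)
                    peak_b = float(np.clip(
                        truth.positions[chrom][k] + rng.normal(0, noise_sd), 0, length))
                    peak = to_own(peak_b)
                    lo = to_own(float(np.clip(peak_b - width / 2, 0, length)))
                    hi = to_own(float(np.clip(peak_b + width / 2, 0, length)))
                    trait_set = sorted(truth.trait_sets[chrom][k])
                    trait = trait_set[int(rng.integers(len(trait_set)))]
                    counter += 1
                    qid = f"q{counter:04d}"
                    qtls.append(QTLRecord(
                        qtl_id=qid, population_id=gmap.population_id, trait=trait,
                        linkage_group=chrom, peak=peak, ci_lo=lo, ci_hi=hi,
                        lod=float(3 + rng.exponential(2)),
                        r2_pct=float(np.clip(rng.normal(8, 4), 1, 60)),
                    ))
                    truth.links[qid] = (chrom, k)
                if rng.random() < config.spurious_rate:
                    peak_b = float(rng.uniform(0, length))
                    width = 0.0
                    while width <= 1.0:
                        width = rng.normal(config.ci_mean, config.ci_sd)
                    peak = to_own(peak_b)
                    lo = to_own(float(np.clip(peak_b - width / 2, 0, length)))
                    hi = to_own(float(np.clip(peak_b + width / 2, 0, length)))
                    trait = config.trait_pool[int(rng.integers(len(config.trait_pool)))]
                    counter += 1
                    qid = f"q{counter:04d}"
                    qtls.append(QTLRecord(
                        qtl_id=qid, population_id=gmap.population_id, trait=trait,
                        linkage_group=chrom, peak=peak, ci_lo=lo, ci_hi=hi,
                        lod=float(3 + rng.exponential(1)),
                        r2_pct=float(np.clip(rng.normal(5, 2), 1, 30)),
                    ))
                    truth.links[qid] = None
    return qtls, truth


def simulate_gff(
    config: SimulationConfig,
) -> tuple[list[GeneRecord], list[MarkerAnchor], dict[str, float]]:
    """A toy gene annotation plus a monotone marker→bp anchor table.

    Genes are placed by rejection sampling with acceptance weight
    0.15 + 0.85 * (distance from centromere / arm length), reproducing the
    depleted-centromere, enriched-(sub)telomere density of real plant
    genomes.  Returns (genes, anchors, physical centromere positions in Mb).
    """
    rng = np.random.default_rng(config.seed + 2_000_003)
    backbone = _backbone(config, rng)
    genes: list[GeneRecord] = []
    anchors: list[MarkerAnchor] = []
    centromeres_mb: dict[str, float] = {}
    for ci, chrom in enumerate(config.chromosomes()):
        length_cm = config.chromosome_lengths[ci]
        length_bp = length_cm * config.bp_per_cm
        cen_bp = config.centromere_fraction * length_bp
        centromeres_mb[chrom] = cen_bp / 1e6
        d_max = max(cen_bp, length_bp - cen_bp)
        placed = 0
        while placed < config.n_genes_per_chromosome:
            x = rng.uniform(0, length_bp)
            w = 0.15 + 0.85 * abs(x - cen_bp) / d_max
            if rng.random() < w:
                start = int(x) + 1
                gene_len = int(rng.uniform(1500, 4000))
                placed += 1
                genes.append(GeneRecord(
                    gene_id=f"G{chrom}g{placed:05d}", chromosome=chrom,
                    start_bp=start, end_bp=start + gene_len,
                    strand="+" if rng.random() < 0.5 else "-",
                ))
        for name, pos_cm in backbone[chrom]:
            start = max(int(round(pos_cm * config.bp_per_cm)), 1)
            anchors.append(MarkerAnchor(
                marker_name=name, chromosome=chrom,
                start_bp=start, end_bp=start + 500,
            ))
    genes.sort(key=lambda g: (g.chromosome, g.start_bp))
    return genes, anchors, centromeres_mb


def write_gff3(genes: list[GeneRecord], path) -> None:
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"Chr{g.chromosome}\tsim\tgene\t{g.start_bp}\t{g.end_bp}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_anchor_table(anchors: list[MarkerAnchor], path) -> None:
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("marker\tchromosome\tstart_bp\tend_bp\n")
        for a in anchors:
            fh.write(f"{a.marker_name}\t{a.chromosome}\t{a.start_bp}\t{a.end_bp}\n")
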