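#!/usr/bin/env python
"""Build the consensus map from the simulated population maps and project
every QTL onto it.

Writes the consensus map (with provenance), the projected QTL table and a
per-population projection report under results/, and prints the
Hubert–Hedgecock adjusted genome length of the consensus.
"""

from pathlib import Path

from ionmqtl.consensus_map import build_consensus, genome_length, map_summary
from ionmqtl.qtl_database import read_genetic_map, read_qtl_table
from ionmqtl.qtl_projection import project_all

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM = ROOT / "sim"


def main() -> None:
    maps = [read_genetic_map(f) for f in sorted(SIM.glob("map_*.tsv"))]
    qtls = read_qtl_table(SIM / "qtls.tsv")

    consensus = build_consensus(maps)
    summ = map_summary(consensus)
    gl = genome_length(consensus)
    with (ROOT / "consensus_map.tsv").open("w") as fh:
        fh.write("linkage_group\tmarker\tposition_cM\tn_source_populations\n")
        for m in consensus.markers:
            prov = consensus.provenance[(m.marker_name, m.linkage_group)]
            fh.write(f"{m.linkage_group}\t{m.marker_name}\t{m.position:.4f}\t{len(prov)}\n")

    projected, report = project_all(qtls, {m.population_id: m for m in maps}, consensus)
    with (ROOT / "projected_qtls.tsv").open("w") as fh:
        fh.write("qtl_id\tpopulation_id\ttrait\tlinkage_group\tpeak_cM\t"
                 "ci_lo_cM\tci_hi_cM\tsd_cM\n")
        for p in projected:
            s = p.source
            fh.write(f"{s.qtl_id}\t{s.population_id}\t{s.trait}\t{s.linkage_group}\t"
                     f"{p.peak_c:.4f}\t{p.ci_lo_c:.4f}\t{p.ci_hi_c:.4f}\t{p.sd:.4f}\n")

    print(f"consensus: {summ['total_markers']} markers over "
          f"{summ['total_length_cM']:.2f} cM raw / {gl.total_adjusted:.2f} cM adjusted "
          f"(chi = {gl.chi:.3f} cM)")
    print(f"projected {report.n_projected} QTLs, skipped {len(report.skipped)}")


if __name__ == "__main__":
    main()
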