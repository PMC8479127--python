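#!/usr/bin/env python
"""Generate a synthetic 12-population ionomic QTL study and write its files.

Emulates the scale of the published study pool: 12 RIL populations, five
chromosomes, ~30 markers each, three planted loci per chromosome, 60%
detection probability, original CIs averaging 10.88 cM.  Writes per-
population map TSVs, the pooled QTL table, a toy gene annotation, marker
anchors and the ground truth under results/sim/.
"""

import json
from pathlib import Path

from ionmqtl.qtl_database import write_genetic_map, write_qtl_table
from ionmqtl.synthetic_data import (
    SimulationConfig,
    simulate_gff,
    simulate_maps,
    simulate_qtls,
    write_anchor_table,
    write_gff3,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(seed=seed)
    maps = simulate_maps(config)
    qtls, truth = simulate_qtls(config, maps)
    genes, anchors, centromeres = simulate_gff(config)

    for gmap in maps:
        write_genetic_map(gmap, OUT / f"map_{gmap.population_id}.tsv")
    write_qtl_table(qtls, OUT / "qtls.tsv")
    write_gff3(genes, OUT / "genes.gff3")
    write_anchor_table(anchors, OUT / "anchors.tsv")
    (OUT / "truth.json").write_text(json.dumps({
        "positions": {c: list(map(float, p)) for c, p in truth.positions.items()},
        "links": {q: list(l) if l else None for q, l in truth.links.items()},
        "centromeres_mb": centromeres,
    }, indent=1))

    n_linked = sum(1 for v in truth.links.values() if v is not None)
    print(f"{len(maps)} population maps, {len(qtls)} QTLs "
          f"({n_linked} linked to {5 * config.true_mqtls_per_chromosome} planted loci, "
          f"{len(qtls) - n_linked} spurious), {len(genes)} genes -> {OUT}")


if __name__ == "__main__":
    main()
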