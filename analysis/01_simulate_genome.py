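#!/usr/bin/env python
"""Simulate the desk-scale study system and write its raw inputs.

Emits the synthetic genome (FASTA), gene annotation (GFF3), repeat
annotation (BED), strand-specific expression (bedGraph x2), Hi-C valid
pairs and the ground-truth JSON under results/sim/.  Every later driver
consumes these files or regenerates the same data from the same seed.
"""

import dataclasses
import json
from pathlib import Path

from dinochrom import genome_io as gio
from dinochrom import simulate as sim

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = sim.SyntheticSpec(seed=SEED)
    assembly, genes, repeats, truth = sim.generate_genome(spec, sequence=True)
    pairs = sim.generate_contacts(assembly, truth, spec)
    plus, minus = sim.generate_expression(genes, truth, spec)

    gio.write_fasta(assembly, OUT / "genome.fa")
    gio.write_gff3_genes(genes, OUT / "genes.gff3")
    gio.write_bed(repeats, OUT / "repeats.bed")
    gio.write_bedgraph(plus, OUT / "expr_plus.bedgraph")
    gio.write_bedgraph(minus, OUT / "expr_minus.bedgraph")
    gio.write_pairs(pairs, OUT / "contacts.pairs", assembly.lengths)
    (OUT / "truth.json").write_text(
        json.dumps(
            {
                "chrom_lengths": truth.chrom_lengths,
                "boundaries": {c: v.tolist() for c, v in truth.boundaries.items()},
                "divergent": {c: v.tolist() for c, v in truth.divergent.items()},
                "spec": dataclasses.asdict(spec),
            },
            indent=1,
        )
    )
    n_bnd = sum(len(v) for v in truth.boundaries.values())
    print(
        f"simulated {len(assembly)} chromosomes "
        f"({sum(L for _, L in assembly.chromosomes)/1e6:.0f} Mb), "
        f"{len(genes)} genes, {n_bnd} planted boundaries, "
        f"{len(pairs)} valid pairs -> {OUT}"
    )


if __name__ == "__main__":
    main()
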