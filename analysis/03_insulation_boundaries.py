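#!/usr/bin/env python
"""Insulation profiles and domain boundaries, control versus treated.

Runs the boundary-calling pipeline on the desk genome for control and
transcription-blocked conditions over five seeds, writes the boundary
calls (BED), insulation profile (bedGraph) and a recovery summary.
"""

from pathlib import Path

import pandas as pd

from dinochrom import benchmarks as bm
from dinochrom import genome_io as gio
from dinochrom import insulation as ins
from dinochrom import simulate as sim

OUT = Path(__file__).resolve().parents[1] / "results"
SEEDS = range(1, 6)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    # one representative run's tracks on disk
    spec = sim.SyntheticSpec(seed=SEEDS[0])
    _, truth, _, matrix, boundaries = bm.run_boundary_pipeline(spec)
    prof = ins.insulation_score(matrix)
    gio.write_bedgraph(
        prof.table.rename(columns={"score": "value"})[
            ["chrom", "start", "end", "value"]
        ],
        OUT / "insulation.bedgraph",
    )
    bed = boundaries.rename(columns={"strength": "score"})
    bed["name"] = "boundary"
    gio.write_bed(bed, OUT / "boundaries.bed")

    r = bm.boundary_recovery_study(SEEDS)
    pd.DataFrame([r]).to_csv(OUT / "boundary_recovery.tsv", sep="\t", index=False)
    print(
        f"boundary calling over {len(list(SEEDS))} seeds: "
        f"recall {r['recall']:.3f}, precision {r['precision']:.3f} "
        f"({r['n_called']} calls vs {r['n_true']} planted)"
    )
    print(
        "transcription-blocked condition retains "
        f"{100 * r['treated_fraction']:.1f}% of planted-position calls "
        "(boundaries disappear without the convergent-transcription block)"
    )


if __name__ == "__main__":
    main()
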