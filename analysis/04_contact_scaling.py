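#!/usr/bin/env python
"""Contact-probability scaling: regimes, rod cutoff, terminal domains, gaps.

Computes genome-wide P(s) at full scale (3-Mb rod cutoff), segments the
three regimes, locates the drop, compares terminal with internal domains,
and recovers a planted inter-domain spacer.  Writes the curve, a fit
report and a figure.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from dinochrom import benchmarks as bm
from dinochrom import scaling as sca
from dinochrom import simulate as sim

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = sim.SyntheticSpec(
        seed=2, beta=1.0, tau=1.0, stripe_factor=1.0, d_max=3_000_000
    )
    asm, _, _, truth = sim.generate_genome(spec, sequence=False)
    pairs = sim.generate_contacts(asm, truth, spec)
    curve = sca.ps_from_pairs(pairs, asm)
    slope, err = sca.fit_exponent(curve, (50_000, 0.8 * spec.d_max))
    drop = sca.detect_drop(curve)
    keep = curve.s >= spec.artifact_smax
    sub = sca.ScalingCurve(s=curve.s[keep], P=curve.P[keep], n_obs=curve.n_obs[keep])
    fit = sca.segment_regimes(sub)

    pd.DataFrame({"s": curve.s, "P": curve.P, "n_obs": curve.n_obs}).to_csv(
        OUT / "ps_curve.tsv", sep="\t", index=False
    )
    report = {
        "regime2_exponent": slope,
        "regime2_stderr": err,
        "rod_cutoff_bp": drop,
        "segment_breakpoints_bp": fit.breakpoints.tolist(),
        "segment_slopes": fit.slopes.tolist(),
    }

    ter = bm.terminal_compaction_study(seed=5)
    report["terminal_internal_ratio"] = ter["ratio"]
    report["terminal_exponent"] = ter["exponents"].get("terminal")
    report["internal_exponent"] = ter["exponents"].get("internal")

    gap = bm.gap_shift_study(seed=4)
    report["gap_shift_bp"] = gap["shift"]
    report["gap_planted_bp"] = gap["planted"]

    (OUT / "ps_fit.json").write_text(json.dumps(report, indent=1))

    fig, ax = plt.subplots(figsize=(5, 4))
    ok = curve.populated()
    ax.loglog(curve.s[ok], curve.P[ok], "k.", ms=3)
    ax.axvline(drop, color="r", ls="--", lw=0.8, label=f"cutoff {drop/1e6:.2f} Mb")
    ax.set_xlabel("genomic separation s (bp)")
    ax.set_ylabel("contact probability P(s)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(OUT / "ps_curve.png", dpi=150)

    print(
        f"P(s): regime II exponent {slope:.3f} +/- {err:.3f}, "
        f"rod cutoff at {drop/1e6:.2f} Mb "
        f"(the decay is shallow out to the cutoff, then drops sharply)"
    )
    print(
        f"terminal domains {ter['ratio']:.2f}x internal at s <= 1 Mb; "
        f"per-class exponents {report['terminal_exponent']:.2f} / "
        f"{report['internal_exponent']:.2f}"
    )
    print(
        f"planted 500-kb inter-domain spacer recovered as "
        f"{gap['shift']/1e3:.0f} kb shift"
    )


if __name__ == "__main__":
    main()
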