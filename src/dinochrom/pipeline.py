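"""End-to-end pipeline driver: one YAML config, staged execution, provenance.

Stages run in dependency order (simulate -> matrix -> insulation ->
scaling -> pileup); every stage communicates with the next only through
declared file formats, and the manifest records a content hash for every
artifact so a rerun with the same config and seed is verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from . import genome_io, insulation, pileups, scaling, simulate

log = logging.getLogger("dinochrom")


class StageToggles(BaseModel):
    model_config = ConfigDict(extra="forbid")
    simulate: bool = True
    matrix: bool = True
    insulation: bool = True
    scaling: bool = True
    pileup: bool = True


class SimulateParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_chromosomes: int = 4
    chrom_length: int = 10_000_000
    domain_size: int = 2_500_000
    alpha: float = -0.4
    d_max: int = 1_000_000
    beta: float = 0.5
    tau: float = 2.0
    n_pairs: int = 1_000_000
    treated: bool = False
    sequence: bool = False


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: str = "dinochrom_out"
    stages: StageToggles = StageToggles()
    simulate: SimulateParams = SimulateParams()
    pairs_file: str | None = None
    resolution: int = 10_000
    balance_tol: float = 1e-5
    balance_max_iter: int = 500
    mad_filter: float = 5.0
    insulation_window: int = 500_000
    delta_span: int = 100_000
    strength_min: float = 0.2
    pileup_flank: int = 500_000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and return a manifest of hashed artifacts.

    A stage failure raises with the stage named; artifacts written before
    the failure are kept.  Identical config and seed reproduce identical
    hashes for the deterministic stages.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.model_dump(), "artifacts": {}, "stages": []}
    (out / "config_echo.yaml").write_text(yaml.safe_dump(config.model_dump()))

    def record(name: str, path: Path):
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    assembly = truth = pairs = matrix = boundaries = None
    try:
        if config.stages.simulate:
            stage = "simulate"
            sp = config.simulate
            spec = simulate.SyntheticSpec(
                seed=config.seed,
                n_chromosomes=sp.n_chromosomes,
                chrom_length=sp.chrom_length,
                domain_size=sp.domain_size,
                alpha=sp.alpha,
                d_max=sp.d_max,
                beta=sp.beta,
                tau=sp.tau,
                n_pairs=sp.n_pairs,
            )
            if sp.treated:
                spec = simulate.apply_treatment(spec)
            assembly, genes, repeats, truth = simulate.generate_genome(
                spec, sequence=sp.sequence
            )
            pairs = simulate.generate_contacts(assembly, truth, spec)
            genome_io.write_pairs(pairs, out / "contacts.pairs", assembly.lengths)
            genome_io.write_gff3_genes(genes, out / "genes.gff3")
            genome_io.write_bed(repeats, out / "repeats.bed")
            truth_json = {
                "boundaries": {c: v.tolist() for c, v in truth.boundaries.items()},
                "divergent": {c: v.tolist() for c, v in truth.divergent.items()},
                "chrom_lengths": truth.chrom_lengths,
                "params": dataclasses.asdict(spec),
            }
            (out / "truth.json").write_text(json.dumps(truth_json, indent=1))
            for name in ("contacts.pairs", "genes.gff3", "repeats.bed", "truth.json"):
                record(name, out / name)
            log.info("simulate: %d pairs, %d genes", len(pairs), len(genes))
            manifest["stages"].append(stage)

        if config.stages.matrix:
            stage = "matrix"
            if pairs is None:
                if config.pairs_file is None:
                    raise FileNotFoundError("matrix stage needs pairs_file or simulate")
                pairs = genome_io.read_pairs(config.pairs_file)
            if assembly is None:
                raise FileNotFoundError("matrix stage needs chromosome lengths")
            bt = genome_io.bin_genome(assembly, config.resolution)
            matrix, n_disc = genome_io.pairs_to_matrix(pairs, bt)
            matrix = genome_io.ice_balance(
                matrix,
                max_iter=config.balance_max_iter,
                tol=config.balance_tol,
                mad_filter=config.mad_filter,
            )
            genome_io.write_cool(matrix, out / "contacts.cool")
            record("contacts.cool", out / "contacts.cool")
            log.info("matrix: %d bins, %d discarded pairs", bt.n_bins, n_disc)
            manifest["stages"].append(stage)

        if config.stages.insulation:
            stage = "insulation"
            if matrix is None:
                raise FileNotFoundError("insulation stage needs the matrix stage")
            cfg = insulation.InsulationConfig(
                window=config.insulation_window,
                resolution=config.resolution,
                delta_span=config.delta_span,
                strength_min=config.strength_min,
            )
            prof = insulation.insulation_score(matrix, cfg)
            boundaries = insulation.refine_boundaries(
                insulation.call_boundaries(prof, cfg), prof
            )
            genome_io.write_bedgraph(
                prof.table.rename(columns={"score": "value"})[
                    ["chrom", "start", "end", "value"]
                ],
                out / "insulation.bedgraph",
            )
            bed = boundaries.rename(columns={"strength": "score"})
            bed["name"] = "boundary"
            genome_io.write_bed(bed, out / "boundaries.bed")
            record("insulation.bedgraph", out / "insulation.bedgraph")
            record("boundaries.bed", out / "boundaries.bed")
            log.info("insulation: %d boundaries", len(boundaries))
            manifest["stages"].append(stage)

        if config.stages.scaling:
            stage = "scaling"
            if pairs is None or assembly is None:
                raise FileNotFoundError("scaling stage needs pairs")
            curve = scaling.ps_from_pairs(pairs, assembly)
            fit = scaling.segment_regimes(curve)
            import pandas as pd

            pd.DataFrame(
                {"s": curve.s, "P": curve.P, "n_obs": curve.n_obs}
            ).to_csv(out / "ps_curve.tsv", sep="\t", index=False)
            (out / "ps_fit.json").write_text(
                json.dumps(
                    {
                        "breakpoints": fit.breakpoints.tolist(),
                        "slopes": fit.slopes.tolist(),
                        "collapsed": fit.collapsed,
                    },
                    indent=1,
                )
            )
            record("ps_curve.tsv", out / "ps_curve.tsv")
            record("ps_fit.json", out / "ps_fit.json")
            manifest["stages"].append(stage)

        if config.stages.pileup:
            stage = "pileup"
            if matrix is None or boundaries is None:
                raise FileNotFoundError("pileup stage needs matrix and boundaries")
            if len(boundaries):
                exp = pileups.expected_by_distance(matrix)
                pu = pileups.pileup(
                    matrix,
                    boundaries,
                    exp,
                    flank=config.pileup_flank,
                    resolution=config.resolution,
                )
                import pandas as pd

                pd.DataFrame(pu.log10).to_csv(
                    out / "pileup_boundaries.tsv", sep="\t", index=False
                )
                record("pileup_boundaries.tsv", out / "pileup_boundaries.tsv")
                log.info("pileup: %d sites (%d dropped)", pu.n_sites, pu.n_dropped)
            manifest["stages"].append(stage)
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
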