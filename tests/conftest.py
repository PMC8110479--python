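"""Shared fixtures: one desk-scale simulated dataset reused across modules.

The desk profile (4 rod chromosomes, 40 Mb, boundary spacing ~2.5 Mb,
rod cutoff 1 Mb, 1e6 pairs) is expensive enough that the sampled matrix is
built once per session.
"""

from __future__ import annotations

from types import SimpleNamespace

import pandas as pd
import pytest

from dinochrom import genome_io as gio
from dinochrom import insulation as ins
from dinochrom import simulate as sim

DESK_SEED = 1
RES = 10_000


def build_desk(seed: int, treated: bool = False, **overrides) -> SimpleNamespace:
    """Generate a desk-profile dataset and run binning/balancing/insulation."""
    spec = sim.SyntheticSpec(seed=seed, **overrides)
    if treated:
        spec = sim.apply_treatment(spec)
    assembly, genes, repeats, truth = sim.generate_genome(spec, sequence=False)
    pairs = sim.generate_contacts(assembly, truth, spec)
    bt = gio.bin_genome(assembly, RES)
    matrix, n_discarded = gio.pairs_to_matrix(pairs, bt)
    matrix = gio.ice_balance(matrix)
    profile = ins.insulation_score(matrix)
    boundaries = ins.refine_boundaries(ins.call_boundaries(profile), profile)
    return SimpleNamespace(
        spec=spec,
        assembly=assembly,
        genes=genes,
        repeats=repeats,
        truth=truth,
        pairs=pairs,
        matrix=matrix,
        profile=profile,
        boundaries=boundaries,
        n_discarded=n_discarded,
    )


@pytest.fixture(scope="session")
def desk() -> SimpleNamespace:
    return build_desk(DESK_SEED)


@pytest.fixture(scope="session")
def desk_oracle(desk) -> gio.ContactMatrix:
    """Expectation-level matrix of the same truth, balanced identically."""
    return gio.ice_balance(sim.expected_contact_matrix(desk.truth, RES))


@pytest.fixture(scope="session")
def desk_genes() -> SimpleNamespace:
    """Genome + annotation + expression only (no Hi-C), with sequence."""
    spec = sim.SyntheticSpec(seed=7)
    assembly, genes, repeats, truth = sim.generate_genome(spec, sequence=True)
    plus, minus = sim.generate_expression(genes, truth, spec)
    return SimpleNamespace(
        spec=spec,
        assembly=assembly,
        genes=genes,
        repeats=repeats,
        truth=truth,
        plus=plus,
        minus=minus,
    )


def site_frame(positions: dict, kind: str | None = None) -> pd.DataFrame:
    rows = [(c, int(p)) for c, v in positions.items() for p in v]
    df = pd.DataFrame(rows, columns=["chrom", "position"])
    if kind:
        df["kind"] = kind
    return df
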