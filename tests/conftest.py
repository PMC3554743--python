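"""Shared fixtures: one synthetic study and one full pipeline run per session."""

from __future__ import annotations

import pytest

from mirseqkit import RunConfig, run_pipeline
from mirseqkit.simulate import SimConfig, build_genome, simulate_libraries

#: planted fold changes for the standard test study (library B over A)
STANDARD_FC = {"mir-1": 3.0, "mir-2": -3.0, "hidden-1": 2.5}


def standard_sim_config(seed: int = 5) -> SimConfig:
    return SimConfig(
        genome_length=40_000,
        n_known_mirnas=8,
        n_hidden_hairpins=4,
        library_sizes=(20_000, 20_000),
        log2_fc_table=dict(STANDARD_FC),
        seed=seed,
    )


@pytest.fixture(scope="session")
def sim():
    """Standard synthetic genome with its two read libraries drawn."""
    s = build_genome(standard_sim_config())
    lib_a, lib_b = simulate_libraries(s)
    return s, lib_a, lib_b


@pytest.fixture(scope="session")
def run_dir(tmp_path_factory):
    """A complete pipeline run over the standard study (same config/seed)."""
    out = tmp_path_factory.mktemp("standard_run")
    cfg = RunConfig(sim=standard_sim_config())
    run_pipeline(cfg, out)
    return out
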