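"""Shared fixtures: small synthetic genome sets and one full study run.

Simulation sizes here are deliberately small (few genomes, short proteins)
so the whole suite stays fast; the generator is the same code that produces
the full study-shaped set.
"""

from pathlib import Path

import pytest

from seldscope import RunConfig, run_study, simulate
from seldscope.synthetic_data import (
    FusionPlan,
    NeighborhoodPlan,
    SimConfig,
    default_study_config,
)

DATA_DIR = Path(__file__).parent / "data"


def small_config(seed: int = 11, **overrides) -> SimConfig:
    """A scaled-down study-shaped configuration for unit tests."""
    tp_pos = ("TP01", "TP02", "TP03", "TP04")
    tp_neg = ("TP05", "TP06")
    su = ("SU01", "SU02")
    defaults = dict(
        seed=seed,
        clades=(
            ("Thermoproteales", tp_pos + tp_neg),
            ("Sulfolobales", su),
            ("Methanococcales", ("MC01",)),
            ("Halobacteriales", ("HB01",)),
        ),
        n_background_families=12,
        protein_length=(60, 100),
        substitution_rate=0.05,
        trait_plantings=(
            ("MC01", frozenset({"SelD", "SelA", "SelB", "YbbB"})),
            ("HB01", frozenset({"SelD", "YqeB", "YqeC"})),
        ),
        exclusive_gene=(frozenset(tp_pos), frozenset(tp_neg)),
        neighborhood_plan=NeighborhoodPlan(
            genomes=frozenset(tp_pos + su), window_nt=10_000
        ),
        fusion_plan=FusionPlan(genomes=frozenset(tp_pos)),
        intergenic_range=(100, 600),
        reference_genome="TP01",
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    """(GenomeSet, GroundTruth) for the scaled-down configuration."""
    return simulate(small_config())


@pytest.fixture(scope="session")
def study_report(tmp_path_factory):
    """One full end-to-end run of the default study configuration."""
    out = tmp_path_factory.mktemp("study")
    return run_study(RunConfig(seed=7, out_dir=out, bootstrap_replicates=100)), out


@pytest.fixture
def data_dir() -> Path:
    return DATA_DIR
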