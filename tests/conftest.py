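import shutil

import pytest

from rnavista.io import build_master_table
from rnavista.simulate import FixtureConfig, PlantedProfile, \
    generate_experiment, generate_minimal_demo
from rnavista.workflows import run_pipeline_on_bundle


@pytest.fixture(scope="session")
def demo_bundle():
    """The shipped 3x3 demonstration bundle (seeded)."""
    return generate_minimal_demo(seed=1)


@pytest.fixture(scope="session")
def demo_master(demo_bundle):
    return build_master_table(demo_bundle.sheet, demo_bundle.em,
                              demo_bundle.comparisons, demo_bundle.background)


@pytest.fixture(scope="session")
def strong_bundle():
    """A higher-replicate design where per-gene calls are near-certain,
    used by recovery-style checks that isolate downstream behaviour."""
    cfg = FixtureConfig(
        seed=5, n_genes=600, n_groups=3, reps_per_group=12,
        profiles=[PlantedProfile(("up", "ns"), 60),
                  PlantedProfile(("ns", "up"), 60),
                  PlantedProfile(("up", "down"), 60),
                  PlantedProfile(("down", "up"), 60)],
        n_enriched_sets=2, n_null_sets=10, set_size=40)
    return generate_experiment(cfg)


@pytest.fixture(scope="session")
def strong_master(strong_bundle):
    return build_master_table(strong_bundle.sheet, strong_bundle.em,
                              strong_bundle.comparisons,
                              strong_bundle.background)


@pytest.fixture(scope="session")
def demo_run(demo_bundle, tmp_path_factory):
    """One full default pipeline run on the demo bundle (reused widely)."""
    outdir = tmp_path_factory.mktemp("demo_run")
    manifest = run_pipeline_on_bundle(demo_bundle, outdir, seed=1)
    return outdir, manifest
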