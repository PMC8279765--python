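import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from pestiscan.cli_io import FixtureSpec, generate_family_fixture
from pestiscan.model_builder import build_pipeline, calibrate_cutoff

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def family_fixture():
    spec = FixtureSpec(
        seed=FIXTURE_SEED, n_families=3, family_size=6, family_length=120,
        divergence=0.15, n_decoys=10, genome_length=30000,
    )
    families, decoys, labels = generate_family_fixture(spec)
    return spec, families, decoys, labels


@pytest.fixture(scope="session")
def built_collection(family_fixture):
    """Models built and calibrated from the session family fixture."""
    spec, families, decoys, labels = family_fixture
    members = [r for fam in families.values() for r in fam]
    models, clusters, dedup = build_pipeline(members, min_size=5)
    calibrated = []
    member_clusters = []
    for model, cluster in zip(models, clusters.clusters):
        pos = [r for r in members if r.id in cluster]
        report = calibrate_cutoff(model, pos, decoys)
        calibrated.append(model.with_cutoff(report.proposed_cutoff))
        member_clusters.append(sorted(cluster))
    return {
        "spec": spec,
        "members": members,
        "decoys": decoys,
        "models": calibrated,
        "clusters": member_clusters,
    }
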