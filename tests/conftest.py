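import pytest

from sgbforge.config import PipelineConfig
from sgbforge.pipeline import cluster_genomes
from sgbforge.records import QualityMetrics, SpeciesSpec
from sgbforge.synthetic import build_community, generate_species


@pytest.fixture(scope="session")
def ancestor():
    """One 100-kb ancestral genome at 40% GC, reused across modules."""
    spec = SpeciesSpec("spA", 100_000, 0.40, [0.01])
    return generate_species(spec, seed=1)


@pytest.fixture(scope="session")
def community():
    """The default 20-species community plus its planted truth."""
    genomes, metrics, truth = build_community(seed=11)
    qmetrics = {
        gid: QualityMetrics(genome_id=gid, **m) for gid, m in metrics.items()
    }
    return genomes, qmetrics, truth


@pytest.fixture(scope="session")
def community_result(community):
    """Full clustering of the default community (expensive; shared)."""
    genomes, qmetrics, _ = community
    return cluster_genomes(genomes, qmetrics, PipelineConfig())
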