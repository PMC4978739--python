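import numpy as np
import pytest

from nlr_evolkit.core_io import RunConfig
from nlr_evolkit.motif_scan import default_motif_models
from nlr_evolkit.report_cli import SpeciesInput, run_pipeline
from nlr_evolkit.synthetic_data import default_genome_spec, make_annotated_genome


@pytest.fixture(scope="session")
def models():
    return default_motif_models()


@pytest.fixture(scope="session")
def genome():
    """The study-condition synthetic genome: 3 species, 5 subgroups, planted
    clusters, noise 0."""
    return make_annotated_genome(default_genome_spec(seed=3))


@pytest.fixture(scope="session")
def nlr_proteins(genome):
    return [p for sp in genome.proteins.values() for p in sp
            if "_filler_" not in p.id]


@pytest.fixture(scope="session")
def pipeline_result(genome):
    """Full pipeline run on the synthetic genome (100 bootstrap replicates
    for speed; the production default is 500)."""
    inputs = [
        SpeciesInput(name=sp, proteins=genome.proteins[sp],
                     cds=genome.cds[sp], loci=genome.loci[sp])
        for sp in genome.proteins
    ]
    cfg = RunConfig(bootstrap_reps=100, rng_seed=1)
    return run_pipeline(inputs, cfg)


def rand_index(labels_a: list, labels_b: list) -> float:
    """Plain Rand index between two labelings of the same items."""
    n = len(labels_a)
    agree = 0
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_a = labels_a[i] == labels_a[j]
            same_b = labels_b[i] == labels_b[j]
            agree += same_a == same_b
            total += 1
    return agree / total if total else 1.0
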