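import pytest
from hypothesis import settings

from sideromine.adomain_sig import load_anchor
from sideromine.code_knowledgebase import read_database
from sideromine.synthetic_nrps import load_scaffolds

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def anchor():
    return load_anchor()


@pytest.fixture(scope="session")
def scaffolds():
    return load_scaffolds()


@pytest.fixture(scope="session")
def db():
    return read_database()


@pytest.fixture(scope="session")
def db_monomers(db):
    return sorted(rec.monomer for rec in db)


def random_spec(rng, db, code_mutations=0, seed=None):
    """A random small cluster spec with database-drawn codes."""
    from sideromine.synthetic_nrps import SyntheticSpec, truth_from_database

    monomers_pool = sorted(rec.monomer for rec in db)
    n_genes = rng.randint(1, 2)
    modules_per_gene = [rng.randint(1, 2) for _ in range(n_genes)]
    n = sum(modules_per_gene)
    monomers = [rng.choice(monomers_pool) for _ in range(n)]
    epimerized = [rng.random() < 0.4 for _ in range(n)]
    tailoring = set()
    if rng.random() < 0.6:
        tailoring.add("pvdA")
    if rng.random() < 0.5:
        tailoring.add(rng.choice(["pvdYII", "pvdF"]))
    return SyntheticSpec(
        n_genes=n_genes,
        modules_per_gene=modules_per_gene,
        ground_truth=truth_from_database(monomers, epimerized, db),
        code_mutations=code_mutations,
        tailoring_genes=tailoring,
        seed=seed if seed is not None else rng.randrange(2**31),
    )


def run_spec_end_to_end(spec, tmp_dir):
    """Write a synthetic cluster to disk and run the full pipeline on it."""
    from sideromine.pipeline import PipelineConfig, run_predict
    from sideromine.synthetic_nrps import generate_cluster, write_cluster

    cluster = generate_cluster(spec)
    paths = write_cluster(cluster, tmp_dir)
    config = PipelineConfig(
        proteins=str(paths["proteins"]),
        features=str(paths["features"]),
        gene_order=[p.id for p in cluster.proteins],
        tailoring=set(spec.tailoring_genes),
        seed=spec.seed,
    )
    return run_predict(config)
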