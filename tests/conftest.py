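import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import codonsel as cs

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: One seed for the whole synthetic-study fixture; every stochastic test
#: derives its own seeds explicitly.
STUDY_SEED = 1234


def study_manifest() -> dict:
    """Three M8-generated genes with enriched DAM tables plus one
    branch-model gene, exercising every test type."""
    manifest = cs.default_study_manifest(
        n_genes=3, n_taxa=12, n_codons=300, dams_per_gene=10, enrichment=0.9
    )
    manifest["datasets"].append(
        {
            "id": "geneBR",
            "tests": ["branch_site", "two_ratio"],
            "n_taxa": 8,
            "n_codons": 150,
            "model": {"variant": "BranchSiteA_null", "p0": 0.75, "p1": 0.15,
                      "omega0": 0.1},
            "foreground": True,
        }
    )
    manifest["families"]["FBR"] = [["geneBR", "branch_site"], ["geneBR", "two_ratio"]]
    return manifest


@pytest.fixture(scope="session")
def study():
    """The default synthetic study, run end to end once per session.

    Returns the run_study report plus the (identical, deterministic)
    simulation bundle so tests can compare inference against ground truth.
    """
    manifest = study_manifest()
    report = cs.run_study(manifest, seed=STUDY_SEED, n_starts=1)
    bundle = cs.simulate_study(
        {"genes": cs.load_manifest(manifest)["datasets"]}, seed=STUDY_SEED
    )
    return {"manifest": manifest, "report": report, "bundle": bundle,
            "seed": STUDY_SEED}


@pytest.fixture(scope="session")
def small_m0_data():
    """An 8-taxon, 200-codon alignment simulated under M0 (omega = 0.2)."""
    tree = cs.random_tree(8, seed=5, mean_branch=0.15)
    model = cs.OmegaModel(variant="M0", omega=0.2, kappa=2.0)
    aln, truth = cs.simulate_alignment(tree, model, 200, seed=17)
    return aln, tree, truth, model


@pytest.fixture
def rng():
    return np.random.default_rng(99)
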