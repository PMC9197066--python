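import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def small_gene():
    """A 6-variant gene with AR(1) LD and fixed z-scores."""
    from sumgene.containers import AlignedGene, LDMatrix

    m = 6
    idx = np.arange(m)
    r = np.exp(-0.3 * np.abs(idx[:, None] - idx[None, :]))
    ids = [f"v{k+1}" for k in range(m)]
    return AlignedGene(
        gene_id="toy",
        variant_ids=ids,
        z=np.array([1.2, -0.4, 2.1, 0.0, -1.6, 0.8]),
        maf=np.array([0.01, 0.05, 0.002, 0.3, 0.12, 0.04]),
        ld=LDMatrix(ids, r, panel_n=1000),
        pos=np.array([100.0, 220.0, 300.0, 480.0, 560.0, 700.0]),
    )


@pytest.fixture(scope="session")
def pipeline_gene():
    """One simulated gene carried through genotypes → GWAS → alignment.

    Session-scoped: several modules check different facets of the same
    simulated data.
    """
    from sumgene.containers import GeneRegion
    from sumgene.ld_reference import align, build_ld
    from sumgene.synthetic_data import (
        SimConfig,
        gwas,
        simulate_genotypes,
        simulate_phenotype,
    )

    cfg = SimConfig(n=4000, m=25, seed=11, causal_frac=0.12, effect_sd=0.1)
    rng = np.random.default_rng(11)
    geno, _ = simulate_genotypes(cfg, rng)
    y, _ = simulate_phenotype(geno, cfg, rng)
    stats = gwas(geno, y)
    used = stats["variant_id"].tolist()
    keep = [int(v[1:]) - 1 for v in used]
    ld = build_ld(geno[:, keep], used, min_maf=0.0)
    gene = align(stats, GeneRegion("sim_gene", used), ld)
    return {"gene": gene, "geno": geno[:, keep], "y": y, "stats": stats}
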