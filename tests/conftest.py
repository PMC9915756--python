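import math

import pytest

from immunocall import (
    ExpressionSimConfig,
    FlowSimConfig,
    GeneSpec,
    default_antigen_pools,
    gen_expression_cohort,
    gen_flow_cohort,
)


def binomial_ci_halfwidth(p: float, n: int, z: float = 1.96) -> float:
    """Wald half-width for a proportion; floor avoids zero-width at p in {0,1}."""
    return z * math.sqrt(max(p * (1.0 - p), 1e-12) / n)


@pytest.fixture
def small_expression_cohort():
    """Three genes, two regimes, 40 tumors per subtype; seeded."""
    genes = (
        GeneSpec("CTA1", "tissue_restricted", {"AC": 0.3, "SCC": 0.6}),
        GeneSpec("CTA2", "tissue_restricted", {"AC": 0.0, "SCC": 1.0}),
        GeneSpec("UBIQ1", "ubiquitous", {}),
    )
    cfg = ExpressionSimConfig(
        genes=genes,
        n_normal=20,
        n_tumor_per_subtype={"AC": 40, "SCC": 40},
        n_reference=30,
        seed=11,
    )
    return cfg, *gen_expression_cohort(cfg)


@pytest.fixture
def small_flow_cohort():
    """Twelve patients, default antigen pools, paired ±ICI tubes; seeded."""
    cfg = FlowSimConfig(
        antigen_pools=default_antigen_pools(),
        n_patients=12,
        include_ici=True,
        seed=5,
    )
    return cfg, *gen_flow_cohort(cfg)
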