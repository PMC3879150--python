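import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from riboupr import (
    RegulationDesign,
    build_expression_table,
    classify_regulation,
    compute_rpkm,
    generate_genome,
    regulated_set,
    simulate_count_tables,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_genome():
    """30 genes on both strands, one with an intron, one homolog pair."""
    return generate_genome(
        30, (300, 600), intron_gene_count=1, homolog_pair_count=1, seed=11
    )


@pytest.fixture(scope="session")
def plain_genome():
    """20 intronless, non-homologous genes (exact round-trip territory)."""
    return generate_genome(20, (300, 900), 0, 0, seed=23)


@pytest.fixture(scope="session")
def te_recovery():
    """Parameter-recovery scenario: 1,000 genes, 50 with a true 2-fold TE
    increase, 2 replicates at 5M-read depth; returns recovery rates."""
    genome = generate_genome(1000, (300, 1500), 0, 0, seed=101)
    design = RegulationDesign.random(
        genome, conditions=("WT", "mut"), reference="WT",
        replicates=2, depth=5_000_000, seed=202,
    )
    design.te_fold_change["mut"][:50] = 2.0
    sim = simulate_count_tables(genome, design)
    expr = build_expression_table(
        compute_rpkm(sim.footprints), compute_rpkm(sim.mrna),
        sim.condition_map, "WT",
    )
    calls = classify_regulation(expr)
    true_up = set(design.gene_ids[:50])
    null = set(design.gene_ids[50:])
    flagged_up = regulated_set(calls, "te", "mut", "up")
    flagged_any = regulated_set(calls, "te", "mut")
    sensitivity = len(flagged_up & true_up) / len(true_up)
    false_rate = len(flagged_any & null) / len(null)
    return {"sensitivity": sensitivity, "false_rate": false_rate,
            "expr": expr, "calls": calls}
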