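"""Generators: genome layout, count simulation, alignments, lifespan cohorts."""

import numpy as np
import pandas as pd
import pytest

from riboupr import (
    AlignmentRecord,
    LifespanDesign,
    RegulationDesign,
    count_features,
    expected_rpkm,
    generate_genome,
    make_count_table,
    mean_rls,
    ranksum_test,
    simulate_alignments,
    simulate_count_tables,
    simulate_lifespan_cohort,
)
from riboupr.models import effective_length


class TestGenerateGenome:
    def test_single_forced_gene(self):
        genes = generate_genome(1, (300, 300), 0, 0, seed=1)
        assert len(genes) == 1
        assert genes[0].spliced_length == 300

    def test_requested_intron_and_homolog_designations(self):
        genes = generate_genome(100, (300, 900), 1, 2, seed=4)
        assert sum(1 for g in genes if g.introns) == 1
        groups = {}
        for g in genes:
            if g.homology_group:
                groups.setdefault(g.homology_group, []).append(g.gene_id)
        assert len(groups) == 2
        assert all(len(v) == 2 for v in groups.values())

    def test_same_seed_identical_layout(self):
        a = generate_genome(50, (300, 600), 2, 1, seed=9)
        b = generate_genome(50, (300, 600), 2, 1, seed=9)
        assert [(g.start, g.end, g.strand, g.introns) for g in a] == [
            (g.start, g.end, g.strand, g.introns) for g in b
        ]

    def test_genes_do_not_overlap(self):
        genes = generate_genome(200, (300, 1200), 3, 2, seed=2)
        spans = sorted((g.start, g.end) for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2

    def test_lengths_are_codon_multiples_in_range(self):
        genes = generate_genome(50, (301, 899), 0, 0, seed=3)
        for g in genes:
            assert g.spliced_length % 3 == 0
            assert 301 <= g.spliced_length <= 899

    def test_infeasible_designations_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(3, (300, 300), 2, 1, seed=0)

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(50, (300, 300), 0, 0, seed=0, chrom_length=2000)


class TestSimulateCounts:
    def test_constant_te_gives_constant_expected_ratio(self, plain_genome):
        """All baseline TE equal and all TE fold changes 1: the generative
        footprint:mRNA rpkm ratio is the same constant for every gene."""
        n = len(plain_genome)
        design = RegulationDesign.random(plain_genome, seed=3)
        design.baseline_te = np.full(n, 1.7)
        lengths = np.array([effective_length(g, 100)[0] for g in plain_genome], float)
        fp = expected_rpkm(design, lengths, "footprint")
        mr = expected_rpkm(design, lengths, "mrna")
        ratio = fp / mr
        for cond in design.conditions:
            assert np.allclose(ratio[cond], ratio[cond].iloc[0])

    def test_te_fold_change_recovered_over_replicates(self, plain_genome):
        """One gene with a true 2-fold TE change: averaging 200 simulated
        replicates at 5M depth recovers an observed TE ratio within 5% of 2."""
        design = RegulationDesign.random(
            plain_genome, conditions=("WT", "mut"), replicates=200,
            depth=5_000_000, seed=8,
        )
        design.te_fold_change["mut"][0] = 2.0
        sim = simulate_count_tables(plain_genome, design)
        groups = {"WT": [s for s, c in sim.condition_map.items() if c == "WT"],
                  "mut": [s for s, c in sim.condition_map.items() if c == "mut"]}
        fp = sim.footprints.counts
        mr = sim.mrna.counts
        te = {
            cond: (fp[groups[cond]].mean(axis=1) / mr[groups[cond]].mean(axis=1))
            for cond in groups
        }
        observed = (te["mut"] / te["WT"]).iloc[0]
        assert observed == pytest.approx(2.0, rel=0.05)

    def test_expected_rpkm_depth_invariant(self, plain_genome):
        """Expected (generative) rpkm is depth-normalised: doubling depth
        leaves the truth table unchanged."""
        d1 = RegulationDesign.random(plain_genome, depth=1_000_000, seed=5)
        d2 = RegulationDesign.random(plain_genome, depth=2_000_000, seed=5)
        t1 = simulate_count_tables(plain_genome, d1).truth
        t2 = simulate_count_tables(plain_genome, d2).truth
        pd.testing.assert_series_equal(
            t1["expected_mrna_rpkm"], t2["expected_mrna_rpkm"]
        )
        pd.testing.assert_series_equal(
            t1["expected_footprint_rpkm"], t2["expected_footprint_rpkm"]
        )

    def test_determinism(self, plain_genome):
        d = RegulationDesign.random(plain_genome, seed=12, depth=50_000)
        a = simulate_count_tables(plain_genome, d)
        b = simulate_count_tables(plain_genome, d)
        pd.testing.assert_frame_equal(a.footprints.counts, b.footprints.counts)
        pd.testing.assert_frame_equal(a.mrna.counts, b.mrna.counts)

    def test_bad_designs_rejected(self, plain_genome):
        with pytest.raises(ValueError):
            RegulationDesign.random(plain_genome, depth=0)
        with pytest.raises(ValueError):
            RegulationDesign.random(plain_genome, dispersion=0.0)


class TestSimulateAlignments:
    def _counts(self, genome, per_gene):
        frame = pd.DataFrame(
            {"s1": [per_gene] * len(genome)}, index=[g.gene_id for g in genome]
        )
        return make_count_table(frame, genome)

    def test_round_trip_exact_recovery(self, plain_genome):
        """Zero noise fractions: counting the simulated alignments returns
        the source count table exactly."""
        table = self._counts(plain_genome, 40)
        records = simulate_alignments(plain_genome, table, sample="s1", seed=6)
        result = count_features(records, plain_genome)
        assert result.table.counts["sample"].to_dict() == {
            g.gene_id: 40 for g in plain_genome
        }

    def test_conservation_of_record_count(self, small_genome):
        table = self._counts(small_genome, 17)
        records = simulate_alignments(small_genome, table, sample="s1", seed=6)
        assert len(records) == 17 * len(small_genome)

    def test_all_multimappers_count_zero(self, plain_genome):
        table = self._counts(plain_genome, 10)
        records = simulate_alignments(
            plain_genome, table, sample="s1", multimap_fraction=1.0, seed=6
        )
        result = count_features(records, plain_genome)
        assert (result.table.counts == 0).all().all()
        assert result.unassigned.loc["multimapper", "sample"] == len(records)

    def test_first100_reads_land_in_trim_zone(self, plain_genome):
        table = self._counts(plain_genome, 30)
        records = simulate_alignments(
            plain_genome, table, sample="s1", first100_fraction=1.0, seed=6
        )
        result = count_features(records, plain_genome)
        assert (result.table.counts == 0).all().all()
        assert result.unassigned.loc["five_prime_zone", "sample"] == len(records)

    def test_read_length_longer_than_shortest_gene_rejected(self, plain_genome):
        table = self._counts(plain_genome, 1)
        shortest = min(g.spliced_length for g in plain_genome)
        with pytest.raises(ValueError):
            simulate_alignments(
                plain_genome, table, sample="s1", read_length=shortest + 1
            )

    def test_determinism(self, small_genome):
        table = self._counts(small_genome, 9)
        a = simulate_alignments(small_genome, table, sample="s1", seed=42)
        b = simulate_alignments(small_genome, table, sample="s1", seed=42)
        assert a == b


class TestLifespanCohorts:
    def test_large_cohort_mean_converges(self):
        cohort = simulate_lifespan_cohort(
            LifespanDesign("WT", 100_000, 26.4, seed=5)
        )
        assert mean_rls(cohort) == pytest.approx(26.4, abs=0.2)

    def test_single_cell_cohort(self):
        cohort = simulate_lifespan_cohort(LifespanDesign("x", 1, 20.0, seed=1))
        assert len(cohort) == 1
        assert cohort.divisions[0] >= 0

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            LifespanDesign("x", 10, 0.0)

    def test_determinism(self):
        a = simulate_lifespan_cohort(LifespanDesign("x", 500, 26.4, seed=3))
        b = simulate_lifespan_cohort(LifespanDesign("x", 500, 26.4, seed=3))
        assert a.divisions == b.divisions

    def test_equal_designs_reject_at_nominal_rate(self):
        """Two identical cohort designs: the rank-sum test rejects at the 5%
        level in about 5% of simulations (coarse bound on a 400-sim batch)."""
        rng = np.random.SeedSequence(99).generate_state(800) % (2**31)
        rejections = 0
        n_sims = 400
        for i in range(n_sims):
            a = simulate_lifespan_cohort(
                LifespanDesign("a", 70, 26.4, seed=int(rng[2 * i]))
            )
            b = simulate_lifespan_cohort(
                LifespanDesign("b", 70, 26.4, seed=int(rng[2 * i + 1]))
            )
            if ranksum_test(a.divisions, b.divisions).p_value < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_sims <= 0.08
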