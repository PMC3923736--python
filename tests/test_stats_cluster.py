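"""Spectrum, context bias, count matrices, syn/nonsyn, rates and clustering."""

import numpy as np
import pandas as pd
import pytest

import rddkit as rk
from rddkit.seq_core import STANDARD_TABLE

from conftest import brute_force_complete_linkage


def ev(kind, pos, ref="", alt="", gene="g1", tissue="legs", clone="c1"):
    return rk.RDDEvent(clone, gene, tissue, "F1", kind, pos, ref, alt)


class TestSubstitutionSpectrum:
    def test_empty(self):
        spec = rk.substitution_spectrum([])
        assert spec.total == 0 and all(v == 0 for v in spec.counts.values())

    def test_indels_ignored(self):
        spec = rk.substitution_spectrum([ev("deletion", 10, ref="A"),
                                         ev("insertion", 20, alt="C")])
        assert spec.total == 0

    def test_exact_recovery_from_manifest(self, rng):
        cfg = rk.SimConfig(seed=31, tissues=(("legs", 3.0),),
                           clones_per_tissue=50)
        _, ref = rk.simulate_gene(cfg, rng)
        clones, manifest = rk.simulate_clone_set(ref, "legs", cfg, rng)
        events = rk.manifest_to_events(manifest, clones)
        spec = rk.substitution_spectrum(events)
        expected = {c: 0 for c in rk.SUBSTITUTION_CLASSES}
        for e in manifest.events:
            if e["kind"] == "substitution":
                expected[f"{e['ref_allele']}>{e['alt_allele']}"] += 1
        assert spec.counts == expected
        assert spec.total == sum(expected.values())


class TestContextBias:
    def test_all_hits(self, rng):
        ref = rk.make_coding_transcript(rng, 50)
        cdna = ref.cdna
        positions = [i + 1 for i in range(len(cdna) - 1) if cdna[i + 1] == "A"
                     and cdna[i] != "T"][:5]
        events = [ev("substitution", p, ref=cdna[p - 1], alt="T")
                  for p in positions]
        prop, pval, n = rk.three_prime_context_bias(events, ref)
        assert prop == 1.0 and n == len(positions)

    def test_single_event_proportion_binary(self, rng):
        ref = rk.make_coding_transcript(rng, 50)
        alt = "C" if ref.cdna[9] != "C" else "G"
        prop, _, _ = rk.three_prime_context_bias(
            [ev("substitution", 10, ref=ref.cdna[9], alt=alt)], ref)
        assert prop in (0.0, 1.0)

    def test_no_eligible_events_rejected(self, toy_ref):
        with pytest.raises(ValueError):
            rk.three_prime_context_bias([], toy_ref)

    def test_type_i_error_calibrated_under_null(self, rng):
        ref = rk.make_coding_transcript(rng, 100)
        cdna = ref.cdna
        L = len(cdna)
        false_pos = 0
        n_sims = 1000
        for _ in range(n_sims):
            positions = rng.choice(np.arange(1, L), size=30, replace=False)
            events = []
            for p in positions:
                p = int(p)
                src = cdna[p - 1]
                alt = "ACGT"[("ACGT".index(src) + 1) % 4]
                events.append(ev("substitution", p, ref=src, alt=alt))
            _, pval, _ = rk.three_prime_context_bias(events, ref)
            if pval < 0.05:
                false_pos += 1
        assert false_pos / n_sims <= 0.07


class TestGeneTissueCounts:
    # printed 4-gene x 5-tissue grid used as a worked-example fixture
    GRID = {
        "BmorCSP1": {"antennae": 14, "legs": 6, "head": 9, "wings": 5,
                     "pheromone_gland": 27},
        "BmorCSP2": {"antennae": 6, "legs": 5, "head": 5, "wings": 8,
                     "pheromone_gland": 19},
        "BmorCSP4": {"antennae": 12, "legs": 14, "head": 1, "wings": 2,
                     "pheromone_gland": 9},
        "BmorCSP14": {"antennae": 20, "legs": 13, "head": 16, "wings": 17,
                      "pheromone_gland": 25},
    }

    @staticmethod
    def grid_events():
        events = []
        k = 0
        for gene, row in TestGeneTissueCounts.GRID.items():
            for tissue, count in row.items():
                for _ in range(count):
                    k += 1
                    events.append(ev("substitution", 10, ref="A", alt="G",
                                     gene=gene, tissue=tissue, clone=f"c{k}"))
        return events

    def test_intronless_gene_row_total(self):
        matrix = rk.gene_tissue_counts(self.grid_events())
        assert matrix.gene_totals["BmorCSP14"] == 91

    def test_grand_total(self):
        matrix = rk.gene_tissue_counts(self.grid_events())
        assert matrix.grand_total == 233

    def test_totals_consistency(self):
        matrix = rk.gene_tissue_counts(self.grid_events())
        table = matrix.with_totals()
        assert (table.loc["Total"] == table.drop(index="Total").sum()).all()
        assert (table["Total"] == table.drop(columns="Total").sum(axis=1)).all()

    def test_empty_events_zero_matrix(self):
        matrix = rk.gene_tissue_counts([], genes=["g1"], tissues=["legs"])
        assert matrix.grand_total == 0
        assert matrix.table.shape == (1, 1)


class TestSynNonsyn:
    def test_third_position_gga_ggg_synonymous(self, rng):
        ref = rk.make_coding_transcript(rng, 50, codon_overrides={10: "GGA"})
        events = [ev("substitution", 30, ref="A", alt="G")]
        assert rk.syn_nonsyn_counts(events, ref) == (1, 0)

    def test_sense_to_stop_nonsynonymous(self, rng):
        ref = rk.make_coding_transcript(rng, 50, codon_overrides={10: "AAA"})
        events = [ev("substitution", 28, ref="A", alt="T")]
        assert rk.syn_nonsyn_counts(events, ref) == (0, 1)

    def test_outside_orf_skipped(self, rng):
        ref = rk.make_coding_transcript(rng, 50, orf_offset=10)
        src = ref.cdna[2]
        alt = "ACGT"[("ACGT".index(src) + 1) % 4]
        assert rk.syn_nonsyn_counts([ev("substitution", 3, ref=src, alt=alt)],
                                    ref) == (0, 0)

    def test_partition_matches_codon_table_oracle(self, rng):
        cfg = rk.SimConfig(seed=37, p_insertion=0.0, p_deletion=0.0,
                           tissues=(("legs", 1.0),))
        _, ref = rk.simulate_gene(cfg, rng)
        events = []
        for _ in range(500):
            events.extend(rk.draw_random_events(ref, cfg, rng, 1))
        syn, nonsyn = rk.syn_nonsyn_counts(events, ref)
        # oracle: mutate the full cdna and compare translations codon-wise
        o_syn = o_nonsyn = o_out = 0
        orf_end = ref.native_stop_base + 2
        for e in events:
            if not ref.orf_offset + 1 <= e.pos <= orf_end:
                o_out += 1
                continue
            i = e.pos - 1
            mutated = ref.cdna[:i] + e.alt_allele + ref.cdna[i + 1:]
            j = ref.orf_offset + 3 * ((i - ref.orf_offset) // 3)
            if STANDARD_TABLE.aa(mutated[j:j + 3]) \
                    == STANDARD_TABLE.aa(ref.cdna[j:j + 3]):
                o_syn += 1
            else:
                o_nonsyn += 1
        assert (syn, nonsyn) == (o_syn, o_nonsyn)
        assert syn + nonsyn + o_out == len(events)


class TestRates:
    def test_zero_events(self, toy_ref):
        assert rk.rdd_rate([], 10, toy_ref) == (0.0, 0.0)

    def test_arithmetic(self, rng):
        ref = rk.TranscriptRef("g", "ATG" + "GGA" * 165 + "TAA", 0)
        assert len(ref.cdna) == 501
        events = [ev("substitution", 10, ref="G", alt="A", clone=f"c{i}")
                  for i in range(5)]
        per_clone, per_kb = rk.rdd_rate(events, 10, ref)
        assert per_clone == pytest.approx(0.5)
        assert per_kb == pytest.approx(0.5 / 0.501)

    def test_doubling_clones_halves_rate(self, toy_ref):
        events = [ev("substitution", 10, ref=toy_ref.cdna[9],
                     alt="A" if toy_ref.cdna[9] != "A" else "C")]
        assert rk.rdd_rate(events, 20, toy_ref)[0] \
            == rk.rdd_rate(events, 10, toy_ref)[0] / 2

    def test_zero_clones_rejected(self, toy_ref):
        with pytest.raises(ValueError):
            rk.rdd_rate([], 0, toy_ref)


class TestTissueDendrogram:
    def test_identical_rows_merge_at_zero(self):
        m = pd.DataFrame([[1, 2], [1, 2], [9, 9]],
                         index=["a", "b", "c"], columns=["s1", "s2"])
        dendro = rk.tissue_dendrogram(m)
        assert dendro.merges[0][2] == 0.0
        assert dendro.merges[0][0] | dendro.merges[0][1] == {"a", "b"}

    def test_three_rows_hand_computed_heights(self):
        # d(a,b)=3, d(a,c)=4, d(b,c)=5: merge (a,b) at 3 then c at max(4,5)=5
        m = pd.DataFrame([[0, 0], [3, 0], [0, 4]],
                         index=["a", "b", "c"], columns=["x", "y"])
        dendro = rk.tissue_dendrogram(m)
        assert dendro.heights == pytest.approx([3.0, 5.0])
        assert dendro.outermost_leaf() == "c"

    def test_heights_non_decreasing(self, rng):
        for _ in range(20):
            m = pd.DataFrame(rng.random((5, 8)),
                             index=[f"t{i}" for i in range(5)])
            h = rk.tissue_dendrogram(m).heights
            assert all(a <= b + 1e-12 for a, b in zip(h, h[1:]))

    def test_matches_brute_force_agglomeration(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 7))
            labels = [f"t{i}" for i in range(n)]
            X = rng.random((n, 4)) * 10
            dendro = rk.tissue_dendrogram(pd.DataFrame(X, index=labels))
            expected = brute_force_complete_linkage(X, labels)
            assert len(dendro.merges) == len(expected) == n - 1
            for (a, b, h), (ea, eb, eh) in zip(dendro.merges, expected):
                assert {a, b} == {ea, eb}
                assert h == pytest.approx(eh)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            rk.tissue_dendrogram(pd.DataFrame([[1, 2]], index=["a"]))

    def test_newick_contains_all_leaves(self):
        m = pd.DataFrame(np.eye(4), index=list("abcd"))
        dendro = rk.tissue_dendrogram(m)
        for leaf in "abcd":
            assert leaf in dendro.newick

    def test_gland_separates_last_under_elevated_rate(self, rng):
        cfg = rk.SimConfig(seed=41, n_genes=1, clones_per_tissue=10,
                           pheromone_gland_multiplier=3.0)
        wins = 0
        runs = 30
        for r in range(runs):
            run_rng = np.random.default_rng(1000 + r)
            _, ref = rk.simulate_gene(cfg, run_rng)
            events = []
            for tissue, _ in cfg.tissues:
                clones, manifest = rk.simulate_clone_set(ref, tissue, cfg,
                                                         run_rng)
                events.extend(rk.manifest_to_events(manifest, clones))
            dendro = rk.tissue_dendrogram(rk.site_counts_by_tissue(events))
            if dendro.outermost_leaf() == "pheromone_gland":
                wins += 1
        assert wins / runs >= 0.9
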