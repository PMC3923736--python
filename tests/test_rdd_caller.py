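"""Event calling, deletion-run merging, nomenclature and site summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rddkit as rk
from rddkit.alignment import ConsensusResult
from rddkit.rdd_caller import NameParseError


def make_event(kind, pos, ref="", alt="", tissue="legs", clone="c1"):
    return rk.RDDEvent(clone, "g1", tissue, "F1", kind, pos, ref, alt)


@pytest.fixture
def plain_consensus(toy_ref):
    return ConsensusResult(toy_ref.cdna, [])


class TestCallEvents:
    def test_identical_clone_no_events(self, toy_ref, plain_consensus):
        clone = rk.CloneSequence("c1", "toy", "legs", "F1", "cDNA", toy_ref.cdna)
        pair = rk.global_align(toy_ref.cdna, clone.seq)
        assert rk.call_events(plain_consensus, pair, clone) == []

    def test_single_base_deletion_called_at_position(self, rng):
        # a clone missing one base yields exactly one deletion at that base
        ref, (pos, base) = rk.engineer_late_frameshift(rng, 111, 87, 129,
                                                       orf_offset=48)
        clone_seq = ref.cdna[:pos - 1] + ref.cdna[pos:]
        clone = rk.CloneSequence("c1", "toy", "pheromone_gland", "F1", "cDNA",
                                 clone_seq)
        pair = rk.global_align(ref.cdna, clone_seq)
        events = rk.call_events(ConsensusResult(ref.cdna, []), pair, clone)
        assert len(events) == 1
        ev = events[0]
        assert (ev.kind, ev.pos, ev.ref_allele) == ("deletion", 307, "C")
        assert ev.rna_name == "r.307c<"

    def test_masked_positions_skipped(self, toy_ref):
        pos = 30
        alt = "A" if toy_ref.cdna[pos - 1] != "A" else "C"
        clone_seq = toy_ref.cdna[:pos - 1] + alt + toy_ref.cdna[pos:]
        clone = rk.CloneSequence("c1", "toy", "legs", "F1", "cDNA", clone_seq)
        pair = rk.global_align(toy_ref.cdna, clone_seq)
        masked = ConsensusResult(toy_ref.cdna, [pos])
        assert rk.call_events(masked, pair, clone) == []
        unmasked = ConsensusResult(toy_ref.cdna, [])
        events = rk.call_events(unmasked, pair, clone)
        assert [(e.kind, e.pos, e.alt_allele) for e in events] \
            == [("substitution", pos, alt)]

    def test_truth_manifest_recovery(self, rng):
        cfg = rk.SimConfig(seed=21, n_genes=1, clones_per_tissue=20, gdna_clones=5)
        _, ref = rk.simulate_gene(cfg, rng)
        consensus = rk.build_gdna_consensus(ref.cdna, [ref.cdna] * 5)
        called = set()
        truth = rk.TruthManifest()
        for tissue, _ in cfg.tissues:
            clones, manifest = rk.simulate_clone_set(ref, tissue, cfg, rng)
            truth.extend(manifest)
            for clone in clones:
                for ev in rk.call_clone(ref, consensus, clone, rk.AlignParams()):
                    called.add(ev.key())
        assert called == truth.keys()


class TestMergeDeletionRuns:
    def test_adjacent_pair_merges(self):
        events = [make_event("deletion", 115, ref="A"),
                  make_event("deletion", 116, ref="T")]
        merged = rk.merge_deletion_runs(events)
        assert len(merged) == 1
        assert (merged[0].pos, merged[0].ref_allele) == (115, "AT")
        assert merged[0].rna_name == "r.115_116at<"

    def test_isolated_deletion_unchanged(self):
        events = [make_event("deletion", 50, ref="G"),
                  make_event("substitution", 80, ref="C", alt="T")]
        merged = rk.merge_deletion_runs(events)
        assert [(e.kind, e.pos) for e in merged] \
            == [("deletion", 50), ("substitution", 80)]

    def test_three_adjacent_merge_into_one(self):
        events = [make_event("deletion", p, ref=b)
                  for p, b in ((10, "A"), (11, "C"), (12, "G"))]
        merged = rk.merge_deletion_runs(events)
        assert [(e.pos, e.ref_allele) for e in merged] == [(10, "ACG")]

    def test_deleted_base_count_conserved(self, rng):
        for _ in range(50):
            positions = sorted(rng.choice(np.arange(1, 200), size=8, replace=False))
            events = [make_event("deletion", int(p), ref="ACGT"[i % 4])
                      for i, p in enumerate(positions)]
            merged = rk.merge_deletion_runs(events)
            assert sum(len(e.ref_allele) for e in merged) == len(events)

    def test_near_adjacent_stay_separate_but_group_for_display(self):
        # a deletion at 184 and another at 186 skip base 185
        events = [make_event("deletion", 184, ref="C"),
                  make_event("deletion", 186, ref="T")]
        merged = rk.merge_deletion_runs(events)
        assert len(merged) == 2
        groups = rk.group_nearby_deletions(merged, window=3)
        assert len(groups) == 1 and len(groups[0]) == 2


class TestNomenclature:
    @pytest.mark.parametrize("event,expected", [
        (("substitution", 68, "C", "A"), "r.68c>a"),
        (("deletion", 187, "A", ""), "r.187a<"),
        (("deletion", 115, "AT", ""), "r.115_116at<"),
        (("deletion", 181, "GATAAAATTCCA", ""), "r.181-192ga<"),
        (("insertion", 317, "", "A"), "r.317a>"),
    ])
    def test_names(self, event, expected):
        kind, pos, ref, alt = event
        assert make_event(kind, pos, ref=ref, alt=alt).rna_name == expected

    def test_parse_inverts_name(self):
        ev = make_event("substitution", 68, ref="C", alt="A")
        parsed = rk.parse_rna_name(ev.rna_name)
        assert parsed == {"kind": "substitution", "pos": 68,
                          "ref_allele": "C", "alt_allele": "A"}

    def test_parse_range_deletion_with_reference(self, rng):
        ref, (pos, deleted) = rk.engineer_motif_deletion(
            rng, 104, 45, 48, "DKIP", orf_offset=48)
        name = make_event("deletion", pos, ref=deleted).rna_name
        parsed = rk.parse_rna_name(name, ref_seq=ref.cdna)
        assert parsed["ref_allele"] == deleted

    def test_roundtrip_on_random_events(self, rng):
        bases = "ACGT"
        for _ in range(1000):
            kind = ("substitution", "deletion", "insertion")[int(rng.integers(3))]
            pos = int(rng.integers(1, 400))
            if kind == "substitution":
                ref = bases[int(rng.integers(4))]
                alt = bases[int(rng.integers(4))]
                if alt == ref:
                    alt = bases[(bases.index(ref) + 1) % 4]
                ev = make_event(kind, pos, ref=ref, alt=alt)
            elif kind == "deletion":
                d = int(rng.integers(1, 13))
                ref = "".join(bases[i] for i in rng.integers(0, 4, d))
                ev = make_event(kind, pos, ref=ref)
            else:
                ev = make_event(kind, pos, alt=bases[int(rng.integers(4))])
            parsed = rk.parse_rna_name(ev.rna_name)
            assert parsed["kind"] == ev.kind
            assert parsed["pos"] == ev.pos
            assert parsed["alt_allele"] == ev.alt_allele
            if ev.kind == "deletion" and len(ev.ref_allele) >= 3:
                # the dialect only prints first/last bases of long deletions
                assert len(parsed["ref_allele"]) == len(ev.ref_allele)
                assert parsed["ref_allele"][0] == ev.ref_allele[0]
                assert parsed["ref_allele"][-1] == ev.ref_allele[-1]
                rebuilt = rk.RDDEvent("c1", "g1", "legs", "F1", "deletion",
                                      ev.pos, ev.ref_allele, "")
                assert rebuilt.rna_name == ev.rna_name
            else:
                assert parsed["ref_allele"] == ev.ref_allele

    @pytest.mark.parametrize("bad", ["r.68ca", "r68c>a", "r.115_117at<",
                                     "r.10-11ga<", "x.68c>a", ""])
    def test_malformed_names_rejected(self, bad):
        with pytest.raises(NameParseError):
            rk.parse_rna_name(bad)

    @given(pos=st.integers(1, 5000),
           ref=st.sampled_from("ACGT"),
           alt=st.sampled_from("ACGT"),
           kind=st.sampled_from(["substitution", "deletion", "insertion"]))
    @settings(derandomize=True, max_examples=200)
    def test_name_is_parseable_for_any_single_base_event(self, pos, ref, alt,
                                                         kind):
        if kind == "substitution":
            if ref == alt:
                alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            ev = make_event(kind, pos, ref=ref, alt=alt)
        elif kind == "deletion":
            ev = make_event(kind, pos, ref=ref)
        else:
            ev = make_event(kind, pos, alt=alt)
        parsed = rk.parse_rna_name(ev.rna_name)
        assert parsed == {"kind": ev.kind, "pos": ev.pos,
                          "ref_allele": ev.ref_allele,
                          "alt_allele": ev.alt_allele}


class TestSummarizeSites:
    def test_recurrent_substitution_counted(self):
        events = [make_event("substitution", 50, ref="G", alt="A",
                             clone=f"c{i}") for i in range(3)]
        summaries = rk.summarize_sites(events)
        assert len(summaries) == 1
        assert summaries[0].substitutions["legs"]["A"] == 3

    def test_empty_events_empty_summary(self):
        assert rk.summarize_sites([]) == []

    def test_site_shared_between_tissues(self):
        events = [make_event("substitution", 50, ref="G", alt="A", tissue="legs"),
                  make_event("substitution", 50, ref="G", alt="A",
                             tissue="wings", clone="c2"),
                  make_event("substitution", 90, ref="C", alt="T", tissue="legs",
                             clone="c3")]
        summaries = rk.summarize_sites(events)
        sharing = rk.site_tissue_sharing(summaries)
        assert sharing == {"one_tissue": 1, "multi_tissue": 1}

    def test_recurrence_cannot_exceed_clone_count(self):
        events = [make_event("substitution", 50, ref="G", alt="A",
                             clone=f"c{i}") for i in range(3)]
        with pytest.raises(ValueError):
            rk.summarize_sites(events, clones_per_tissue={"legs": 2})
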