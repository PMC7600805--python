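"""Complex-cluster chaining, duplicate-family detection and type labelling."""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pytest

from numt_atlas import SimConfig, simulate_genome
from numt_atlas._align import decode, revcomp
from numt_atlas.homology_search import filter_hits, scan_numts
from numt_atlas.numt_classify import (
    ClassifyParams,
    NumtRecord,
    cluster_complex,
    detect_duplicates,
    label_types,
    records_from_hits,
    with_cluster_ids,
)

from .conftest import match_truth


def rec(i, start, end, strand="+", ms=0, me=100, scaffold="s1", identity=0.95, ev=1e-20):
    return NumtRecord(
        numt_id=f"N{i}",
        scaffold=scaffold,
        nuc_interval=(start, end),
        strand=strand,
        mito_interval=(ms, me),
        identity=identity,
        evalue=ev,
    )


def random_dna(rng, n, at=0.6):
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return decode(rng.choice(4, size=n, p=p).astype(np.uint8))


def mutate(rng, seq, d):
    from numt_atlas._align import encode

    codes = encode(seq).copy()
    mask = rng.random(len(codes)) < d
    codes[mask] = (codes[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    return decode(codes)


# ---------------------------------------------------------------------------
# complex clusters


class TestClusterComplex:
    def test_nearby_syntenic_pair_clusters(self):
        """Two same-strand hits 5 kb apart with advancing mito coordinates
        form one cluster of two."""
        numts = [rec(1, 10_000, 10_300, ms=100, me=400), rec(2, 15_300, 15_700, ms=900, me=1300)]
        (c,) = cluster_complex(numts)
        assert c.member_ids == ("N1", "N2")
        assert c.gaps == (5_000,)
        assert c.mito_span == (100, 1300)

    def test_gap_over_10kb_breaks_cluster(self):
        numts = [rec(1, 10_000, 10_300, ms=100, me=400), rec(2, 22_300, 22_700, ms=900, me=1300)]
        assert cluster_complex(numts) == []

    def test_gap_boundary_exactly_max_gap(self):
        at_limit = [rec(1, 0, 300, ms=100, me=400), rec(2, 10_300, 10_600, ms=900, me=1300)]
        assert cluster_complex(at_limit) == []  # gap == 10 kb is not < 10 kb
        inside = [rec(1, 0, 300, ms=100, me=400), rec(2, 10_299, 10_600, ms=900, me=1300)]
        assert len(cluster_complex(inside)) == 1

    def test_opposite_strands_break_cluster(self):
        numts = [rec(1, 10_000, 10_300, ms=100, me=400), rec(2, 15_300, 15_700, "-", ms=900, me=1300)]
        assert cluster_complex(numts) == []

    def test_minus_strand_chain_needs_decreasing_mito(self):
        good = [rec(1, 10_000, 10_300, "-", ms=900, me=1300), rec(2, 15_300, 15_700, "-", ms=100, me=400)]
        assert len(cluster_complex(good)) == 1
        bad = [rec(1, 10_000, 10_300, "-", ms=100, me=400), rec(2, 15_300, 15_700, "-", ms=900, me=1300)]
        assert cluster_complex(bad) == []

    def test_overlapping_mito_intervals_break_chain(self):
        numts = [rec(1, 10_000, 10_300, ms=100, me=400), rec(2, 15_300, 15_700, ms=300, me=700)]
        assert cluster_complex(numts) == []

    def test_unsorted_input_rejected(self):
        numts = [rec(1, 15_300, 15_700), rec(2, 10_000, 10_300)]
        with pytest.raises(ValueError, match="sorted"):
            cluster_complex(numts)

    def test_gap_monotonicity(self, bundle):
        """Shrinking max_gap never increases the number of clustered NUMTs."""
        counts = []
        for g in (10_000, 6_000, 3_000, 1_000):
            clusters = cluster_complex(bundle.records, ClassifyParams(max_gap=g))
            counts.append(sum(len(c.member_ids) for c in clusters))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_clusters_satisfy_criteria_when_rechecked(self, bundle):
        """Every emitted cluster independently satisfies the three chaining
        criteria (distance, shared strand, synteny)."""
        by_id = {r.numt_id: r for r in bundle.records}
        for c in cluster_complex(bundle.records):
            members = [by_id[m] for m in c.member_ids]
            assert len({m.strand for m in members}) == 1
            for a, b in zip(members, members[1:]):
                gap = b.nuc_interval[0] - a.nuc_interval[1]
                assert 0 <= gap < 10_000
                if c.strand == "+":
                    assert b.mito_interval[0] > a.mito_interval[0]
                    assert b.mito_interval[0] >= a.mito_interval[1] - 20
                else:
                    assert b.mito_interval[1] < a.mito_interval[1]
                    assert b.mito_interval[1] <= a.mito_interval[0] + 20

    def test_truth_clusters_recovered(self, bundle):
        """Fragments planted by the simulator as one TE-split insertion are
        chained into exactly one cluster matching the truth membership."""
        truth_map = match_truth(bundle.records, bundle.result.truth)
        clusters = cluster_complex(bundle.records)
        detected = {}
        for c in clusters:
            for m in c.member_ids:
                detected[m] = c.cluster_id
        truth_groups = defaultdict(set)
        for r in bundle.records:
            t = truth_map[r.numt_id]
            if t is not None and t.cluster_id is not None:
                truth_groups[t.cluster_id].add(r.numt_id)
        assert truth_groups, "fixture should contain complex plants"
        for tc, members in truth_groups.items():
            cids = {detected.get(m) for m in members}
            assert len(cids) == 1 and None not in cids, (tc, members)


# ---------------------------------------------------------------------------
# duplicate families


class TestDetectDuplicates:
    def _two_copy_genome(self, rng, d_numt=0.0, shared_flanks=True, flank=1_000):
        numt = random_dna(rng, 500)
        fl, fr = random_dna(rng, flank), random_dna(rng, flank)
        copy = mutate(rng, numt, d_numt)
        if shared_flanks:
            block2 = fl + copy + fr
        else:
            block2 = random_dna(rng, flank) + copy + random_dna(rng, flank)
        genome = {"s1": random_dna(rng, 2_000) + fl + numt + fr + random_dna(rng, 3_000) + block2 + random_dna(rng, 2_000)}
        a = rec(1, 3_000, 3_500, ms=0, me=500)
        b_start = 2_000 + flank + 500 + flank + 3_000 + flank
        b = rec(2, b_start, b_start + 500, ms=0, me=500)
        return genome, [a, b]

    def test_identical_copies_with_identical_flanks_link(self, rng):
        genome, numts = self._two_copy_genome(rng)
        (fam,) = detect_duplicates(numts, genome)
        assert fam.member_ids == ("N1", "N2")
        ev = fam.evidence[0]
        assert ev.numt_similarity == 1.0
        assert max(ev.left_flank_similarity, ev.right_flank_similarity) == 1.0
        assert ev.flank_homology_len >= 900

    def test_similar_numts_with_unrelated_flanks_do_not_link(self, rng):
        genome, numts = self._two_copy_genome(rng, d_numt=0.05, shared_flanks=False)
        assert detect_duplicates(numts, genome) == []

    def test_duplicate_ids_rejected(self, rng):
        genome, numts = self._two_copy_genome(rng)
        with pytest.raises(ValueError, match="unique"):
            detect_duplicates([numts[0], numts[0]], genome)

    def test_planted_duplications_recovered(self):
        """Flank-carrying duplications are recovered as family links; no
        links appear among independent insertions."""
        cfg = SimConfig(seed=31, n_scaffolds=2, scaffold_lengths=(500_000, 500_000),
                        n_insertions=25, n_duplications=8, n_complex=0,
                        n_te_background=0, n_genes=0)
        res = simulate_genome(cfg)
        hits = filter_hits(scan_numts(res.mito, res.nuclear))
        records = records_from_hits(hits)
        fams = detect_duplicates(records, res.nuclear)
        truth_map = match_truth(records, res.truth)

        def links(groups):
            out = set()
            for ids in groups:
                ids = sorted(ids)
                out.update(frozenset((a, b)) for i, a in enumerate(ids) for b in ids[i + 1 :])
            return out

        truth_groups = defaultdict(list)
        for t in res.truth:
            if t.family_id:
                truth_groups[t.family_id].append(t.numt_id)
        true_links = links(truth_groups.values())
        found_links = links(
            [[truth_map[m].numt_id for m in f.member_ids if truth_map[m]] for f in fams]
        )
        assert true_links, "fixture should contain duplicate families"
        assert len(true_links & found_links) / len(true_links) >= 0.9
        assert not (found_links - true_links), "no false links among independent insertions"

        # labelling: the family originals (planted insertion-type) are mostly
        # recognised as insertion type
        labelled = label_types(records, fams)
        ins = sum(1 for r in labelled if r.type_label == "insertion")
        dup = sum(1 for r in labelled if r.type_label == "duplicate")
        assert ins + dup == len(labelled)
        originals = [t.numt_id for t in res.truth if t.family_id and t.true_type == "insertion"]
        correct = 0
        for r in labelled:
            t = truth_map[r.numt_id]
            if t and t.numt_id in originals and r.family_id is not None:
                correct += r.type_label == "insertion"
        assert originals and correct / len(originals) >= 0.8

    def test_family_components_match_bruteforce(self, rng):
        """Families equal the connected components of the evidence graph."""
        genome, numts = self._two_copy_genome(rng)
        extra = rec(3, 100, 400, ms=5_000, me=5_300)  # unrelated mito region
        fams = detect_duplicates(numts + [extra], genome)
        # brute-force components from the reported evidence
        parent = {n.numt_id: n.numt_id for n in numts + [extra]}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for f in fams:
            for e in f.evidence:
                parent[find(e.pair[1])] = find(e.pair[0])
        comps = defaultdict(set)
        for nid in parent:
            comps[find(nid)].add(nid)
        big = [sorted(c) for c in comps.values() if len(c) > 1]
        assert sorted(tuple(f.member_ids) for f in fams) == sorted(tuple(c) for c in big)


# ---------------------------------------------------------------------------
# type labelling


class TestLabelTypes:
    def test_no_families_all_insertion(self):
        numts = [rec(i, i * 1_000, i * 1_000 + 200) for i in range(1, 5)]
        labelled = label_types(numts, [])
        assert all(r.type_label == "insertion" for r in labelled)

    def test_family_of_three_gives_one_insertion_two_duplicates(self, rng):
        genome, numts = self._three_member_family(rng)
        fams = detect_duplicates(numts, genome)
        assert len(fams) == 1 and len(fams[0].member_ids) == 3
        labelled = label_types(numts, fams)
        counts = defaultdict(int)
        for r in labelled:
            counts[r.type_label] += 1
        assert counts == {"insertion": 1, "duplicate": 2}
        # the most mito-identical member is the putative original
        best = max(numts, key=lambda n: n.identity)
        assert next(r for r in labelled if r.numt_id == best.numt_id).type_label == "insertion"

    def test_whole_family_duplicate_mode(self, rng):
        genome, numts = self._three_member_family(rng)
        fams = detect_duplicates(numts, genome)
        labelled = label_types(numts, fams, originals_as_insertion=False)
        assert sum(1 for r in labelled if r.type_label == "duplicate") == 3

    def test_partition_identity_on_pipeline_output(self, bundle):
        fams = detect_duplicates(bundle.records, bundle.result.nuclear)
        labelled = label_types(bundle.records, fams)
        assert {r.type_label for r in labelled} <= {"insertion", "duplicate"}
        ins = sum(1 for r in labelled if r.type_label == "insertion")
        dup = sum(1 for r in labelled if r.type_label == "duplicate")
        assert ins + dup == len(bundle.records)

    def _three_member_family(self, rng):
        numt = random_dna(rng, 600)
        fl, fr = random_dna(rng, 1_000), random_dna(rng, 1_000)
        pieces, recs = [random_dna(rng, 2_000)], []
        idents = [0.99, 0.95, 0.93]
        for i, ident in enumerate(idents, 1):
            start = sum(len(p) for p in pieces) + 1_000
            # a duplication carries its flanks: numt and flanks diverge together
            pieces.append(mutate(rng, fl + numt + fr, 1 - ident))
            pieces.append(random_dna(rng, 2_500))
            recs.append(rec(i, start, start + 600, ms=0, me=600, identity=ident))
        return {"s1": "".join(pieces)}, recs


def test_with_cluster_ids(bundle):
    clusters = cluster_complex(bundle.records)
    tagged = with_cluster_ids(bundle.records, clusters)
    in_cluster = {m for c in clusters for m in c.member_ids}
    for r in tagged:
        assert (r.cluster_id is not None) == (r.numt_id in in_cluster)
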