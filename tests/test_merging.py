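import numpy as np
import pytest

from polysv import (
    ConsistencyError,
    MergeParams,
    SVCallSet,
    concordance,
    force_call,
    merge_callsets,
)

from conftest import make_record, random_callset


def brute_force_partition(records, params):
    """O(n^2) single-linkage union-find over the pairwise linkage relation:
    same stratum and both breakpoint distances within the threshold."""
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    d = params.max_breakpoint_distance
    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i], records[j]
            if a.chrom != b.chrom:
                continue
            if params.type_aware and a.svtype != b.svtype:
                continue
            if abs(a.pos - b.pos) <= d and abs(a.end - b.end) <= d:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(
            (records[i].sample_id, records[i].chrom, records[i].pos,
             records[i].end, records[i].svtype))
    return frozenset(frozenset(g) for g in groups.values())


def cluster_partition(clusters):
    return frozenset(
        frozenset((m.sample_id, m.chrom, m.pos, m.end, m.svtype)
                  for ms in cl.members.values() for m in ms)
        for cl in clusters)


def test_overlapping_deletions_from_two_samples_form_one_cluster():
    a = SVCallSet("s1", [make_record(sample="s1", pos=10_000, svlen=700)])
    b = SVCallSet("s2", [make_record(sample="s2", pos=10_300, svlen=700)])
    clusters = merge_callsets([a, b])
    assert len(clusters) == 1
    assert clusters[0].presence == {"s1": True, "s2": True}
    assert clusters[0].n_members == 2


def test_type_awareness_separates_colocated_del_and_ins():
    a = SVCallSet("s1", [make_record(sample="s1", pos=10_000, svtype="DEL",
                                     svlen=700)])
    b = SVCallSet("s2", [make_record(sample="s2", pos=10_000, svtype="INS",
                                     svlen=700)])
    assert len(merge_callsets([a, b])) == 2
    assert len(merge_callsets([a, b], MergeParams(type_aware=False))) == 1


def test_distance_threshold_separates_distant_breakpoints():
    a = SVCallSet("s1", [make_record(sample="s1", pos=10_000, svlen=700)])
    b = SVCallSet("s2", [make_record(sample="s2", pos=11_500, svlen=700)])
    assert len(merge_callsets([a, b])) == 2


def test_representatives_are_member_medians():
    a = SVCallSet("s1", [make_record(sample="s1", pos=10_000, svlen=700)])
    b = SVCallSet("s2", [make_record(sample="s2", pos=10_300, svlen=700)])
    c = SVCallSet("s3", [make_record(sample="s3", pos=10_600, svlen=700)])
    (cl,) = merge_callsets([a, b, c])
    assert cl.rep_pos == 10_300
    assert cl.rep_end == 11_000
    assert cl.rep_len == 700


def test_merge_matches_bruteforce_on_random_instances():
    params = MergeParams()
    for seed in range(20):
        rng = np.random.default_rng(seed)
        callsets = [random_callset(rng, sample=f"s{k}", n=60, pos_max=80_000)
                    for k in range(3)]
        clusters = merge_callsets(callsets, params)
        records = [r for cs in callsets for r in cs]
        assert cluster_partition(clusters) == brute_force_partition(records,
                                                                    params)
        # conservation
        assert sum(cl.n_members for cl in clusters) == len(records)


def test_merge_invariant_to_callset_and_record_order():
    rng = np.random.default_rng(17)
    callsets = [random_callset(rng, sample=f"s{k}", n=50, pos_max=60_000)
                for k in range(3)]
    ref = cluster_partition(merge_callsets(callsets))
    assert cluster_partition(merge_callsets(callsets[::-1])) == ref
    shuffled = []
    for cs in callsets:
        recs = list(cs.records)
        rng.shuffle(recs)
        shuffled.append(SVCallSet(cs.sample_id, recs))
    assert cluster_partition(merge_callsets(shuffled)) == ref


def test_merging_representatives_is_idempotent():
    rng = np.random.default_rng(23)
    callsets = [random_callset(rng, sample=f"s{k}", n=80, pos_max=50_000)
                for k in range(2)]
    clusters = merge_callsets(callsets)
    reps = SVCallSet("rep", [
        make_record(sample="rep", chrom=cl.chrom, pos=cl.rep_pos,
                    svtype=cl.svtype, svlen=max(cl.rep_len, 1))
        for cl in clusters])
    assert len(merge_callsets([reps])) == len(clusters)


def test_jitter_within_half_distance_is_recovered():
    """Planted cross-platform record pairs whose breakpoints are jittered by
    at most half the merge distance always co-cluster."""
    rng = np.random.default_rng(99)
    d = 1000
    recs_a, recs_b = [], []
    for i in range(300):
        pos = 5000 + i * 10_000
        svlen = int(rng.integers(50, 3000))
        jitter = int(rng.integers(-d // 2, d // 2 + 1))
        recs_a.append(make_record(sample="a", pos=pos, svlen=svlen))
        recs_b.append(make_record(sample="b", pos=pos + jitter, svlen=svlen))
    clusters = merge_callsets([SVCallSet("a", recs_a), SVCallSet("b", recs_b)],
                              MergeParams(max_breakpoint_distance=d))
    paired = sum(1 for cl in clusters if len(cl.members) == 2)
    assert paired >= 0.99 * 300


def test_force_call_geometric_matching():
    clusters = merge_callsets([
        SVCallSet("s1", [make_record(sample="s1", pos=10_150, svlen=700)])])
    near = SVCallSet("x", [make_record(sample="x", pos=10_100, svlen=700)])
    assert force_call(clusters, near) == [True]
    wrong_type = SVCallSet("x", [make_record(sample="x", pos=10_150,
                                             svtype="INS", svlen=700)])
    assert force_call(clusters, wrong_type) == [False]
    assert force_call(clusters, SVCallSet("x", [])) == [False]


def test_force_call_assigns_each_record_to_nearest_cluster_only():
    cs1 = SVCallSet("s1", [make_record(sample="s1", pos=10_000, svlen=700)])
    cs2 = SVCallSet("s2", [make_record(sample="s2", pos=11_500, svlen=700)])
    clusters = merge_callsets([cs1, cs2])  # two clusters 1500 apart
    probe = SVCallSet("x", [make_record(sample="x", pos=10_600, svlen=700)])
    # record is within 1000 of both representatives but supports only the
    # nearer one
    assert force_call(clusters, probe) == [True, False]


def test_concordance_counts():
    a = [True, True, False, True]
    b = [True, False, False, True]
    res = concordance(a, b)
    assert res == {"n_total": 4, "n_both": 2, "pct_both": 50.0}
    # identical vectors over a merged set are all-present (a cluster absent
    # from every member set cannot exist), hence 100%
    assert concordance([True] * 5, [True] * 5)["pct_both"] == 100.0
    assert concordance([True, False], [False, True])["pct_both"] == 0.0
    assert concordance([], [])["pct_both"] is None
    with pytest.raises(ConsistencyError):
        concordance([True], [True, False])
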