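import itertools

import numpy as np
import pytest

from polysv import (
    GeneModel,
    GenomeLayout,
    SVCallSet,
    amplicon_implied_length,
    count_intragenic,
    group_gene_sets,
    intersect_genes,
    qtl_candidates,
    read_gff3,
    subgenome_rates,
    window_counts,
    write_gff3,
)

from conftest import make_record


def gene(gid="g1", chrom="A01", start=4000, end=6000, strand="+", exons=()):
    return GeneModel(gene_id=gid, chrom=chrom, start=start, end=end,
                     strand=strand, exons=tuple(exons))


def test_deletion_overlapping_exon_is_exonic():
    g = gene(exons=[(4900, 5100)])
    cs = SVCallSet("s1", [make_record(pos=5000, svlen=700)])
    res = intersect_genes(cs, [g])
    assert res.gene_hits == {"g1": {0}}
    assert res.sv_label[0] == "exonic"


def test_deletion_missing_all_exons_is_intronic():
    g = gene(exons=[(4000, 4100), (5900, 6000)])
    cs = SVCallSet("s1", [make_record(pos=4500, svlen=700)])
    res = intersect_genes(cs, [g])
    assert res.sv_label[0] == "intronic"


def test_insertion_upstream_of_plus_gene_is_promoter():
    g = gene(start=6000, end=7000, strand="+")
    cs = SVCallSet("s1", [make_record(pos=5000, svtype="INS", svlen=90)])
    res = intersect_genes(cs, [g], promoter_flank=2000)
    assert res.sv_label[0] == "promoter"
    assert res.promoter_hits == {"g1": {0}}


def test_promoter_is_strand_aware():
    g = gene(start=6000, end=7000, strand="-")
    upstream_of_minus = SVCallSet(
        "s1", [make_record(pos=7500, svtype="INS", svlen=90)])
    res = intersect_genes(upstream_of_minus, [g], promoter_flank=2000)
    assert res.sv_label[0] == "promoter"
    wrong_side = SVCallSet(
        "s1", [make_record(pos=5000, svtype="INS", svlen=90)])
    assert intersect_genes(wrong_side, [g], 2000).sv_label[0] == "intergenic"


def test_no_overlap_across_chromosomes():
    g = gene(chrom="C01")
    cs = SVCallSet("s1", [make_record(chrom="A01", pos=5000, svlen=700)])
    res = intersect_genes(cs, [g])
    assert res.gene_hits == {} and res.sv_label[0] == "intergenic"


def test_interval_overlap_matches_allpairs_bruteforce():
    rng = np.random.default_rng(2)
    for _ in range(25):
        genes = []
        for i in range(30):
            start = int(rng.integers(1, 400_000))
            end = start + int(rng.integers(200, 4000))
            mid = (start + end) // 2
            genes.append(gene(gid=f"g{i}",
                              chrom=str(rng.choice(["A01", "C01"])),
                              start=start, end=end,
                              exons=[(start, mid)]))
        recs = []
        for j in range(60):
            svtype = str(rng.choice(["DEL", "INS", "INV"]))
            recs.append(make_record(chrom=str(rng.choice(["A01", "C01"])),
                                    pos=int(rng.integers(1, 400_000)),
                                    svtype=svtype,
                                    svlen=int(rng.integers(30, 3000))))
        cs = SVCallSet("s1", recs)
        res = intersect_genes(cs, genes)
        # brute force: 1-based inclusive interval overlap per pair
        expected_hits = {}
        for i, r in enumerate(cs):
            lo, hi = r.span
            for g in genes:
                if g.chrom == r.chrom and lo < g.end and hi > g.start - 1:
                    expected_hits.setdefault(g.gene_id, set()).add(i)
        assert res.gene_hits == expected_hits


def test_exonic_plus_intronic_equals_intragenic():
    rng = np.random.default_rng(8)
    genes = [gene(gid=f"g{i}", start=1 + 10_000 * i, end=6000 + 10_000 * i,
                  exons=[(1 + 10_000 * i, 2000 + 10_000 * i)])
             for i in range(20)]
    cs = SVCallSet("s1", [make_record(pos=int(rng.integers(1, 210_000)),
                                      svlen=int(rng.integers(30, 2000)))
                          for _ in range(100)])
    res = intersect_genes(cs, genes)
    stats = count_intragenic(res, n_total_genes=len(genes))
    assert stats["n_exonic_sv"] + stats["n_intronic_sv"] == stats["n_intragenic_sv"]


def test_intragenic_percentages():
    genes = [gene(gid="g1"), gene(gid="g2", start=14_000, end=16_000),
             gene(gid="g3", start=24_000, end=26_000)]
    cs = SVCallSet("s1", [make_record(pos=5000, svlen=100),
                          make_record(pos=15_000, svlen=100)])
    stats = count_intragenic(intersect_genes(cs, genes), n_total_genes=3)
    assert stats["n_genes_hit"] == 2
    assert stats["pct_genes_hit"] == 66.7
    empty = count_intragenic(
        intersect_genes(SVCallSet("s1", []), genes), n_total_genes=3)
    assert empty["exon_pct"] is None


def test_window_tiling_and_conservation():
    layout = GenomeLayout([("A01", 2_500_000)])
    cs = SVCallSet("s1", [make_record(pos=1_500_000, svlen=100)])
    df = window_counts(cs, layout)
    assert len(df) == 3
    assert df.iloc[-1]["end"] == 2_500_000
    row = df[(df.start == 1_000_001)].iloc[0]
    assert row["DEL"] == 1 and df["DEL"].sum() == 1

    rng = np.random.default_rng(4)
    recs = [make_record(chrom="A01", pos=int(rng.integers(1, 2_500_000)),
                        svtype=str(rng.choice(["DEL", "INS"])),
                        svlen=int(rng.integers(30, 500)))
            for _ in range(100)]
    df = window_counts(SVCallSet("s1", recs), layout)
    assert int(df["DEL"].sum() + df["INS"].sum()) == 100


def test_subgenome_rates_null_and_errors():
    layout = GenomeLayout([(f"A{i:02d}", 1_000_000) for i in range(1, 5)]
                          + [(f"C{i:02d}", 1_000_000) for i in range(1, 5)])
    equal = {c: 50 for c in layout.names}
    res = subgenome_rates(equal, layout)
    assert res["p_value"] == 1.0
    assert res["rate_A"] == res["rate_C"] == 50.0
    single = GenomeLayout([("A01", 1_000_000), ("C01", 1_000_000)])
    with pytest.raises(ValueError):
        subgenome_rates(equal, single)


def test_subgenome_bias_detected_on_planted_signal():
    rng = np.random.default_rng(12)
    layout = GenomeLayout([(f"A{i:02d}", 2_000_000) for i in range(1, 11)]
                          + [(f"C{i:02d}", 2_000_000) for i in range(1, 10)])
    counts = {c: int(rng.poisson(80 if c.startswith("A") else 40))
              for c in layout.names}
    res = subgenome_rates(counts, layout)
    assert res["p_value"] < 0.05
    assert 1.5 < res["rate_A"] / res["rate_C"] < 2.5


def test_group_gene_sets_regions():
    report = group_gene_sets(
        {"s1": {"g1", "g2"}, "s2": {"g2", "g3"}},
        {"s1": "a", "s2": "b"})
    assert report.regions[("a", "b")] == 1
    assert report.unique_to("a") == 1 and report.unique_to("b") == 1

    same = {f"s{i}": {"x", "y"} for i in range(4)}
    groups = {f"s{i}": f"G{i}" for i in range(4)}
    rep = group_gene_sets(same, groups)
    assert rep.common_all == 2
    assert sum(rep.regions.values()) == 2  # regions partition the union


def test_group_gene_sets_match_inclusion_exclusion_bruteforce():
    rng = np.random.default_rng(9)
    universe = [f"g{i}" for i in range(40)]
    samples = {f"s{i}": set(rng.choice(universe, size=15, replace=False))
               for i in range(6)}
    groups = {f"s{i}": f"G{i % 3}" for i in range(6)}
    rep = group_gene_sets(samples, groups)
    gsets = rep.group_sets
    names = sorted(gsets)
    for r in range(1, 4):
        for combo in itertools.combinations(names, r):
            expected = sum(
                1 for el in set().union(*gsets.values())
                if all(el in gsets[g] for g in combo)
                and all(el not in gsets[g] for g in names if g not in combo))
            assert rep.regions[combo] == expected
    assert sum(rep.regions.values()) == len(set().union(*gsets.values()))


def test_more_than_four_groups_reports_pairwise():
    samples = {f"s{i}": {f"g{i}"} for i in range(5)}
    groups = {f"s{i}": f"G{i}" for i in range(5)}
    rep = group_gene_sets(samples, groups)
    assert rep.regions == {}
    assert len(rep.pairwise) == 10


def make_interval_genes(n=606, chrom="C05", start=6_329_426, end=10_659_726):
    span = (end - start) // n
    return [GeneModel(gene_id=f"q{i:03d}", chrom=chrom,
                      start=start + i * span, end=start + i * span + 500)
            for i in range(n)]


def test_qtl_candidates_symmetric_difference():
    genes = make_interval_genes()
    ids = [g.gene_id for g in genes]
    a = set(ids[:37])
    b = set(ids[20:37]) | set(ids[40:68])   # |B| = 45, |A&B| = 17
    res = qtl_candidates("C05", 6_329_426, 10_659_726, genes, a, b)
    assert len(res.candidates_a) == 20
    assert len(res.candidates_b) == 28
    assert res.n_common_dropped == 17
    assert res.interval_mbp == 4.3
    assert res.n_genes == 606

    res_same = qtl_candidates("C05", 6_329_426, 10_659_726, genes, a, a)
    assert res_same.candidates_a == [] and res_same.candidates_b == []

    res_disjoint = qtl_candidates("C05", 6_329_426, 10_659_726, genes,
                                  set(ids[:10]), set(ids[10:20]))
    assert len(res_disjoint.candidates_a) + len(res_disjoint.candidates_b) == 20


def test_qtl_keyword_filter_and_empty_interval():
    genes = make_interval_genes(n=10)
    ids = [g.gene_id for g in genes]
    ann = {ids[0]: "defence response protein", ids[1]: "unknown"}
    res = qtl_candidates("C05", 6_329_426, 10_659_726, genes,
                         {ids[0], ids[1]}, set(), keywords=["defence"],
                         gene_annotations=ann)
    assert res.candidates_a == [ids[0]]
    with pytest.raises(ValueError):
        qtl_candidates("C05", 100, 100, genes, set(), set())


def test_amplicon_arithmetic():
    assert amplicon_implied_length(900, 200) == 700
    assert amplicon_implied_length(1060, 1170) == -110  # insertion case
    with pytest.raises(ValueError):
        amplicon_implied_length(0, 100)


def test_gff3_roundtrip(tmp_path):
    genes = [gene(gid="gA", exons=[(4100, 4500), (5000, 5500)]),
             gene(gid="gB", chrom="C01", start=100, end=900, strand="-",
                  exons=[(100, 900)])]
    p = tmp_path / "genes.gff3"
    write_gff3(genes, p)
    back = read_gff3(p)
    assert {g.gene_id: (g.chrom, g.start, g.end, g.strand, g.exons)
            for g in back} == \
           {g.gene_id: (g.chrom, g.start, g.end, g.strand, g.exons)
            for g in genes}
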