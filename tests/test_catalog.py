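"""Alignment building, SNP classification and hierarchy attribution."""
import numpy as np
import pytest

from poolskim import (
    FIXED_DIFFERENCE,
    MIXED,
    WITHIN_POOL_ONLY,
    MinorAllele,
    PoolConsensus,
    ReferenceLocus,
    SamplingDesign,
    ScenarioConfig,
    SequencingModel,
    VariantCall,
    build_alignment,
    call_study,
    classify_snps,
    count_between,
    count_unique_fixed,
    generate_study,
)


def consensus(site, sequence, variant_positions=(), locus="cpDNA"):
    variants = tuple(
        VariantCall(
            position=p,
            major_allele=sequence[p],
            minor_alleles=(MinorAllele("G" if sequence[p] != "G" else "T", 0.2, True, True),),
            depth=40,
        )
        for p in variant_positions
    )
    return PoolConsensus(site=site, locus_id=locus, sequence=sequence, variants=variants)


def variants_map(consensuses):
    return {c.site: list(c.variants) for c in consensuses}


def test_identical_unmasked_consensuses_have_no_polymorphism(small_design):
    cs = [consensus(s, "ACGTACGT") for s in small_design.site_labels]
    aln = build_alignment(cs)
    assert aln.analysable.all()
    assert classify_snps(aln, variants_map(cs), small_design) == []


def test_masking_propagates_to_all_sites(small_design):
    seq = "A" * 30
    masked = "A" * 10 + "N" * 10 + "A" * 10
    cs = [consensus("N1a", masked)] + [
        consensus(s, seq) for s in small_design.site_labels[1:]
    ]
    aln = build_alignment(cs)
    assert set(np.nonzero(~aln.analysable)[0]) == set(range(10, 20))
    assert aln.analysable_length == 20


def test_alignment_rejects_mixed_loci_and_lengths():
    with pytest.raises(ValueError, match="length"):
        build_alignment([consensus("A", "ACGT"), consensus("B", "ACGTA")])
    with pytest.raises(ValueError, match="loci"):
        build_alignment(
            [consensus("A", "ACGT"), consensus("B", "ACGT", locus="nrDNA")]
        )


def test_private_fixed_snp_attributed_to_site_and_catchment(default_design):
    """A column where one Richmond site carries T and the 11 other sites
    carry C is a fixed difference private to that site and catchment."""
    cs = [
        consensus(site, "ACTAC" if site == "BS" else "ACCAC")
        for site in default_design.site_labels
    ]
    aln = build_alignment(cs)
    records = classify_snps(aln, variants_map(cs), default_design)
    (record,) = records
    assert record.position == 2
    assert record.kind == FIXED_DIFFERENCE
    assert record.private_to_site == "BS"
    assert record.private_to_catchment == "Richmond"
    assert record.private_to_region == "NNSW"
    assert count_unique_fixed(records, "Richmond", default_design) == 1
    assert count_unique_fixed(records, "Clarence", default_design) == 0


def test_within_pool_only_and_mixed_kinds(small_design):
    sites = small_design.site_labels
    # column 1: consensuses equal, one pool polymorphic -> within_pool_only
    # column 3: consensuses differ AND a pool polymorphic there -> mixed
    seqs = {s: "AAAAA" for s in sites}
    seqs["S1a"] = "AAATA"
    cs = [
        consensus(s, seqs[s], variant_positions=(1,) if s == "N1a" else ())
        for s in sites
    ]
    cs[2] = consensus("S1a", seqs["S1a"], variant_positions=(3,))
    by_site = variants_map(cs)
    aln = build_alignment(cs)
    records = classify_snps(aln, by_site, small_design)
    kinds = {r.position: r.kind for r in records}
    assert kinds == {1: WITHIN_POOL_ONLY, 3: MIXED}
    # mixed columns never count as fixed differences
    assert count_unique_fixed(records, "s1", small_design) == 0


def test_classification_partitions_polymorphic_columns(small_design, rng):
    """Every analysable polymorphic column yields exactly one record."""
    sites = small_design.site_labels
    length = 60
    base = rng.integers(0, 4, size=length)
    seqs = {}
    for i, s in enumerate(sites):
        codes = base.copy()
        flip = rng.choice(length, size=5, replace=False)
        codes[flip] = (codes[flip] + 1 + i) % 4
        mask = rng.choice(length, size=4, replace=False)
        seq = "".join("ACGT"[c] for c in codes)
        seqs[s] = "".join("N" if j in set(mask.tolist()) else b for j, b in enumerate(seq))
    cs = [PoolConsensus(site=s, locus_id="cpDNA", sequence=seqs[s]) for s in sites]
    aln = build_alignment(cs)
    records = classify_snps(aln, {}, small_design)
    polymorphic = [
        p for p in np.nonzero(aln.analysable)[0]
        if len({seqs[s][p] for s in sites}) > 1
    ]
    assert sorted(r.position for r in records) == polymorphic
    assert len({r.position for r in records}) == len(records)


def test_three_catchment_private_count_construction():
    """Constructed toy: known numbers of catchment-private fixed columns."""
    design = SamplingDesign(
        regions=("r",),
        catchments={"c1": "r", "c2": "r", "c3": "r"},
        sites={"A": "c1", "B": "c1", "C": "c2", "D": "c2", "E": "c3", "F": "c3"},
        pool_size=8,
    )
    length = 40
    ref = ["A"] * length
    seqs = {s: ref.copy() for s in design.site_labels}
    private = {"c1": 3, "c2": 5, "c3": 2}
    pos = 0
    for catchment, n in private.items():
        for _ in range(n):
            for site in design.sites_in_catchment(catchment):
                seqs[site][pos] = "T"
            pos += 1
    cs = [
        PoolConsensus(site=s, locus_id="cpDNA", sequence="".join(seqs[s]))
        for s in design.site_labels
    ]
    records = classify_snps(build_alignment(cs), {}, design)
    for catchment, n in private.items():
        assert count_unique_fixed(records, catchment, design) == n
    total_fixed = sum(1 for r in records if r.kind == FIXED_DIFFERENCE)
    assert sum(private.values()) <= total_fixed
    with pytest.raises(KeyError):
        count_unique_fixed(records, "nope", design)


def test_count_between_construction_and_symmetry(small_design):
    sites = small_design.site_labels  # N1a N2a S1a S2a
    k = 6
    north = "A" * 30
    south = "".join("T" if i < k else "A" for i in range(30))
    cs = [
        consensus(s, north if s.startswith("N") else south) for s in sites
    ]
    aln = build_alignment(cs)
    records = classify_snps(aln, variants_map(cs), small_design)
    a, b = {"N1a", "N2a"}, {"S1a", "S2a"}
    assert count_between(records, aln, a, b) == k
    assert count_between(records, aln, b, a) == k
    assert count_between(records, aln, {"N1a"}, {"N2a"}) == 0
    with pytest.raises(ValueError, match="overlap"):
        count_between(records, aln, a, a)
    with pytest.raises(ValueError, match="non-empty"):
        count_between(records, aln, set(), b)


def test_within_pool_variant_vetoes_member_fixed_difference(small_design):
    """A column is not a fixed difference for groups whose member pools are
    internally polymorphic there."""
    sites = small_design.site_labels
    seqs = {s: ("TAAA" if s.startswith("S") else "AAAA") for s in sites}
    cs = [
        consensus(s, seqs[s], variant_positions=(0,) if s == "S1a" else ())
        for s in sites
    ]
    aln = build_alignment(cs)
    records = classify_snps(aln, variants_map(cs), small_design)
    assert records[0].kind == MIXED
    assert count_between(records, aln, {"N1a", "N2a"}, {"S1a", "S2a"}) == 0
    # the polymorphic pool is outside these groups, so the column counts
    assert count_between(records, aln, {"N1a", "N2a"}, {"S2a"}) == 1


def test_variant_at_masked_column_rejected(small_design):
    cs = [consensus(s, "AAAA") for s in small_design.site_labels]
    bad = {
        "N1a": [
            VariantCall(0, "A", (MinorAllele("G", 0.2, True, True),), 40)
        ]
    }
    cs[0] = PoolConsensus(site="N1a", locus_id="cpDNA", sequence="NAAA")
    aln = build_alignment(cs)
    with pytest.raises(ValueError, match="masked"):
        classify_snps(aln, bad, small_design)


def test_simulated_polymorphic_columns_match_ground_truth(default_design):
    """Error-free deep sequencing: polymorphic columns in the SNP catalog
    equal the segregating ground-truth site-consensus differences that
    survive masking."""
    locus = ReferenceLocus.random("cpDNA", 2_000, seed=8)
    scenarios = {
        "AWT": ScenarioConfig(
            scenario="persistence", n_founder_lineages=3,
            lineage_divergence=10_000, mutation_rate=1e-6, rng_seed=0,
        ),
        "NNSW": ScenarioConfig(
            scenario="founder_expansion", founder_age=0, mutation_rate=1e-6, rng_seed=0,
        ),
    }
    study = generate_study(
        default_design, [locus], scenarios,
        SequencingModel(mean_depth=80, error_rate=0.0), seed=11,
    )
    consensuses = call_study(
        [study.pileups[(s, "cpDNA")] for s in default_design.site_labels]
    )
    aln = build_alignment(consensuses)
    records = classify_snps(
        aln, {c.site: list(c.variants) for c in consensuses}, default_design
    )
    # expected: columns analysable after masking where site haplotypes differ
    site_codes = {
        s: study.haplotypes_for(s, "cpDNA")[0].codes for s in default_design.site_labels
    }
    matrix = np.stack([site_codes[s] for s in default_design.site_labels])
    expected = [
        int(p)
        for p in np.nonzero((matrix != matrix[0]).any(axis=0))[0]
        if aln.analysable[p]
    ]
    assert sorted(r.position for r in records) == expected
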