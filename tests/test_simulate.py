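"""Simulator behaviour: lineage structure, pooling, sequencing channel."""
import numpy as np
import pytest
from scipy import stats

from poolskim import (
    Haplotype,
    ReferenceLocus,
    SamplingDesign,
    ScenarioConfig,
    SequencingModel,
    generate_study,
    simulate_haplotypes,
    simulate_pool_pileup,
)


def test_zero_mutation_rate_reproduces_reference(small_design, small_locus):
    scenario = ScenarioConfig(
        scenario="persistence", n_founder_lineages=2,
        founder_age=500, lineage_divergence=5_000, mutation_rate=0.0, rng_seed=3,
    )
    haps = simulate_haplotypes(small_design, small_locus, scenario)
    assert len(haps) == len(small_design.sites) * small_design.pool_size
    assert all(h.sequence == small_locus.sequence for h in haps)


def test_single_founder_age_zero_is_homogeneous_within_region(small_design, small_locus):
    scenario = ScenarioConfig(
        scenario="founder_expansion", n_founder_lineages=1,
        founder_age=0, lineage_divergence=0, mutation_rate=1e-4, rng_seed=5,
    )
    haps = simulate_haplotypes(small_design, small_locus, scenario)
    for region in small_design.regions:
        seqs = {h.sequence for h in haps if small_design.region_of_site(h.site) == region}
        assert len(seqs) == 1


def test_invalid_scenario_parameters_rejected():
    with pytest.raises(ValueError):
        ScenarioConfig(scenario="founder_expansion", n_founder_lineages=0)
    with pytest.raises(ValueError):
        ScenarioConfig(scenario="persistence", mutation_rate=-1e-9)
    with pytest.raises(ValueError):
        ReferenceLocus("cpDNA", "")


def test_pairwise_divergence_matches_poisson_expectation():
    """Two lineages diverged T generations at rate mu accumulate ~2*mu*T*L
    pairwise differences (Monte-Carlo mean vs the analytic value)."""
    design = SamplingDesign(
        regions=("r",), catchments={"c1": "r", "c2": "r"},
        sites={"A": "c1", "B": "c2"}, pool_size=1,
    )
    locus = ReferenceLocus.random("cpDNA", 2_000, seed=11)
    mu, T = 1e-5, 50
    expected = 2 * mu * T * locus.length  # = 2.0
    diffs = []
    for seed in range(400):
        scenario = ScenarioConfig(
            scenario="persistence", n_founder_lineages=2,
            founder_age=0, lineage_divergence=T, mutation_rate=mu, rng_seed=seed,
        )
        a, b = simulate_haplotypes(design, locus, scenario)
        diffs.append(sum(x != y for x, y in zip(a.sequence, b.sequence)))
    mean = np.mean(diffs)
    se = np.std(diffs) / np.sqrt(len(diffs))
    assert abs(mean - expected) < max(4 * se, 0.05 * expected)


def test_divergence_monotonic_in_lineage_divergence():
    """Mean pairwise haplotype divergence grows with lineage_divergence."""
    design = SamplingDesign(
        regions=("r",), catchments={"c1": "r", "c2": "r"},
        sites={"A": "c1", "B": "c2"}, pool_size=1,
    )
    locus = ReferenceLocus.random("cpDNA", 1_000, seed=13)
    means = []
    for T in (20, 100, 500):
        diffs = []
        for seed in range(120):
            scenario = ScenarioConfig(
                scenario="persistence", n_founder_lineages=2,
                lineage_divergence=T, mutation_rate=2e-5, rng_seed=seed,
            )
            a, b = simulate_haplotypes(design, locus, scenario)
            diffs.append(sum(x != y for x, y in zip(a.sequence, b.sequence)))
        means.append(np.mean(diffs))
    assert means[0] < means[1] < means[2]


def _singleton_pool(locus, pos=100, alt="G", pool_size=8):
    seqs = [locus.sequence] * (pool_size - 1)
    ref = locus.sequence
    carrier = ref[:pos] + alt + ref[pos + 1:]
    assert carrier != ref
    seqs.append(carrier)
    return [
        Haplotype(f"S|{i+1}", "S", locus.locus_id, s) for i, s in enumerate(seqs)
    ]


def test_error_free_identical_pool_is_monomorphic(small_locus):
    haps = [
        Haplotype(f"S|{i+1}", "S", "cpDNA", small_locus.sequence) for i in range(8)
    ]
    pileup = simulate_pool_pileup(haps, SequencingModel(mean_depth=30, error_rate=0.0), seed=1)
    per_base = pileup.counts.sum(axis=2)
    assert ((per_base > 0).sum(axis=1) <= 1).all()


def test_singleton_allele_frequency_expectation():
    """A 1-of-8 carrier allele tallies at ~12.5% of reads at high depth."""
    locus = ReferenceLocus.random("cpDNA", 50, seed=3)
    pos = 10
    ref_base = locus.sequence[pos]
    alt = "A" if ref_base != "A" else "C"
    haps = _singleton_pool(locus, pos=pos, alt=alt)
    model = SequencingModel(mean_depth=20_000, error_rate=0.0)
    pileup = simulate_pool_pileup(haps, model, seed=9)
    per_base = pileup.counts[pos].sum(axis=1)
    depth = per_base.sum()
    frac = per_base["ACGT".index(alt)] / depth
    # binomial(depth, 1/8): 4 sigma band
    sigma = np.sqrt(0.125 * 0.875 / depth)
    assert abs(frac - 0.125) < 4 * sigma


def test_singleton_call_rate_matches_enumeration_oracle():
    """Empirical call rate of a 1-of-8 allele at depth exactly 20 matches
    the exact binomial computation for the caller thresholds (freq >= 12.5%
    i.e. >= 3 of 20 reads, >= 1 read per strand)."""
    from poolskim import PoolCallerConfig, call_pool

    locus = ReferenceLocus.random("cpDNA", 150_000, seed=21)
    # make every position a singleton-alt column via one divergent haplotype
    ref = locus.sequence
    shifted = "".join("ACGT"[("ACGT".index(b) + 1) % 4] for b in ref)
    haps = [Haplotype(f"S|{i+1}", "S", "cpDNA", ref) for i in range(7)]
    haps.append(Haplotype("S|8", "S", "cpDNA", shifted))
    model = SequencingModel(mean_depth=20, error_rate=0.0)
    pileup = simulate_pool_pileup(haps, model, seed=4)

    consensus = call_pool(pileup, PoolCallerConfig())
    called = np.zeros(locus.length, dtype=bool)
    called[list(consensus.variant_positions)] = True
    depth = pileup.depth
    at_20 = depth == 20
    empirical = called[at_20].mean()

    # exact: alt count k ~ Binomial(20, 1/8); called iff k >= 3 and both
    # strands see >= 1 alt read (strands split Binomial(k, 1/2))
    k = np.arange(3, 21)
    p_exact = float(
        np.sum(stats.binom.pmf(k, 20, 0.125) * (1 - 2 * 0.5**k))
    )
    n = int(at_20.sum())
    se = np.sqrt(p_exact * (1 - p_exact) / n)
    assert abs(empirical - p_exact) < 4 * se


def test_generate_study_bookkeeping_and_determinism(default_design):
    loci = [
        ReferenceLocus.random("cpDNA", 1_000, seed=1),
        ReferenceLocus.random("nrDNA", 400, seed=2, intra_individual_variants=1.0),
    ]
    scenarios = {
        "AWT": ScenarioConfig(
            scenario="persistence", n_founder_lineages=3,
            lineage_divergence=3_000, mutation_rate=1e-6, rng_seed=0,
        ),
        "NNSW": ScenarioConfig(
            scenario="founder_expansion", n_founder_lineages=1,
            founder_age=100, mutation_rate=1e-6, rng_seed=0,
        ),
    }
    model = SequencingModel(mean_depth=40, error_rate=0.001)
    study1 = generate_study(default_design, loci, scenarios, model, seed=42)
    study2 = generate_study(default_design, loci, scenarios, model, seed=42)
    assert len(study1.pileups) == 12 * 2
    for key in study1.pileups:
        assert np.array_equal(study1.pileups[key].counts, study2.pileups[key].counts)
    assert study1.truth.equals(study2.truth)
    assert [h.sequence for h in study1.haplotypes["cpDNA"]] == [
        h.sequence for h in study2.haplotypes["cpDNA"]
    ]

    study3 = generate_study(default_design, loci, scenarios, model, seed=43)
    assert not all(
        np.array_equal(study1.pileups[k].counts, study3.pileups[k].counts)
        for k in study1.pileups
    )


def test_ground_truth_recounts_haplotype_matrix(default_design):
    locus = ReferenceLocus.random("cpDNA", 800, seed=5)
    scenarios = {
        "AWT": ScenarioConfig(
            scenario="persistence", n_founder_lineages=3,
            lineage_divergence=5_000, mutation_rate=1e-6, rng_seed=0,
        ),
        "NNSW": ScenarioConfig(
            scenario="founder_expansion", founder_age=500, mutation_rate=1e-6, rng_seed=0,
        ),
    }
    study = generate_study(
        default_design, [locus], scenarios, SequencingModel(mean_depth=30), seed=7
    )
    matrix = np.stack([h.codes for h in study.haplotypes["cpDNA"]])
    mutated_cols = int(((matrix != locus.codes).any(axis=0)).sum())
    assert len(study.truth) == mutated_cols
    assert set(study.truth["position"]) == set(
        np.nonzero((matrix != locus.codes).any(axis=0))[0].tolist()
    )


def test_region_without_scenario_raises(default_design):
    locus = ReferenceLocus.random("cpDNA", 100, seed=1)
    with pytest.raises(ValueError, match="no scenario"):
        generate_study(
            default_design, [locus],
            {"AWT": ScenarioConfig(scenario="persistence")},
            SequencingModel(), seed=0,
        )


def test_empty_pool_rejected():
    with pytest.raises(ValueError, match="empty"):
        simulate_pool_pileup([], SequencingModel(), seed=0)
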