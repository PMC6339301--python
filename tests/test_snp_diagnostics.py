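"""Variant classification, stringent filtering, Weir-Cockerham F_ST."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capkit import snp_diagnostics as snp
from capkit import synthetic_data as sd


def var(chrom="c1", pos=1, ref="A", alts=("G",), qual=1000.0, genotypes=()):
    return snp.VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alts=tuple(alts), qual=qual,
        genotypes=tuple(genotypes),
    )


# genotype shorthands over a biallelic site (0 = ref allele, 1 = alt)
AA, Aa, aa, NN = (0, 0), (0, 1), (1, 1), None


class TestClassifyVariants:
    def test_empty_input(self):
        c = snp.classify_variants([])
        assert (c.biallelic_snp, c.indel, c.multiallelic_snp) == (0, 0, 0)

    def test_definitional_examples(self):
        records = [
            var(alts=("G",)),
            var(alts=("G", "T")),
            var(alts=("AG",)),
        ]
        c = snp.classify_variants(records)
        assert (c.biallelic_snp, c.multiallelic_snp, c.indel) == (1, 1, 1)

    def test_deletion_counts_as_indel(self):
        c = snp.classify_variants([var(ref="AT", alts=("A",))])
        assert c.indel == 1

    def test_counts_match_planted_labels(self):
        rng = np.random.default_rng(0)
        records, truth = [], {"biallelic_snp": 0, "indel": 0, "multiallelic_snp": 0}
        for i in range(1000):
            kind = rng.choice(["biallelic_snp", "indel", "multiallelic_snp"])
            truth[kind] += 1
            if kind == "biallelic_snp":
                records.append(var(chrom=f"c{i}", alts=("G",)))
            elif kind == "indel":
                records.append(var(chrom=f"c{i}", alts=("AGG",)))
            else:
                records.append(var(chrom=f"c{i}", alts=("G", "T")))
        c = snp.classify_variants(records)
        assert (c.biallelic_snp, c.indel, c.multiallelic_snp) == (
            truth["biallelic_snp"], truth["indel"], truth["multiallelic_snp"]
        )


class TestMinorAlleleFrequency:
    def test_all_heterozygotes(self):
        assert snp.minor_allele_frequency([Aa] * 6) == 0.5

    def test_counting_example(self):
        gts = [AA] * 9 + [Aa]
        assert snp.minor_allele_frequency(gts) == pytest.approx(0.05)

    def test_missing_excluded_from_denominator(self):
        assert snp.minor_allele_frequency([Aa, NN, NN]) == 0.5

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            snp.minor_allele_frequency([NN, NN])

    @given(st.integers(0, 5000))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_tally(self, seed):
        rng = np.random.default_rng(seed)
        gts = []
        for _ in range(rng.integers(1, 20)):
            if rng.random() < 0.2:
                gts.append(None)
            else:
                gts.append(tuple(sorted(rng.integers(0, 2, 2))))
        if all(g is None for g in gts):
            return
        alleles = [a for g in gts if g is not None for a in g]
        p = sum(alleles) / len(alleles)
        assert snp.minor_allele_frequency(gts) == pytest.approx(min(p, 1 - p))


class TestStringentFilter:
    def test_empty_input(self):
        assert snp.stringent_filter([]) == []

    def test_missing_genotype_removes_site(self):
        rec = var(qual=900.0, genotypes=[Aa, Aa, NN, aa, AA])
        assert snp.stringent_filter([rec]) == []

    def test_quality_boundary_is_strict(self):
        keep = var(qual=500.1, genotypes=[Aa] * 4)
        drop = var(chrom="c2", qual=500.0, genotypes=[Aa] * 4)
        assert snp.stringent_filter([keep, drop]) == [keep]

    def test_maf_boundary_is_inclusive(self):
        at_boundary = var(genotypes=[AA] * 9 + [Aa])  # MAF exactly 0.05
        below = var(chrom="c2", genotypes=[AA] * 19 + [Aa])
        assert snp.stringent_filter([at_boundary, below]) == [at_boundary]

    def test_non_biallelic_removed(self):
        rec = var(alts=("G", "T"), genotypes=[Aa] * 4)
        indel = var(chrom="c2", alts=("AG",), genotypes=[Aa] * 4)
        assert snp.stringent_filter([rec, indel]) == []

    def test_order_preserved_and_idempotent(self):
        rng = np.random.default_rng(3)
        records = []
        for i in range(50):
            gts = [tuple(sorted(rng.integers(0, 2, 2))) for _ in range(6)]
            if rng.random() < 0.3:
                gts[rng.integers(0, 6)] = None
            records.append(var(chrom=f"c{i}", qual=float(rng.uniform(0, 2000)),
                               genotypes=gts))
        once = snp.stringent_filter(records)
        assert [r.chrom for r in once] == [
            r.chrom for r in records if r in once
        ]  # relative order kept
        assert snp.stringent_filter(once) == once

    def test_report_counts_match_planted_failures(self):
        records = [
            var(chrom="pass", genotypes=[Aa] * 6),
            var(chrom="low_qual", qual=100.0, genotypes=[Aa] * 6),
            var(chrom="missing", genotypes=[Aa] * 5 + [NN]),
            var(chrom="low_maf", genotypes=[AA] * 29 + [Aa]),
            var(chrom="multi", alts=("G", "T"), genotypes=[Aa] * 6),
        ]
        retained, report = snp.stringent_filter(records, return_report=True)
        assert [r.chrom for r in retained] == ["pass"]
        assert report.fail_qual == 1
        assert report.fail_missing == 1
        assert report.fail_maf == 1
        assert report.fail_not_biallelic == 1
        assert report.n_retained == 1


def wc_oracle_components(pop_genotypes):
    """Exact-fraction Weir-Cockerham components, derived by hand from the
    1984 definitions; independent of the floating-point implementation."""
    r = len(pop_genotypes)
    n = [Fraction(len(g)) for g in pop_genotypes]
    p = [
        Fraction(sum(sum(1 for a in gt if a != 0) for gt in g), 2 * len(g))
        for g in pop_genotypes
    ]
    h = [Fraction(sum(1 for gt in g if gt[0] != gt[1]), len(g)) for g in pop_genotypes]
    n_bar = sum(n) / r
    n_c = (r * n_bar - sum(ni ** 2 for ni in n) / (r * n_bar)) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / (r * n_bar)
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, h)) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - Fraction(r - 1, r) * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - Fraction(r - 1, r) * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return a, b, c


class TestWeirCockerham:
    def _fst(self, pop_genotypes, **kw):
        gts = [g for pop in pop_genotypes for g in pop]
        pops = [f"p{i}" for i, pop in enumerate(pop_genotypes) for _ in pop]
        rec = var(genotypes=gts)
        return snp.weir_cockerham_fst(rec, pops, **kw)

    def test_complete_fixation_gives_theta_one(self):
        res = self._fst([[AA, AA, AA], [aa, aa, aa]])
        assert res.theta == pytest.approx(1.0)

    def test_monomorphic_site_undefined(self):
        res = self._fst([[AA, AA], [AA, AA]])
        assert res.theta is None
        assert res.a == res.b == res.c == 0.0

    def test_components_match_hand_derived_values(self):
        # pop1 = {AA, AA, Aa}, pop2 = {aa, Aa, aa}: by hand,
        # a = 7/36, b = 0, c = 1/6, theta = 7/13
        res = self._fst([[AA, AA, Aa], [aa, Aa, aa]])
        assert res.a == pytest.approx(7 / 36, abs=1e-12)
        assert res.b == pytest.approx(0.0, abs=1e-12)
        assert res.c == pytest.approx(1 / 6, abs=1e-12)
        assert res.theta == pytest.approx(7 / 13, abs=1e-12)

    @given(st.integers(0, 2000))
    @settings(max_examples=60, deadline=None)
    def test_matches_exact_fraction_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pops = []
        for _ in range(int(rng.integers(2, 5))):
            size = int(rng.integers(2, 8))
            pops.append(
                [tuple(sorted(rng.integers(0, 2, 2))) for _ in range(size)]
            )
        res = self._fst(pops)
        a, b, c = wc_oracle_components(pops)
        assert res.a == pytest.approx(float(a), abs=1e-12)
        assert res.b == pytest.approx(float(b), abs=1e-12)
        assert res.c == pytest.approx(float(c), abs=1e-12)
        if a + b + c == 0:
            assert res.theta is None
        else:
            assert res.theta == pytest.approx(float(a / (a + b + c)), abs=1e-10)

    def test_single_population_rejected(self):
        rec = var(genotypes=[Aa, Aa])
        with pytest.raises(ValueError):
            snp.weir_cockerham_fst(rec, ["p1", "p1"])

    def test_small_population_excluded_with_warning(self, caplog):
        gts = [AA, AA, AA, aa, aa, aa, Aa]
        pops = ["p1"] * 3 + ["p2"] * 3 + ["p3"]
        with caplog.at_level("WARNING"):
            res = snp.weir_cockerham_fst(var(genotypes=gts), pops, min_pop_size=2)
        assert "p3" in caplog.text
        # p3 dropped: remaining configuration is the complete fixation case
        assert res.theta == pytest.approx(1.0)

    def test_exchangeable_within_populations(self):
        rng = np.random.default_rng(11)
        gts = [tuple(sorted(rng.integers(0, 2, 2))) for _ in range(12)]
        pops = ["p1"] * 6 + ["p2"] * 6
        base = snp.weir_cockerham_fst(var(genotypes=gts), pops)
        perm = list(range(12))
        rng.shuffle(perm[:6])
        rng.shuffle(perm[6:])
        shuffled = snp.weir_cockerham_fst(
            var(genotypes=[gts[i] for i in perm]), pops
        )
        assert shuffled == base

    def test_equal_frequencies_concentrate_near_zero(self):
        # two large samples at the same allele frequency: theta near 0,
        # possibly slightly negative, never clamped
        rng = np.random.default_rng(21)
        thetas = []
        for _ in range(100):
            gts = [tuple(sorted(rng.binomial(1, 0.5, 2))) for _ in range(100)]
            pops = ["p1"] * 50 + ["p2"] * 50
            res = snp.weir_cockerham_fst(var(genotypes=gts), pops)
            if res.theta is not None:
                thetas.append(res.theta)
        assert abs(np.mean(thetas)) < 0.02
        assert min(thetas) < 0  # negative estimates are reported as computed

    def test_negative_theta_retained(self):
        res = self._fst([[AA, aa], [AA, aa]])
        assert res.theta is not None and res.theta < 0

    def test_mean_theta_increases_with_planted_differential(self, tmp_path):
        means = []
        for i, delta in enumerate([0.1, 0.3, 0.5]):
            sites = tuple(
                sd.SiteTruth(f"s{k}", {"spA": 0.25, "spB": 0.25 + delta}, sd.SHARED)
                for k in range(120)
            )
            truth = sd.GenotypeTruth(sites=sites)
            sim = sd.simulate_genotype_vcf(truth, {"spA": 10, "spB": 10}, seed=40 + i)
            path = tmp_path / f"d{i}.vcf"
            path.write_text(sim.vcf_text)
            records, samples = snp.read_vcf(path)
            pops = [sim.sample_species[s] for s in samples]
            results = snp.fst_scan(records, pops)
            means.append(snp.fst_distribution(results).mean_theta)
        assert means[0] < means[1] < means[2]


class TestFstDistribution:
    def _results(self, thetas):
        return [
            snp.FstResult("c", i + 1, a=t if t is not None else 0.0, b=0.0,
                          c=0.0 if t is None else (0.0 if t == 0 else 0.0),
                          theta=t)
            for i, t in enumerate(thetas)
        ]

    def test_summary_counts(self):
        summary = snp.fst_distribution(self._results([0.0, 0.5, 1.0]))
        assert summary.mean_theta == pytest.approx(0.5)
        assert summary.n_ge_half == 2
        assert summary.n_fixed == 1

    def test_undefined_excluded_but_counted(self):
        summary = snp.fst_distribution(self._results([0.2, None, None]))
        assert summary.n_defined == 1
        assert summary.n_undefined == 2
        assert summary.mean_theta == pytest.approx(0.2)

    def test_all_undefined_rejected(self):
        with pytest.raises(ValueError):
            snp.fst_distribution(self._results([None, None]))

    def test_histogram_covers_negative_estimates(self):
        summary = snp.fst_distribution(self._results([-0.02, 0.01, 0.99, 1.0]))
        assert sum(summary.bin_counts) == 4


class TestCandidateDiagnosticSnps:
    def test_threshold_one_selects_only_fixed(self):
        results = self._two_results()
        hits = snp.candidate_diagnostic_snps(results, threshold=1.0)
        assert [h.pos for h in hits] == [2]

    def test_threshold_zero_returns_all_sorted(self):
        hits = snp.candidate_diagnostic_snps(self._two_results(), threshold=0.0)
        assert [h.theta for h in hits] == [1.0, 0.9]

    @staticmethod
    def _two_results():
        return [
            snp.FstResult("c", 1, 0.9, 0.05, 0.05, 0.9),
            snp.FstResult("c", 2, 1.0, 0.0, 0.0, 1.0),
        ]

    def test_recovers_planted_fixed_sites(self, tmp_path):
        truth = sd.make_genotype_truth(
            100, ["spA", "spB", "spC"], fixed_fraction=0.2,
            qual_params={"low_rate": 0.0, "high_range": (600.0, 3000.0)},
            missing_rate=0.0, seed=8,
        )
        sim = sd.simulate_genotype_vcf(truth, {"spA": 4, "spB": 4, "spC": 4}, seed=8)
        path = tmp_path / "panel.vcf"
        path.write_text(sim.vcf_text)
        records, samples = snp.read_vcf(path)
        pops = [sim.sample_species[s] for s in samples]
        results = snp.fst_scan(snp.stringent_filter(records), pops)
        hits = {r.chrom for r in snp.candidate_diagnostic_snps(results, 1.0)}
        planted = {s.site_id for s in truth.sites if s.fst_class == sd.FIXED}
        assert hits == planted


def test_vcf_round_trip(tmp_path):
    truth = sd.make_genotype_truth(10, ["spA", "spB"], missing_rate=0.1, seed=4)
    sim = sd.simulate_genotype_vcf(truth, {"spA": 3, "spB": 2}, seed=4)
    path = tmp_path / "rt.vcf"
    path.write_text(sim.vcf_text)
    records, samples = snp.read_vcf(path)
    assert list(samples) == list(sim.samples)
    assert len(records) == 10
    assert all(r.ref == "A" and r.alts == ("G",) for r in records)
    # genotype strings in the text match what the reader returns
    body = [l for l in sim.vcf_text.splitlines() if not l.startswith("#")]
    for line, rec in zip(body, records):
        fields = line.split("\t")[9:]
        for f, gt in zip(fields, rec.genotypes):
            if f == "./.":
                assert gt is None
            else:
                assert f == f"{gt[0]}/{gt[1]}"
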