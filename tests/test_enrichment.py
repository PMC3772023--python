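"""Gene, domain and pathway enrichment statistics."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumoronly import (
    CohortCallMatrix,
    build_cohort_matrix,
    compute_mutation_rate,
    domain_enrichment,
    gene_enrichment,
    hypergeom_upper_tail,
    pathway_enrichment,
    per_patient_gene_probability,
    poisson_upper_tail,
    results_to_frame,
)
from tumoronly.enrichment import add_bh_column
from tumoronly.variants import AnnotationBundle, CallSet, Domain, GeneModel

from conftest import vk


def matrix_from_records(patients, m, rows):
    return CohortCallMatrix(
        patients=list(patients),
        m=np.asarray(m),
        records=pd.DataFrame(rows, columns=["patient", "gene", "cds_pos"]),
    )


class TestGeneProbability:
    def test_boundary_values(self):
        assert per_patient_gene_probability(0, 100, 1000) == 0.0
        N = 1000
        assert per_patient_gene_probability(1, N, N) == pytest.approx(
            -math.expm1(N * math.log1p(-1 / N))
        )
        assert per_patient_gene_probability(N, 10, N) == 1.0

    def test_paper_scale_value(self):
        # m = 30,800 over N = 30.8 Mb in a 1 kb gene: P = 1 - 0.999^1000
        p = per_patient_gene_probability(30_800, 1_000, 30_800_000)
        assert p == pytest.approx(1 - 0.999**1000, rel=1e-12)
        assert p == pytest.approx(0.6323, abs=5e-5)

    @pytest.mark.parametrize("m,n,N", [(-1, 10, 100), (101, 10, 100), (5, 0, 100), (5, 101, 100)])
    def test_argument_errors(self, m, n, N):
        with pytest.raises(ValueError):
            per_patient_gene_probability(m, n, N)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        m=st.integers(1, 500),
        n=st.integers(1, 900),
        N=st.just(1000),
    )
    def test_monotone_and_union_bounded(self, m, n, N):
        p = per_patient_gene_probability(m, n, N)
        assert 0.0 <= p <= 1.0
        assert p <= m * n / N + 1e-12
        # strictly increasing in m and n (up to float saturation near 1)
        strict = p < 1 - 1e-9
        prev_m = per_patient_gene_probability(m - 1, n, N)
        assert p > prev_m if strict else p >= prev_m
        if n > 1:
            prev_n = per_patient_gene_probability(m, n - 1, N)
            assert p > prev_n if strict else p >= prev_n


class TestTailFunctions:
    def test_poisson_examples(self):
        assert poisson_upper_tail(0, 5.0) == 1.0
        assert poisson_upper_tail(1, 0.0) == 0.0
        assert poisson_upper_tail(3, 1.0) == pytest.approx(1 - 2.5 / math.e, abs=1e-9)

    def test_poisson_against_term_summation(self):
        for mean in (0.1, 1.0, 3.7, 12.0, 40.0):
            for obs in (1, 2, 5, 11, 30):
                term = math.exp(-mean + obs * math.log(mean) - math.lgamma(obs + 1))
                brute, i = 0.0, obs
                while term > 0 and i < obs + 400:
                    brute += term
                    i += 1
                    term *= mean / i
                assert poisson_upper_tail(obs, mean) == pytest.approx(brute, abs=1e-12)

    def test_hypergeom_examples(self):
        assert hypergeom_upper_tail(2, 5, 5, 2) == 1.0
        assert hypergeom_upper_tail(0, 3, 10, 2) == 1.0
        assert hypergeom_upper_tail(2, 5, 10, 2) == pytest.approx(10 / 45, abs=1e-12)

    def test_hypergeom_against_exact_enumeration(self):
        for pop, succ, draws in [(10, 4, 3), (20, 7, 6), (37, 12, 9), (60, 25, 14)]:
            for obs in range(0, min(succ, draws) + 1):
                exact = sum(
                    Fraction(math.comb(succ, i) * math.comb(pop - succ, draws - i), math.comb(pop, draws))
                    for i in range(obs, min(succ, draws) + 1)
                )
                assert hypergeom_upper_tail(obs, succ, pop, draws) == pytest.approx(
                    float(exact), abs=1e-12
                )

    def test_tail_argument_errors(self):
        with pytest.raises(ValueError):
            poisson_upper_tail(-1, 1.0)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(1, 20, 10, 5)  # domain longer than gene
        with pytest.raises(ValueError):
            hypergeom_upper_tail(9, 5, 10, 2)  # observed above min(domain, draws)


class TestGeneEnrichment:
    def small_bundle(self):
        return AnnotationBundle(
            genes={
                "GA": GeneModel("GA", 100),
                "GB": GeneModel("GB", 400),
            },
            total_cds_length=1000,
        )

    def test_hand_computed_expected_and_p(self):
        ann = self.small_bundle()
        mat = matrix_from_records(
            ["P1", "P2"],
            [10, 20],
            [("P1", "GA", 5), ("P2", "GA", 7), ("P2", "GA", 30)],
        )
        res = {r.unit_id: r for r in gene_enrichment(mat, ann)}
        pa = 1 - (1 - 10 / 1000) ** 100
        pb = 1 - (1 - 20 / 1000) ** 100
        assert res["GA"].expected == pytest.approx(pa + pb, rel=1e-12)
        assert res["GA"].observed == 2  # two patients, pooled SNVs = 3
        assert res["GA"].n_snvs == 3
        assert res["GA"].p_value == pytest.approx(
            poisson_upper_tail(2, pa + pb), rel=1e-12
        )
        assert res["GB"].observed == 0
        assert res["GB"].p_value == 1.0

    def test_unknown_gene_rejected_at_matrix_build(self):
        ann = self.small_bundle()
        cs = CallSet(sample_id="P1", variants={vk(1)}, attrs={vk(1): {"gene": "NOPE"}})
        with pytest.raises(ValueError, match="unknown gene"):
            build_cohort_matrix([cs], ann)

    def test_missing_gene_assignment_rejected(self):
        ann = self.small_bundle()
        cs = CallSet(sample_id="P1", variants={vk(1)})
        with pytest.raises(ValueError, match="no gene assignment"):
            build_cohort_matrix([cs], ann)


class TestDomainEnrichment:
    def bundle(self):
        return AnnotationBundle(
            genes={
                "GA": GeneModel(
                    "GA",
                    1000,
                    [Domain("D1", 1, 100, cosmic=True), Domain("D2", 500, 700, cosmic=False)],
                ),
            }
        )

    def rows(self, n_in_domain, n_out):
        rows = [("P%d" % i, "GA", 10 + i) for i in range(n_in_domain)]
        rows += [("Q%d" % i, "GA", 900) for i in range(n_out)]
        return rows

    def test_count_filters(self):
        ann = self.bundle()
        # 4 pooled gene SNVs: below the >=5 filter, never tested
        mat = matrix_from_records(["P0", "P1", "P2", "Q0"], [1, 1, 1, 1], self.rows(3, 1))
        assert domain_enrichment(mat, ann) == []
        # gene has 6 SNVs but only 2 in the domain: below the >=3 filter
        mat = matrix_from_records(
            ["P0", "P1", "Q0", "Q1", "Q2", "Q3"], [1] * 6, self.rows(2, 4)
        )
        assert domain_enrichment(mat, ann) == []

    def test_cosmic_restriction(self):
        ann = self.bundle()
        rows = [("P%d" % i, "GA", 550 + i) for i in range(6)]  # all inside non-COSMIC D2
        mat = matrix_from_records([r[0] for r in rows], [1] * 6, rows)
        assert domain_enrichment(mat, ann) == []
        res = domain_enrichment(mat, ann, cosmic_only=False)
        assert [r.unit_id for r in res] == ["GA:D2"]
        assert res[0].p_value == pytest.approx(
            hypergeom_upper_tail(6, 201, 1000, 6), rel=1e-12
        )

    def test_expected_count_is_length_scaled(self):
        ann = self.bundle()
        mat = matrix_from_records([f"P{i}" for i in range(8)], [1] * 8, self.rows(5, 3))
        [res] = domain_enrichment(mat, ann)
        assert res.unit_id == "GA:D1"
        assert res.expected == pytest.approx(8 * 100 / 1000)
        assert res.n_gene_snvs == 8


class TestPathwayEnrichment:
    def test_mutation_rate_paper_arithmetic(self):
        rows = [(f"P{i}", f"G{j:05d}", 1) for i in range(5) for j in range(172)]
        mat = matrix_from_records([f"P{i}" for i in range(5)], [172] * 5, rows)
        assert compute_mutation_rate(mat, 17_175) == pytest.approx(172 / 17_175)
        with pytest.raises(ValueError):
            compute_mutation_rate(matrix_from_records([], [], []), 100)

    def test_lambda_formula_and_bounds(self):
        genes = {f"G{j:03d}": GeneModel(f"G{j:03d}", 100) for j in range(200)}
        members = frozenset(list(genes)[:50])
        ann = AnnotationBundle(
            genes=genes, pathways={"PW": members}, total_genes=200, cohort_size=97
        )
        # 97 patients, each mutating 2 distinct genes -> M = 2/200 = 0.01
        rows = []
        patients = [f"P{i}" for i in range(97)]
        for i, p in enumerate(patients):
            rows.append((p, f"G{i % 200:03d}", 1))
            rows.append((p, f"G{(i + 100) % 200:03d}", 1))
        mat = matrix_from_records(patients, [2] * 97, rows)
        [res] = pathway_enrichment(mat, ann)
        lam = (1 - (1 - 0.01) ** 50) * 97
        assert lam == pytest.approx(38.31, abs=0.01)
        assert res.expected == pytest.approx(lam, rel=1e-9)
        assert res.expected <= 97
        assert res.p_value == pytest.approx(
            poisson_upper_tail(res.observed, lam), rel=1e-12
        )

    def test_lambda_saturates_at_cohort_size(self):
        genes = {f"G{j}": GeneModel(f"G{j}", 100) for j in range(40)}
        ann = AnnotationBundle(
            genes=genes, pathways={"ALL": frozenset(genes)}, total_genes=40
        )
        rows = [(f"P{i}", f"G{j}", 1) for i in range(10) for j in range(30)]
        mat = matrix_from_records([f"P{i}" for i in range(10)], [30] * 10, rows)
        [res] = pathway_enrichment(mat, ann)
        assert res.expected <= 10.0
        assert res.expected == pytest.approx(10 * (1 - 0.25**40), rel=1e-6)

    def test_unknown_pathway_genes_skipped_with_warning(self):
        genes = {"GA": GeneModel("GA", 100)}
        ann = AnnotationBundle(genes=genes, pathways={"PW": frozenset({"NOPE"})})
        mat = matrix_from_records(["P1"], [1], [("P1", "GA", 1)])
        with pytest.warns(UserWarning, match="skipped"):
            assert pathway_enrichment(mat, ann) == []


class TestResultFrames:
    def test_frame_and_bh_column(self, small_cohort, small_genome):
        mat = build_cohort_matrix(small_cohort.tumor, small_genome.annotations)
        res = gene_enrichment(mat, small_genome.annotations)
        frame = add_bh_column(results_to_frame(res))
        assert {"unit_id", "kind", "p_value", "q_value"} <= set(frame.columns)
        assert (frame["q_value"] >= frame["p_value"] - 1e-15).all()
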