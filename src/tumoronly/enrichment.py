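"""Mutation-enrichment statistics at gene, protein-domain and pathway level.

Three one-sided (enrichment) screens over a cohort of per-patient
coding SNV call sets:

Gene level
    A patient with m coding SNVs over a coding space of N bases hits a
    gene of CDS length n with probability P = 1 - (1 - m/N)^n.  The
    expected number of mutated cancers in the gene is the sum of P over
    patients; the observed number of patients with at least one SNV in
    the gene is tested against it with a Poisson upper tail.

Domain level
    Within a gene carrying at least ``min_gene_snvs`` pooled SNVs, the
    number falling in a domain of length d (of the gene's n bases) is
    tested with a hypergeometric upper tail (population n, successes d,
    draws = pooled gene SNVs); only domains with at least
    ``min_domain_snvs`` SNVs are tested, and by default only domains
    known to harbor catalogued somatic cancer mutations (COSMIC flag).

Pathway level
    With per-patient mutation rate M (mean distinct mutated genes over
    the total gene count), a pathway of n genes is hit by a patient with
    probability 1 - (1 - M)^n; the expected number of cancers with SNVs
    in the pathway is lambda = (1 - (1 - M)^n) x cohort size, and the
    observed count is tested with a Poisson upper tail.

All p-values are upper tails P(X >= observed); no multiple-testing
correction is applied by default (results are conventionally filtered
at P < 0.02 for genes/domains and P < 0.05 for pathways), but a
Benjamini-Hochberg column can be added with :func:`add_bh_column`.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variants import AnnotationBundle, CallSet

__all__ = [
    "EnrichmentResult",
    "CohortCallMatrix",
    "build_cohort_matrix",
    "per_patient_gene_probability",
    "poisson_upper_tail",
    "hypergeom_upper_tail",
    "gene_enrichment",
    "domain_enrichment",
    "pathway_enrichment",
    "compute_mutation_rate",
    "results_to_frame",
    "add_bh_column",
]


@dataclasses.dataclass(frozen=True)
class EnrichmentResult:
    unit_id: str
    kind: str  # "gene" | "domain" | "pathway"
    observed: int
    expected: float
    p_value: float
    n_snvs: int | None = None       # pooled SNVs in the unit
    n_gene_snvs: int | None = None  # pooled SNVs in the host gene (domain rows)

    def __post_init__(self):
        if self.observed < 0 or self.expected < 0:
            raise ValueError("counts and expectations must be non-negative")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.unit_id, r.kind, r.observed, r.expected, r.p_value, r.n_snvs, r.n_gene_snvs)
            for r in results
        ],
        columns=["unit_id", "kind", "observed", "expected", "p_value", "n_snvs", "n_gene_snvs"],
    )


def add_bh_column(frame: pd.DataFrame) -> pd.DataFrame:
    """Append a Benjamini-Hochberg adjusted p-value column (q_value)."""
    out = frame.copy()
    out["q_value"] = stats.false_discovery_control(out["p_value"].to_numpy(), method="bh")
    return out


@dataclasses.dataclass
class CohortCallMatrix:
    """Per-patient coding SNV calls with gene assignment.

    ``m`` holds each patient's total coding SNV count; ``records`` has
    one row per call occurrence (columns: patient, gene, cds_pos).
    """

    patients: list[str]
    m: np.ndarray
    records: pd.DataFrame

    def __post_init__(self):
        if len(self.patients) != len(self.m):
            raise ValueError("m must align with patients")
        if len(set(self.patients)) != len(self.patients):
            raise ValueError("duplicate patient ids")

    def distinct_genes_per_patient(self) -> np.ndarray:
        counts = self.records.groupby("patient", observed=True)["gene"].nunique()
        return counts.reindex(self.patients, fill_value=0).to_numpy()

    def gene_summary(self) -> pd.DataFrame:
        """Per gene: patients with >= 1 SNV and pooled SNV count."""
        g = self.records.groupby("gene", observed=True)
        return pd.DataFrame(
            {"observed_patients": g["patient"].nunique(), "pooled_snvs": g.size()}
        )


def build_cohort_matrix(
    callsets: Sequence[CallSet], annotations: AnnotationBundle
) -> CohortCallMatrix:
    """Assemble the cohort call matrix from per-patient call sets.

    Every call must carry a gene assignment known to the annotation
    bundle (from simulation or from the ``GENE`` INFO field on input).
    """
    patients = [cs.sample_id for cs in callsets]
    m = np.array([len(cs) for cs in callsets], dtype=np.int64)
    rows = []
    for cs in callsets:
        for v in cs.variants:
            a = cs.attrs.get(v, {})
            gene = a.get("gene")
            if gene is None:
                raise ValueError(
                    f"call {v} of {cs.sample_id} has no gene assignment"
                )
            if gene not in annotations.genes:
                raise ValueError(f"unknown gene {gene!r} on call {v}")
            rows.append((cs.sample_id, gene, a.get("cds_pos", -1)))
    records = pd.DataFrame(rows, columns=["patient", "gene", "cds_pos"])
    return CohortCallMatrix(patients=patients, m=m, records=records)


# ---------------------------------------------------------------------------
# elementary probabilities


def per_patient_gene_probability(m: int, n: int, N: int) -> float:
    """P = 1 - (1 - m/N)^n: chance a patient with m SNVs hits a gene of length n.

    Evaluated in log space; strictly increasing in both m and n, and
    bounded by the union bound m*n/N.
    """
    if not (0 <= m <= N):
        raise ValueError(f"m must lie in [0, N], got m={m}, N={N}")
    if not (1 <= n <= N):
        raise ValueError(f"n must lie in [1, N], got n={n}, N={N}")
    if m == N:
        return 1.0
    return float(-math.expm1(n * math.log1p(-m / N)))


def poisson_upper_tail(observed: int, mean: float) -> float:
    """P(X >= observed) for X ~ Poisson(mean); upper-tail enrichment p-value."""
    if observed < 0 or mean < 0:
        raise ValueError("observed and mean must be non-negative")
    if observed == 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, mean))


def hypergeom_upper_tail(observed: int, domain_len: int, gene_len: int, draws: int) -> float:
    """P(X >= observed) for a hypergeometric draw of gene SNVs into a domain.

    Population = gene CDS bases, successes = domain bases, draws = the
    gene's pooled SNV count.
    """
    if domain_len > gene_len:
        raise ValueError("domain longer than its gene")
    if draws > gene_len:
        raise ValueError("more draws than gene bases")
    if not (0 <= observed <= min(domain_len, draws)):
        raise ValueError(
            f"observed {observed} outside [0, min(domain_len, draws)]"
        )
    if observed == 0:
        return 1.0
    return float(stats.hypergeom.sf(observed - 1, gene_len, domain_len, draws))


# ---------------------------------------------------------------------------
# the three screens


def gene_enrichment(
    cohort: CohortCallMatrix, annotations: AnnotationBundle
) -> list[EnrichmentResult]:
    """Gene-level Poisson screen of observed vs expected mutated cancers.

    For every annotated gene, expected = sum over patients of
    P(m_i, n_t, N) and observed = patients with at least one SNV in the
    gene; p is the Poisson upper tail of observed at mean expected.
    """
    N = annotations.n_total
    if np.any(cohort.m > N):
        raise ValueError("a patient has more SNVs than the coding space")
    gene_ids = sorted(annotations.genes)
    lens = np.array([annotations.genes[g].cds_length for g in gene_ids], dtype=float)
    log_miss = np.log1p(-cohort.m.astype(float) / N)  # per patient
    # expected[t] = sum_i 1 - exp(n_t * log_miss_i)
    expected = (-np.expm1(lens[:, None] * log_miss[None, :])).sum(axis=1)
    summary = cohort.gene_summary()
    observed = summary["observed_patients"].reindex(gene_ids).fillna(0).to_numpy(dtype=int)
    pooled = summary["pooled_snvs"].reindex(gene_ids).fillna(0).to_numpy(dtype=int)
    p = np.where(observed > 0, stats.poisson.sf(observed - 1, expected), 1.0)
    return [
        EnrichmentResult(
            unit_id=g,
            kind="gene",
            observed=int(observed[i]),
            expected=float(expected[i]),
            p_value=float(p[i]),
            n_snvs=int(pooled[i]),
        )
        for i, g in enumerate(gene_ids)
    ]


def domain_enrichment(
    cohort: CohortCallMatrix,
    annotations: AnnotationBundle,
    min_gene_snvs: int = 5,
    min_domain_snvs: int = 3,
    cosmic_only: bool = True,
) -> list[EnrichmentResult]:
    """Hypergeometric screen for SNV concentration in protein domains.

    Tests only (gene, domain) pairs where the gene pools at least
    ``min_gene_snvs`` SNVs across patients, the domain at least
    ``min_domain_snvs``, and (by default) the domain is COSMIC-flagged.
    """
    results: list[EnrichmentResult] = []
    recs = cohort.records
    if recs.empty:
        return results
    for gene, grp in recs.groupby("gene", observed=True):
        draws = len(grp)
        if draws < min_gene_snvs:
            continue
        model = annotations.genes[gene]
        if draws > model.cds_length:
            raise ValueError(f"gene {gene} has more pooled SNVs than CDS bases")
        cpos = grp["cds_pos"].to_numpy()
        if np.any(cpos < 1):
            raise ValueError(f"gene {gene} has calls without CDS positions")
        for d in model.domains:
            if cosmic_only and not d.cosmic:
                continue
            obs = int(((cpos >= d.start) & (cpos <= d.end)).sum())
            if obs < min_domain_snvs:
                continue
            expected = draws * d.length / model.cds_length
            p = hypergeom_upper_tail(obs, d.length, model.cds_length, draws)
            results.append(
                EnrichmentResult(
                    unit_id=f"{gene}:{d.domain_id}",
                    kind="domain",
                    observed=obs,
                    expected=float(expected),
                    p_value=p,
                    n_snvs=obs,
                    n_gene_snvs=draws,
                )
            )
    return results


def compute_mutation_rate(cohort: CohortCallMatrix, total_genes: int) -> float:
    """M: mean distinct mutated genes per patient over the total gene count."""
    if total_genes < 1:
        raise ValueError("total_genes must be >= 1")
    if len(cohort.patients) == 0:
        raise ValueError("empty cohort")
    mean_genes = float(cohort.distinct_genes_per_patient().mean())
    M = mean_genes / total_genes
    if M > 1.0:
        raise ValueError("mutation rate above 1: total_genes too small for the cohort")
    return M


def pathway_enrichment(
    cohort: CohortCallMatrix,
    annotations: AnnotationBundle,
    cohort_size: int | None = None,
) -> list[EnrichmentResult]:
    """Pathway-level Poisson screen via lambda(t, n) = (1 - (1 - M)^n) x cohort size.

    ``n`` counts pathway member genes present in the annotation
    universe; pathways with no known genes are skipped with a warning.
    Observed = patients with at least one SNV in any member gene.
    """
    if cohort_size is None:
        cohort_size = annotations.cohort_size or len(cohort.patients)
    M = compute_mutation_rate(cohort, annotations.total_genes)
    by_patient_genes = (
        cohort.records.groupby("patient", observed=True)["gene"].agg(set).to_dict()
    )
    results: list[EnrichmentResult] = []
    for pid in sorted(annotations.pathways):
        members = {g for g in annotations.pathways[pid] if g in annotations.genes}
        if not members:
            warnings.warn(f"pathway {pid} has no genes in the annotation universe; skipped")
            continue
        n = len(members)
        lam = -math.expm1(n * math.log1p(-M)) * cohort_size if M > 0 else 0.0
        observed = sum(1 for genes in by_patient_genes.values() if genes & members)
        p = poisson_upper_tail(observed, lam)
        results.append(
            EnrichmentResult(
                unit_id=pid,
                kind="pathway",
                observed=int(observed),
                expected=float(lam),
                p_value=p,
                n_snvs=None,
            )
        )
    return results
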