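"""Synthetic cohort generator.

Emulates the data structure of a tumor-only exome study: a population
germline pool with a rare-heavy allele-frequency spectrum, external
germline exome panels, per-patient tumor candidate call lists
contaminated with miscalled germline variants, matched-normal call
sets, and survival times with gene-linked hazards.

Model assumptions
-----------------
* Diploid Hardy-Weinberg carriage: an individual carries a site of
  allele frequency f with probability q = 1 - (1 - f)^2; presence /
  absence is all the downstream set algebra ever sees.
* Somatic SNVs are private per patient except a small recurrent
  fraction drawn from a shared hotspot pool; positions fall uniformly
  over the concatenated coding space unless per-gene or per-domain rate
  multipliers are supplied (used to implant driver genes).
* Artifact calls (germline miscalled as somatic) are sampled from the
  patient's own germline carriers, mirroring germline leakage through
  an under-covered matched normal.

The default frequency classes were calibrated so that an external panel
of k exomes detects ~54% of a patient's germline variants at k = 96 and
~64% at k = 217, saturating at 90%/95% around k ~ 1350/2000.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
import pandas as pd

from .variants import (
    DEFAULT_CODING_SPACE,
    AnnotationBundle,
    BASES,
    CallSet,
    Domain,
    GeneModel,
    PanelCollection,
    VariantKey,
)

__all__ = [
    "DEFAULT_FREQUENCY_CLASSES",
    "PopulationModel",
    "CohortConfig",
    "SurvivalConfig",
    "GermlinePool",
    "SyntheticGenome",
    "SimulatedCohort",
    "synthetic_annotations",
    "build_germline_pool",
    "simulate_panel",
    "simulate_cohort",
    "simulate_survival",
]

#: (allele frequency, site weight) classes of the germline pool.
DEFAULT_FREQUENCY_CLASSES: tuple[tuple[float, float], ...] = (
    (0.25, 0.001268),
    (0.01, 0.032341),
    (0.001, 0.272700),
    (0.0004, 0.693691),
)


@dataclasses.dataclass(frozen=True)
class PopulationModel:
    """Allele-frequency spectrum and size of the germline site pool."""

    frequency_classes: tuple[tuple[float, float], ...] = DEFAULT_FREQUENCY_CLASSES
    n_germline_sites: int = 100_000
    coding_space: int = DEFAULT_CODING_SPACE

    def __post_init__(self):
        if self.n_germline_sites < 1:
            raise ValueError("n_germline_sites must be >= 1")
        if self.coding_space < 1:
            raise ValueError("coding_space must be positive")
        if not self.frequency_classes:
            raise ValueError("at least one frequency class is required")
        total = 0.0
        for f, w in self.frequency_classes:
            if not (0.0 < f <= 1.0):
                raise ValueError(f"allele frequency {f} outside (0, 1]")
            if w < 0:
                raise ValueError("class weights must be non-negative")
            total += w
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class weights must sum to 1 (got {total})")

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([f for f, _ in self.frequency_classes])

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.frequency_classes])

    @property
    def carrier_probs(self) -> np.ndarray:
        f = self.frequencies
        return 1.0 - (1.0 - f) ** 2


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 97
    somatic_per_patient: float = 150.0
    recurrent_fraction: float = 0.03
    artifact_fraction: float = 0.25
    normal_miss_rate: float = 0.02
    recurrent_pool_size: int = 30

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for name in ("recurrent_fraction", "artifact_fraction", "normal_miss_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.artifact_fraction >= 1.0:
            raise ValueError("artifact_fraction must be < 1")
        if self.recurrent_pool_size < 1:
            raise ValueError("recurrent_pool_size must be >= 1")


@dataclasses.dataclass(frozen=True)
class SurvivalConfig:
    baseline_hazard: float = 0.015
    hazard_ratio_by_gene: Mapping[str, float] = dataclasses.field(default_factory=dict)
    censoring_time: float = 60.0

    def __post_init__(self):
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censoring_time < 0:
            raise ValueError("censoring_time must be >= 0")
        for g, hr in self.hazard_ratio_by_gene.items():
            if hr <= 0:
                raise ValueError(f"hazard ratio for {g} must be > 0")


# ---------------------------------------------------------------------------
# synthetic genome / annotations

_N_CHROMS = 22


@dataclasses.dataclass
class SyntheticGenome:
    """Gene models laid out over a concatenated coding space.

    Gene g occupies global offsets [gene_starts[g], gene_starts[g] +
    cds_length) in a 0-based concatenated coordinate; the same block
    maps to consecutive 1-based positions on its chromosome.
    """

    annotations: AnnotationBundle
    gene_ids: list[str]
    gene_lengths: np.ndarray
    gene_starts: np.ndarray
    gene_chroms: list[str]
    gene_chrom_starts: np.ndarray
    driver_genes: list[str] = dataclasses.field(default_factory=list)
    gene_rate_multipliers: dict[str, float] = dataclasses.field(default_factory=dict)
    domain_rate_multipliers: dict[tuple[str, str], float] = dataclasses.field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return int(self.gene_lengths.sum())

    def locate(self, offsets: np.ndarray):
        """Map global offsets to (gene index, chrom, 1-based pos, 1-based cds_pos)."""
        offsets = np.asarray(offsets)
        gi = np.searchsorted(self.gene_starts, offsets, side="right") - 1
        within = offsets - self.gene_starts[gi]
        if np.any(within >= self.gene_lengths[gi]) or np.any(within < 0):
            raise ValueError("offset outside the coding space")
        cds_pos = within + 1
        pos = self.gene_chrom_starts[gi] + within + 1
        chroms = [self.gene_chroms[i] for i in gi]
        return gi, chroms, pos, cds_pos


_DRIVER_GENE_MULTIPLIERS = (50.0, 25.0, 20.0, 15.0, 12.0, 10.0, 8.0, 8.0, 6.0, 6.0, 5.0)
_DRIVER_DOMAIN_MULTIPLIER = 5.0


def synthetic_annotations(
    n_genes: int = 17_175,
    mean_cds: float = 1793.0,
    sigma_log: float = 0.7,
    min_cds: int = 150,
    max_cds: int = 30_000,
    domain_rate: float = 1.2,
    cosmic_prob: float = 0.25,
    n_pathways: int = 180,
    pathway_size: tuple[int, int] = (20, 200),
    n_cancer_pathways: int = 20,
    cancer_pathway_size: tuple[int, int] = (20, 80),
    n_drivers: int = 11,
    seed: int = 0,
) -> SyntheticGenome:
    """Generate gene models, domains, pathways and a genome layout.

    CDS lengths are lognormal with the given mean (defaults match a
    ~30.8 Mb coding space over 17,175 genes); each gene carries a
    Poisson number of domains, a fraction of them COSMIC-flagged.
    ``n_drivers`` genes are designated drivers: they get a
    COSMIC-flagged domain and elevated per-base mutation rates
    (gene-level multipliers descending from 50x, with a further 5x
    concentration inside the driver domain), and are seeded into the
    first ``n_cancer_pathways`` pathways.
    """
    rng = np.random.default_rng(seed)
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    mu = math.log(mean_cds) - sigma_log**2 / 2.0
    lengths = np.clip(
        np.round(rng.lognormal(mu, sigma_log, n_genes)).astype(np.int64), min_cds, max_cds
    )
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]

    genes: dict[str, GeneModel] = {}
    n_domains = rng.poisson(domain_rate, n_genes)
    for i, gid in enumerate(gene_ids):
        L = int(lengths[i])
        doms = []
        for j in range(int(n_domains[i])):
            dlen = max(9, int(L * rng.uniform(0.10, 0.40)))
            dlen = min(dlen, L)
            start = int(rng.integers(1, L - dlen + 2))
            doms.append(
                Domain(
                    domain_id=f"D{i + 1:05d}.{j + 1}",
                    start=start,
                    end=start + dlen - 1,
                    cosmic=bool(rng.random() < cosmic_prob),
                )
            )
        genes[gid] = GeneModel(gene_id=gid, cds_length=L, domains=doms)

    # drivers: mid-length genes, forced COSMIC domain, elevated rates
    driver_genes: list[str] = []
    gene_mult: dict[str, float] = {}
    domain_mult: dict[tuple[str, str], float] = {}
    if n_drivers:
        eligible = np.flatnonzero((lengths >= 1000) & (lengths <= 8000))
        if len(eligible) < n_drivers:
            eligible = np.argsort(lengths)[: max(n_drivers, 1)]
        chosen = rng.choice(eligible, size=n_drivers, replace=False)
        for rank, gi in enumerate(sorted(chosen.tolist())):
            gid = gene_ids[gi]
            g = genes[gid]
            cosmic_doms = [d for d in g.domains if d.cosmic]
            if not cosmic_doms:
                L = g.cds_length
                dlen = max(30, int(L * 0.3))
                start = int(rng.integers(1, L - dlen + 2))
                d = Domain(f"D{gi + 1:05d}.C", start, start + dlen - 1, cosmic=True)
                g.domains.append(d)
                cosmic_doms = [d]
            driver_genes.append(gid)
            mult = _DRIVER_GENE_MULTIPLIERS[rank % len(_DRIVER_GENE_MULTIPLIERS)]
            gene_mult[gid] = mult
            domain_mult[(gid, cosmic_doms[0].domain_id)] = _DRIVER_DOMAIN_MULTIPLIER

    # pathways: cancer pathways seeded with drivers, the rest random
    pathways: dict[str, frozenset[str]] = {}
    all_ids = np.array(gene_ids)
    for p in range(n_pathways):
        cancer = p < n_cancer_pathways and driver_genes
        lo, hi = cancer_pathway_size if cancer else pathway_size
        size = min(int(rng.integers(lo, hi + 1)), n_genes)
        members = set(rng.choice(all_ids, size=size, replace=False).tolist())
        if cancer:
            k = int(rng.integers(1, min(4, len(driver_genes)) + 1))
            members |= set(rng.choice(driver_genes, size=k, replace=False).tolist())
        pathways[f"PW{p + 1:04d}"] = frozenset(members)

    bundle = AnnotationBundle(genes=genes, pathways=pathways)

    # layout: contiguous gene blocks over 22 chromosomes
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    chrom_of = np.minimum((np.arange(n_genes) * _N_CHROMS) // n_genes, _N_CHROMS - 1)
    chrom_names = [str(c + 1) for c in chrom_of]
    chrom_starts = np.zeros(n_genes, dtype=np.int64)
    offset = 0
    prev = -1
    for i in range(n_genes):
        if chrom_of[i] != prev:
            offset = 0
            prev = chrom_of[i]
        chrom_starts[i] = offset
        offset += lengths[i]

    return SyntheticGenome(
        annotations=bundle,
        gene_ids=gene_ids,
        gene_lengths=lengths,
        gene_starts=starts,
        gene_chroms=chrom_names,
        gene_chrom_starts=chrom_starts,
        driver_genes=driver_genes,
        gene_rate_multipliers=gene_mult,
        domain_rate_multipliers=domain_mult,
    )


def genome_from_bundle(bundle: AnnotationBundle) -> SyntheticGenome:
    """Lay out an explicit annotation bundle over the 22-chromosome coding space.

    Genes are placed in sorted id order as contiguous blocks; no driver
    profile is attached (rate multipliers default to uniform).
    """
    gene_ids = sorted(bundle.genes)
    lengths = np.array([bundle.genes[g].cds_length for g in gene_ids], dtype=np.int64)
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    n = len(gene_ids)
    chrom_of = np.minimum((np.arange(n) * _N_CHROMS) // max(n, 1), _N_CHROMS - 1)
    chrom_starts = np.zeros(n, dtype=np.int64)
    offset = 0
    prev = -1
    for i in range(n):
        if chrom_of[i] != prev:
            offset = 0
            prev = chrom_of[i]
        chrom_starts[i] = offset
        offset += lengths[i]
    return SyntheticGenome(
        annotations=bundle,
        gene_ids=gene_ids,
        gene_lengths=lengths,
        gene_starts=starts,
        gene_chroms=[str(c + 1) for c in chrom_of],
        gene_chrom_starts=chrom_starts,
    )


# ---------------------------------------------------------------------------
# germline pool and panels


@dataclasses.dataclass
class GermlinePool:
    """Realized population germline sites with per-site allele frequency."""

    keys: list[VariantKey]
    freqs: np.ndarray
    carrier_probs: np.ndarray
    offsets: np.ndarray
    gene_ids: list[str | None]
    cds_pos: np.ndarray
    genome: SyntheticGenome | None = None

    def __len__(self) -> int:
        return len(self.keys)

    def offset_set(self) -> set[int]:
        return set(self.offsets.tolist())


def _distinct_offsets(rng: np.random.Generator, n: int, space: int, taken: set[int] | None = None) -> np.ndarray:
    """n distinct global offsets in [0, space), avoiding ``taken``."""
    if n > space:
        raise ValueError("more sites requested than available bases")
    chosen: set[int] = set()
    taken = taken or set()
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = rng.integers(0, space, size=(n - filled) + 16)
        for v in draw.tolist():
            if v in chosen or v in taken:
                continue
            chosen.add(v)
            out[filled] = v
            filled += 1
            if filled == n:
                break
    return out


def _alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref = rng.integers(0, 4, n)
    alt = (ref + rng.integers(1, 4, n)) % 4
    return ref, alt


def build_germline_pool(
    pop_model: PopulationModel,
    genome: SyntheticGenome | None = None,
    seed: int = 0,
) -> GermlinePool:
    """Realize the germline site pool (positions, frequencies, alleles).

    With a :class:`SyntheticGenome`, sites fall uniformly over its coding
    space and are annotated with gene and CDS position; without one they
    are placed on a single contig of length ``pop_model.coding_space``.
    """
    rng = np.random.default_rng(seed)
    n = pop_model.n_germline_sites
    space = genome.total_length if genome is not None else pop_model.coding_space
    offsets = np.sort(_distinct_offsets(rng, n, space))
    cls = rng.choice(len(pop_model.frequency_classes), size=n, p=pop_model.weights)
    freqs = pop_model.frequencies[cls]
    q = pop_model.carrier_probs[cls]
    refs, alts = _alleles(rng, n)
    if genome is not None:
        gi, chroms, pos, cpos = genome.locate(offsets)
        gene_ids: list[str | None] = [genome.gene_ids[i] for i in gi]
        cds = np.asarray(cpos, dtype=np.int64)
    else:
        chroms = ["1"] * n
        pos = offsets + 1
        gene_ids = [None] * n
        cds = np.zeros(n, dtype=np.int64)
    keys = [
        VariantKey(chroms[i], int(pos[i]), BASES[refs[i]], BASES[alts[i]]) for i in range(n)
    ]
    return GermlinePool(
        keys=keys,
        freqs=freqs,
        carrier_probs=q,
        offsets=offsets,
        gene_ids=gene_ids,
        cds_pos=cds,
        genome=genome,
    )


def simulate_panel(
    pool: GermlinePool | PopulationModel,
    n_individuals: int,
    population_label: str = "PANEL",
    seed: int = 0,
) -> PanelCollection:
    """Draw external germline exomes from the population pool.

    Each individual carries each site independently with probability
    q = 1 - (1 - f)^2.  Pass a realized :class:`GermlinePool` to share
    the population with a simulated cohort; a bare
    :class:`PopulationModel` is realized on the fly (standalone use).
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if isinstance(pool, PopulationModel):
        pool = build_germline_pool(pool, None, seed=seed)
    rng = np.random.default_rng(seed)
    q = pool.carrier_probs
    members = []
    for i in range(n_individuals):
        idx = np.flatnonzero(rng.random(len(q)) < q)
        members.append(
            CallSet(
                sample_id=f"{population_label}_{i + 1:04d}",
                variants={pool.keys[j] for j in idx.tolist()},
            )
        )
    return PanelCollection(label=population_label, members=members)


# ---------------------------------------------------------------------------
# cohort simulation


@dataclasses.dataclass
class SimulatedCohort:
    """Paired tumor / matched-normal call sets with per-variant truth labels."""

    patient_ids: list[str]
    tumor: list[CallSet]
    normal: list[CallSet]
    germline: list[frozenset[VariantKey]]
    pool: GermlinePool
    genome: SyntheticGenome | None
    config: CohortConfig
    recurrent_sites: list[VariantKey] = dataclasses.field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patient_ids)

    def germline_truth(self) -> dict[str, frozenset[VariantKey]]:
        return dict(zip(self.patient_ids, self.germline))

    def cohort_frequencies(self) -> dict[VariantKey, float]:
        """Occurrence fraction of each germline variant across the cohort."""
        counts: dict[VariantKey, int] = {}
        for g in self.germline:
            for k in g:
                counts[k] = counts.get(k, 0) + 1
        n = len(self.patient_ids)
        return {k: c / n for k, c in counts.items()}

    def truth_label_counts(self) -> pd.DataFrame:
        rows = []
        for pid, cs in zip(self.patient_ids, self.tumor):
            lab = {"somatic": 0, "artifact": 0}
            for k in cs.variants:
                lab[cs.attrs[k]["label"]] += 1
            rows.append((pid, len(cs), lab["somatic"], lab["artifact"]))
        return pd.DataFrame(rows, columns=["patient_id", "n_calls", "n_somatic", "n_artifact"])


def _segment_weights(
    genome: SyntheticGenome,
    gene_mult: Mapping[str, float],
    domain_mult: Mapping[tuple[str, str], float],
):
    """Per-gene sampling weight and, for rate-modified genes, CDS segments.

    Returns (gene_weights array, segments dict gene_id -> (bounds, seg_w))
    where bounds are 0-based segment starts within the CDS.
    """
    weights = genome.gene_lengths.astype(float).copy()
    segments: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    touched = sorted(set(gene_mult) | {g for g, _ in domain_mult})
    for gid in touched:
        gi = genome.gene_ids.index(gid)
        L = int(genome.gene_lengths[gi])
        base = float(gene_mult.get(gid, 1.0))
        cuts = {0, L}
        dms = []
        for (g, did), m in domain_mult.items():
            if g != gid:
                continue
            dom = next(d for d in genome.annotations.genes[gid].domains if d.domain_id == did)
            cuts.add(dom.start - 1)
            cuts.add(dom.end)
            dms.append((dom.start - 1, dom.end, float(m)))
        bounds = np.array(sorted(cuts))
        seg_m = np.full(len(bounds) - 1, base)
        for s, e, m in dms:
            sel = (bounds[:-1] >= s) & (bounds[1:] <= e)
            seg_m[sel] *= m
        seg_len = np.diff(bounds)
        seg_w = seg_len * seg_m
        segments[gid] = (bounds, seg_w)
        weights[gi] = seg_w.sum()
    return weights, segments


def _sample_positions_in_genes(
    rng: np.random.Generator,
    genome: SyntheticGenome,
    gene_idx: np.ndarray,
    segments: Mapping[str, tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """0-based within-CDS positions for sampled genes (piecewise for drivers)."""
    n = len(gene_idx)
    out = np.empty(n, dtype=np.int64)
    lens = genome.gene_lengths[gene_idx]
    uniform = rng.integers(0, lens)
    out[:] = uniform
    if segments:
        for gid, (bounds, seg_w) in sorted(segments.items()):
            gi = genome.gene_ids.index(gid)
            sel = np.flatnonzero(gene_idx == gi)
            if len(sel) == 0:
                continue
            p = seg_w / seg_w.sum()
            seg = rng.choice(len(seg_w), size=len(sel), p=p)
            lo = bounds[:-1][seg]
            hi = bounds[1:][seg]
            out[sel] = rng.integers(lo, hi)
    return out


def simulate_cohort(
    config: CohortConfig,
    pool: GermlinePool | PopulationModel,
    genome: SyntheticGenome,
    seed: int = 0,
    gene_rate_multipliers: Mapping[str, float] | None = None,
    domain_rate_multipliers: Mapping[tuple[str, str], float] | None = None,
) -> SimulatedCohort:
    """Simulate paired tumor / matched-normal call sets for a cohort.

    Per patient, the tumor candidate list is the union of true somatic
    calls (Poisson count around ``somatic_per_patient``, a
    ``recurrent_fraction`` of them drawn from a shared hotspot pool) and
    artifact calls sampled from the patient's germline carriers so that
    the expected artifact share of candidates is ``artifact_fraction``.
    The matched-normal call set is the patient's germline minus misses
    at ``normal_miss_rate``.

    Rate multipliers default to the genome's driver profile; pass empty
    mappings for a fully uniform (null) cohort.
    """
    if config.somatic_per_patient <= 0:
        raise ValueError("somatic_per_patient must be > 0")
    if isinstance(pool, PopulationModel):
        pool = build_germline_pool(pool, genome, seed=seed)
    if pool.genome is not genome:
        raise ValueError("pool was realized over a different genome")
    gene_mult = genome.gene_rate_multipliers if gene_rate_multipliers is None else dict(gene_rate_multipliers)
    dom_mult = genome.domain_rate_multipliers if domain_rate_multipliers is None else dict(domain_rate_multipliers)

    rng = np.random.default_rng(seed)
    n_pat = config.n_patients
    n_sites = len(pool)
    q = pool.carrier_probs
    patient_ids = [f"P{i + 1:03d}" for i in range(n_pat)]

    # germline carriage and matched-normal call sets
    germ_idx: list[np.ndarray] = []
    normal_idx: list[np.ndarray] = []
    for _ in range(n_pat):
        g = np.flatnonzero(rng.random(n_sites) < q)
        keep = g[rng.random(len(g)) >= config.normal_miss_rate]
        germ_idx.append(g)
        normal_idx.append(keep)

    gene_w, segments = _segment_weights(genome, gene_mult, dom_mult)
    gene_p = gene_w / gene_w.sum()
    germ_offsets = np.sort(pool.offsets)

    def draw_somatic_offsets(count: int, forbidden: set[int]) -> np.ndarray:
        """Distinct global offsets at the mutated per-base rates."""
        got: list[int] = []
        need = count
        while need > 0:
            gi = rng.choice(len(gene_p), size=need, p=gene_p)
            within = _sample_positions_in_genes(rng, genome, gi, segments)
            offs = genome.gene_starts[gi] + within
            in_pool = germ_offsets[
                np.clip(np.searchsorted(germ_offsets, offs), 0, len(germ_offsets) - 1)
            ] == offs
            for o, bad in zip(offs.tolist(), in_pool.tolist()):
                if bad or o in forbidden:
                    continue
                forbidden.add(o)
                got.append(o)
            need = count - len(got)
        return np.array(got, dtype=np.int64)

    used: set[int] = set()

    # shared recurrent hotspot pool
    rec_offsets = draw_somatic_offsets(config.recurrent_pool_size, used)
    rec_keys = _keys_for_offsets(rng, genome, rec_offsets)

    tumor: list[CallSet] = []
    somatic_counts = rng.poisson(config.somatic_per_patient, n_pat)
    somatic_counts = np.maximum(somatic_counts, 1)
    af = config.artifact_fraction
    for i in range(n_pat):
        s_i = int(somatic_counts[i])
        is_rec = rng.random(s_i) < config.recurrent_fraction
        n_rec = min(int(is_rec.sum()), len(rec_keys))
        rec_choice = (
            rng.choice(len(rec_keys), size=n_rec, replace=False)
            if n_rec
            else np.array([], dtype=int)
        )
        priv_offsets = draw_somatic_offsets(s_i - n_rec, used)
        priv_keys = _keys_for_offsets(rng, genome, priv_offsets)

        cs = CallSet(sample_id=patient_ids[i])
        for j in rec_choice.tolist():
            k = rec_keys[j]
            if k in cs.variants:
                continue
            cs.variants.add(k)
            gi2, _, _, cpos = genome.locate(np.array([rec_offsets[j]]))
            cs.attrs[k] = {
                "label": "somatic",
                "gene": genome.gene_ids[int(gi2[0])],
                "cds_pos": int(cpos[0]),
            }
        gi2, _, _, cpos = (
            genome.locate(priv_offsets) if len(priv_offsets) else (np.array([], dtype=int), [], [], np.array([], dtype=int))
        )
        for j, k in enumerate(priv_keys):
            cs.variants.add(k)
            cs.attrs[k] = {
                "label": "somatic",
                "gene": genome.gene_ids[int(gi2[j])],
                "cds_pos": int(cpos[j]),
            }

        n_somatic = len(cs.variants)
        if af > 0 and len(germ_idx[i]) > 0:
            lam = n_somatic * af / (1.0 - af)
            n_art = min(int(rng.poisson(lam)), len(germ_idx[i]))
            art = rng.choice(germ_idx[i], size=n_art, replace=False) if n_art else np.array([], dtype=int)
            for j in np.sort(art).tolist():
                k = pool.keys[j]
                cs.variants.add(k)
                cs.attrs[k] = {
                    "label": "artifact",
                    "gene": pool.gene_ids[j],
                    "cds_pos": int(pool.cds_pos[j]),
                }
        tumor.append(cs)

    normal: list[CallSet] = []
    for i in range(n_pat):
        cs = CallSet(sample_id=patient_ids[i])
        for j in normal_idx[i].tolist():
            k = pool.keys[j]
            cs.variants.add(k)
            cs.attrs[k] = {
                "label": "germline",
                "gene": pool.gene_ids[j],
                "cds_pos": int(pool.cds_pos[j]),
            }
        normal.append(cs)

    germline_sets = [frozenset(pool.keys[j] for j in g.tolist()) for g in germ_idx]
    return SimulatedCohort(
        patient_ids=patient_ids,
        tumor=tumor,
        normal=normal,
        germline=germline_sets,
        pool=pool,
        genome=genome,
        config=config,
        recurrent_sites=rec_keys,
    )


def _keys_for_offsets(
    rng: np.random.Generator, genome: SyntheticGenome, offsets: np.ndarray
) -> list[VariantKey]:
    if len(offsets) == 0:
        return []
    _, chroms, pos, _ = genome.locate(offsets)
    refs, alts = _alleles(rng, len(offsets))
    return [
        VariantKey(chroms[i], int(pos[i]), BASES[refs[i]], BASES[alts[i]])
        for i in range(len(offsets))
    ]


# ---------------------------------------------------------------------------
# survival


def simulate_survival(
    cohort: SimulatedCohort,
    config: SurvivalConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival times with gene-linked hazards.

    A patient's hazard is ``baseline_hazard`` times the product of
    ratios for every hazard-map gene hit by one of their true somatic
    calls; times beyond ``censoring_time`` are administratively censored
    (event = 0).  Returns a table (patient_id, time, event).
    """
    if cohort.genome is not None:
        known = cohort.genome.annotations.genes
        for g in config.hazard_ratio_by_gene:
            if g not in known:
                raise ValueError(f"hazard map references unknown gene {g!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for pid, cs in zip(cohort.patient_ids, cohort.tumor):
        hazard = config.baseline_hazard
        hit = {
            cs.attrs[k].get("gene")
            for k in cs.variants
            if cs.attrs.get(k, {}).get("label") == "somatic"
        }
        for g, hr in config.hazard_ratio_by_gene.items():
            if g in hit:
                hazard *= hr
        t = rng.exponential(1.0 / hazard)
        if t > config.censoring_time:
            rows.append((pid, config.censoring_time, 0))
        else:
            rows.append((pid, t, 1))
    return pd.DataFrame(rows, columns=["patient_id", "time", "event"])
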