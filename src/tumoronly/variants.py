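"""Core domain containers for tumor-only SNV analysis.

The unit of identity throughout the package is the single-nucleotide
variant key (chromosome, 1-based position, reference base, alternate
base).  Two calls in different samples refer to the same variant if and
only if their keys are equal; all filtering is set algebra over keys.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Iterable, Iterator, NamedTuple

__all__ = [
    "BASES",
    "VariantKey",
    "variant_key",
    "CallSet",
    "PanelCollection",
    "Domain",
    "GeneModel",
    "AnnotationBundle",
    "chrom_sort_key",
]

BASES = ("A", "C", "G", "T")
_BASE_SET = frozenset(BASES)

#: Default total protein-coding space, in bases (~30.8 Mb).
DEFAULT_CODING_SPACE = 30_800_000
#: Default number of protein-coding genes in the mutation-rate denominator.
DEFAULT_TOTAL_GENES = 17_175


class VariantKey(NamedTuple):
    """A genomic single-nucleotide change; hashable identity for set operations."""

    chrom: str
    pos: int
    ref: str
    alt: str


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Build a validated :class:`VariantKey`.

    Raises ``ValueError`` for non-SNV alleles (multi-base ref/alt),
    non-ACGT bases, ref == alt, or a non-positive position.
    """
    ref = ref.upper()
    alt = alt.upper()
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    if ref not in _BASE_SET or alt not in _BASE_SET:
        raise ValueError(f"SNV alleles must be single bases in ACGT, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt must differ at {chrom}:{pos}")
    return VariantKey(str(chrom), int(pos), ref, alt)


_CHROM_RE = re.compile(r"^(chr)?(\d+|[XYM]T?)$", re.IGNORECASE)


def chrom_sort_key(chrom: str):
    """Natural chromosome ordering: 1..22, X, Y, MT, then lexicographic."""
    m = _CHROM_RE.match(chrom)
    if m:
        body = m.group(2).upper()
        if body.isdigit():
            return (0, int(body), "")
        return (0, {"X": 23, "Y": 24, "M": 25, "MT": 25}[body], "")
    return (1, 0, chrom)


@dataclasses.dataclass
class CallSet:
    """One sample's set of variant keys with optional per-variant attributes.

    ``attrs`` maps a key to a small dict; recognised entries are
    ``label`` (truth label: germline / somatic / artifact), ``gene``
    (gene id) and ``cds_pos`` (1-based position within the gene CDS).
    """

    sample_id: str
    variants: set[VariantKey] = dataclasses.field(default_factory=set)
    attrs: dict[VariantKey, dict] = dataclasses.field(default_factory=dict)
    n_skipped_records: int = 0

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.variants

    def __iter__(self) -> Iterator[VariantKey]:
        return iter(self.variants)

    def sorted_variants(self) -> list[VariantKey]:
        return sorted(self.variants, key=lambda v: (chrom_sort_key(v.chrom), v.pos, v.ref, v.alt))

    def label_of(self, key: VariantKey) -> str | None:
        return self.attrs.get(key, {}).get("label")

    def gene_of(self, key: VariantKey) -> str | None:
        return self.attrs.get(key, {}).get("gene")

    def subset(self, keys: Iterable[VariantKey], sample_id: str | None = None) -> "CallSet":
        """New CallSet restricted to ``keys`` (attributes carried over)."""
        keep = self.variants.intersection(keys)
        return CallSet(
            sample_id=sample_id or self.sample_id,
            variants=keep,
            attrs={k: dict(self.attrs[k]) for k in keep if k in self.attrs},
        )


@dataclasses.dataclass
class PanelCollection:
    """Germline call sets from external individuals, tagged with a population."""

    label: str
    members: list[CallSet] = dataclasses.field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[CallSet]:
        return iter(self.members)

    def site_union(self) -> set[VariantKey]:
        out: set[VariantKey] = set()
        for m in self.members:
            out |= m.variants
        return out


@dataclasses.dataclass(frozen=True)
class Domain:
    """A protein-domain interval in 1-based inclusive CDS base coordinates."""

    domain_id: str
    start: int
    end: int
    cosmic: bool = False

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid domain interval [{self.start}, {self.end}] for {self.domain_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, cds_pos: int) -> bool:
        return self.start <= cds_pos <= self.end


@dataclasses.dataclass
class GeneModel:
    gene_id: str
    cds_length: int
    domains: list[Domain] = dataclasses.field(default_factory=list)

    def __post_init__(self):
        if self.cds_length < 1:
            raise ValueError(f"gene {self.gene_id} has non-positive CDS length")
        for d in self.domains:
            if d.end > self.cds_length:
                raise ValueError(
                    f"domain {d.domain_id} [{d.start},{d.end}] exceeds CDS "
                    f"length {self.cds_length} of {self.gene_id}"
                )


@dataclasses.dataclass
class AnnotationBundle:
    """Gene models, pathway gene sets, and the enrichment constants.

    ``total_cds_length`` is N, the size of the mutation space in bases
    (defaults to the sum of gene CDS lengths); ``total_genes`` is the
    denominator of the per-patient mutation rate M (defaults to the
    number of genes in the bundle); ``cohort_size`` may be left None and
    taken from the cohort at analysis time.
    """

    genes: dict[str, GeneModel]
    pathways: dict[str, frozenset[str]] = dataclasses.field(default_factory=dict)
    total_cds_length: int | None = None
    total_genes: int | None = None
    cohort_size: int | None = None

    def __post_init__(self):
        if not self.genes:
            raise ValueError("annotation bundle needs at least one gene")
        if self.total_cds_length is None:
            self.total_cds_length = sum(g.cds_length for g in self.genes.values())
        if self.total_genes is None:
            self.total_genes = len(self.genes)
        longest = max(g.cds_length for g in self.genes.values())
        if self.total_cds_length < longest:
            raise ValueError("total CDS length smaller than the longest gene")
        if self.total_genes < 1:
            raise ValueError("total_genes must be positive")

    @property
    def n_total(self) -> int:
        return int(self.total_cds_length)

    def cds_length(self, gene_id: str) -> int:
        return self.genes[gene_id].cds_length
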