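"""Read/write the standard formats the pipeline touches.

VCF 4.2 in and out (via pysam), the gene/domain annotation table, GMT
pathway gene-set files, clinical survival tables, and known-variant
lists (dbSNP-style), plus the known-variant exclusion filter.

Truth labels from the simulator travel in the ``TL`` INFO field
(germline | somatic | artifact); gene assignment in ``GENE`` and the
1-based CDS coordinate in ``CPOS``.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .variants import (
    AnnotationBundle,
    CallSet,
    Domain,
    GeneModel,
    PanelCollection,
    VariantKey,
    chrom_sort_key,
    variant_key,
)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_known_sites",
    "filter_known_variants",
    "read_annotation_table",
    "write_annotation_table",
    "read_gmt",
    "write_gmt",
    "read_survival_table",
    "write_survival_table",
]

logger = logging.getLogger(__name__)

_HEADER_META = [
    '##INFO=<ID=TL,Number=1,Type=String,Description="Truth label: germline, somatic or artifact">',
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id the variant falls in">',
    '##INFO=<ID=CPOS,Number=1,Type=Integer,Description="1-based position within the gene CDS">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def _sorted_keys(keys: Iterable[VariantKey]) -> list[VariantKey]:
    return sorted(keys, key=lambda v: (chrom_sort_key(v.chrom), v.pos, v.ref, v.alt))


def _build_header(contigs: Sequence[str], samples: Sequence[str] = ()) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for line in _HEADER_META:
        header.add_line(line)
    for c in contigs:
        header.add_line(f"##contig=<ID={c}>")
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(obj: CallSet | PanelCollection, path: str | os.PathLike) -> None:
    """Write a CallSet (sites-only VCF) or PanelCollection (multi-sample VCF).

    Records are sorted by (chromosome, position, ref, alt) with natural
    chromosome ordering; the output is valid VCF 4.2 and byte-stable for
    identical inputs.
    """
    path = Path(path)
    if isinstance(obj, CallSet):
        keys = _sorted_keys(obj.variants)
        contigs = sorted({k.chrom for k in keys}, key=chrom_sort_key)
        header = _build_header(contigs)
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for k in keys:
                rec = out.new_record(contig=k.chrom, start=k.pos - 1, alleles=(k.ref, k.alt))
                a = obj.attrs.get(k, {})
                if a.get("label"):
                    rec.info["TL"] = str(a["label"])
                if a.get("gene"):
                    rec.info["GENE"] = str(a["gene"])
                if a.get("cds_pos") is not None:
                    rec.info["CPOS"] = int(a["cds_pos"])
                out.write(rec)
        return
    if isinstance(obj, PanelCollection):
        carriers: dict[VariantKey, set[str]] = {}
        for m in obj.members:
            for k in m.variants:
                carriers.setdefault(k, set()).add(m.sample_id)
        keys = _sorted_keys(carriers)
        contigs = sorted({k.chrom for k in keys}, key=chrom_sort_key)
        sample_ids = [m.sample_id for m in obj.members]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("panel members must have unique sample ids")
        header = _build_header(contigs, sample_ids)
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for k in keys:
                rec = out.new_record(contig=k.chrom, start=k.pos - 1, alleles=(k.ref, k.alt))
                carry = carriers[k]
                for s in sample_ids:
                    rec.samples[s]["GT"] = (0, 1) if s in carry else (0, 0)
                out.write(rec)
        return
    raise TypeError(f"cannot write object of type {type(obj).__name__} as VCF")


def _snv_alleles(rec) -> list[tuple[str, int]]:
    """Valid SNV (alt, allele_index) pairs of a record; allele_index is 1-based."""
    out = []
    if rec.alts is None or rec.ref is None:
        return out
    for i, alt in enumerate(rec.alts, start=1):
        if alt is None:
            continue
        if len(rec.ref) == 1 and len(alt) == 1 and alt != rec.ref and alt in "ACGT" and rec.ref in "ACGT":
            out.append((alt, i))
    return out


def read_vcf(
    path: str | os.PathLike,
    sample: str | None = None,
    sample_id: str | None = None,
    population_label: str | None = None,
) -> CallSet | PanelCollection:
    """Read a VCF 4.x, keeping SNV records only.

    A sites-only VCF yields one :class:`CallSet` (named ``sample_id`` or
    the file stem).  A VCF with genotype columns yields a
    :class:`PanelCollection` of per-sample call sets (a sample carries a
    variant if its GT includes the alternate allele), or a single
    CallSet when ``sample`` selects one column.  Non-SNV alleles are
    skipped and counted (``n_skipped_records`` on the result, also
    logged).
    """
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed or unreadable VCF {path}: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        if sample is not None and sample not in samples:
            raise ValueError(f"sample {sample!r} not present in {path}")
        n_skipped = 0
        if not samples:
            cs = CallSet(sample_id=sample_id or path.stem.replace(".vcf", ""))
            for rec in vf:
                snvs = _snv_alleles(rec)
                n_skipped += (0 if rec.alts is None else len(rec.alts)) - len(snvs)
                for alt, _ in snvs:
                    k = variant_key(rec.chrom, rec.pos, rec.ref, alt)
                    cs.variants.add(k)
                    a = {}
                    if "TL" in rec.info:
                        a["label"] = str(rec.info["TL"])
                    if "GENE" in rec.info:
                        a["gene"] = str(rec.info["GENE"])
                    if "CPOS" in rec.info:
                        a["cds_pos"] = int(rec.info["CPOS"])
                    if a:
                        cs.attrs[k] = a
            cs.n_skipped_records = n_skipped
            if n_skipped:
                logger.info("read_vcf(%s): skipped %d non-SNV allele(s)", path, n_skipped)
            return cs
        wanted = samples if sample is None else [sample]
        members = {s: CallSet(sample_id=s) for s in wanted}
        for rec in vf:
            snvs = _snv_alleles(rec)
            n_skipped += (0 if rec.alts is None else len(rec.alts)) - len(snvs)
            for alt, ai in snvs:
                k = variant_key(rec.chrom, rec.pos, rec.ref, alt)
                for s in wanted:
                    gt = rec.samples[s].get("GT")
                    if gt and ai in [g for g in gt if g is not None]:
                        members[s].variants.add(k)
        if n_skipped:
            logger.info("read_vcf(%s): skipped %d non-SNV allele(s)", path, n_skipped)
        if sample is not None:
            cs = members[sample]
            cs.n_skipped_records = n_skipped
            return cs
        panel = PanelCollection(
            label=population_label or path.stem.replace(".vcf", ""),
            members=[members[s] for s in wanted],
        )
        return panel


def read_known_sites(path: str | os.PathLike) -> frozenset[VariantKey]:
    """Load a known-variant list from VCF or a 4-column TSV (chrom pos ref alt)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".vcf", ".vcf.gz", ".bcf")):
        obj = read_vcf(path)
        if isinstance(obj, PanelCollection):
            return frozenset(obj.site_union())
        return frozenset(obj.variants)
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 4:
        raise ValueError(f"known-variant TSV {path} needs 4 columns (chrom pos ref alt)")
    return frozenset(
        variant_key(r[0], int(r[1]), r[2], r[3]) for r in df.itertuples(index=False)
    )


def filter_known_variants(
    calls: CallSet, *known: Iterable[VariantKey]
) -> CallSet:
    """Remove variants present in any known-variant set (dbSNP-style exclusion).

    Returns a new CallSet; the input is left unmodified.  Idempotent,
    and the order of the known sets is irrelevant.
    """
    drop: set[VariantKey] = set()
    for ks in known:
        drop.update(ks)
    keep = calls.variants - drop
    return CallSet(
        sample_id=calls.sample_id,
        variants=keep,
        attrs={k: dict(calls.attrs[k]) for k in keep if k in calls.attrs},
    )


# ---------------------------------------------------------------------------
# annotation tables and pathway gene sets


def read_annotation_table(
    path: str | os.PathLike,
    domain_unit: str = "nt",
    total_cds_length: int | None = None,
    total_genes: int | None = None,
    cohort_size: int | None = None,
) -> AnnotationBundle:
    """Read a gene/domain annotation TSV.

    Columns: ``gene_id  cds_length  domain_id  dstart  dend  cosmic_flag``;
    domain fields are ``.`` on rows describing a domain-less gene.  Domain
    coordinates are 1-based inclusive CDS bases by default; pass
    ``domain_unit="aa"`` for amino-acid coordinates (converted on ingest,
    residue r spanning bases 3(r-1)+1 .. 3r).
    """
    if domain_unit not in ("nt", "aa"):
        raise ValueError("domain_unit must be 'nt' or 'aa'")
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["gene_id", "cds_length", "domain_id", "dstart", "dend", "cosmic_flag"],
        dtype=str,
    )
    genes: dict[str, GeneModel] = {}
    domains: dict[str, list[Domain]] = {}
    lengths: dict[str, int] = {}
    for r in df.itertuples(index=False):
        gid = str(r.gene_id)
        lengths.setdefault(gid, int(r.cds_length))
        if r.domain_id and str(r.domain_id) != ".":
            start, end = int(r.dstart), int(r.dend)
            if domain_unit == "aa":
                start, end = 3 * (start - 1) + 1, 3 * end
            cosmic = str(r.cosmic_flag).strip().lower() in ("1", "true", "t", "yes")
            domains.setdefault(gid, []).append(
                Domain(domain_id=str(r.domain_id), start=start, end=end, cosmic=cosmic)
            )
    for gid, length in lengths.items():
        genes[gid] = GeneModel(gene_id=gid, cds_length=length, domains=domains.get(gid, []))
    return AnnotationBundle(
        genes=genes,
        total_cds_length=total_cds_length,
        total_genes=total_genes,
        cohort_size=cohort_size,
    )


def write_annotation_table(bundle: AnnotationBundle, path: str | os.PathLike) -> None:
    rows = []
    for gid in sorted(bundle.genes):
        g = bundle.genes[gid]
        if not g.domains:
            rows.append((gid, g.cds_length, ".", ".", ".", "."))
        for d in g.domains:
            rows.append((gid, g.cds_length, d.domain_id, d.start, d.end, int(d.cosmic)))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path: str | os.PathLike) -> dict[str, frozenset[str]]:
    """Read pathway gene sets in GMT format (id, description, gene ids...)."""
    out: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
            out[parts[0]] = frozenset(g for g in parts[2:] if g)
    return out


def write_gmt(
    pathways: Mapping[str, Iterable[str]],
    path: str | os.PathLike,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for pid in sorted(pathways):
            desc = (descriptions or {}).get(pid, "na")
            genes = "\t".join(sorted(pathways[pid]))
            fh.write(f"{pid}\t{desc}\t{genes}\n")


# ---------------------------------------------------------------------------
# survival tables


def read_survival_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"patient_id", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    return df


def write_survival_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
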