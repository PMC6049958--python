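"""Readers and writers for the formats the pipeline touches.

VCF 4.x is read and written through :mod:`pysam`, which supports the
tetraploid ``a/b/c/d`` GT encoding natively; GFF3 gene annotations are
read through :mod:`gffutils`. Tables are plain TSV with ``NA`` for
missing values and 6-significant-digit floats so that repeated runs are
byte-identical.

Genotypes are treated as unphased ALT-allele dosages; phase separators
are ignored because every downstream statistic is frequency-based. The
outgroup panel may have a different ploidy (e.g. a diploid species used
for polarization); its genotypes contribute allele states only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
import pysam

from .core import MISSING, GeneAnnotation, GenotypeMatrix

logger = logging.getLogger(__name__)

_ALLOWED_PLOIDY = (1, 2, 4)


@dataclass
class VariantRecord:
    """One biallelic SNP with per-sample dosages after filtering."""

    scaffold: str
    position: int  # 1-based, as in VCF
    ref_allele: str
    alt_allele: str
    dosage: np.ndarray  # ALT-allele count per sample, MISSING where filtered
    ploidy: np.ndarray
    depth: np.ndarray  # -1 where the VCF carries no DP
    low_sample_pops: list = field(default_factory=list)


def _is_snp(ref: str, alts) -> bool:
    return (
        alts is not None
        and len(alts) == 1
        and len(ref) == 1
        and alts[0] is not None
        and len(alts[0]) == 1
        and ref != alts[0]
    )


def read_vcf(path, min_depth: int = 4, min_individuals: int = 5, populations=None):
    """Stream biallelic SNP records from a VCF, applying the depth filter.

    Per-sample genotypes with sequencing depth below ``min_depth`` are set
    missing. If *populations* (label -> sample names) is given, records
    where any population has fewer than ``min_individuals`` non-missing
    genotypes are flagged via ``low_sample_pops`` (but still yielded).
    Records whose GT arity is not 1, 2 or 4 are rejected with a warning;
    multi-allelic records and indels are skipped silently (the pipeline
    is defined on biallelic SNPs only).
    """
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        pop_cols = None
        if populations is not None:
            lookup = {s: i for i, s in enumerate(samples)}
            missing = {
                s for pops in populations.values() for s in pops if s not in lookup
            }
            if missing:
                raise KeyError(f"samples absent from VCF: {sorted(missing)}")
            pop_cols = {
                label: np.array([lookup[s] for s in pops])
                for label, pops in populations.items()
            }
        for rec in vcf:
            if not _is_snp(rec.ref, rec.alts):
                continue
            n = len(samples)
            dosage = np.full(n, MISSING, dtype=np.int16)
            ploidy = np.zeros(n, dtype=np.int16)
            depth = np.full(n, -1, dtype=np.int32)
            malformed = False
            for j, s in enumerate(samples):
                call = rec.samples[s]
                gt = call.get("GT")
                if gt is None or all(a is None for a in gt):
                    ploidy[j] = 0
                    continue
                if len(gt) not in _ALLOWED_PLOIDY:
                    malformed = True
                    break
                ploidy[j] = len(gt)
                dp = call.get("DP")
                if dp is not None:
                    depth[j] = dp
                    if dp < min_depth:
                        continue  # genotype fails the depth filter -> missing
                if any(a is None for a in gt):
                    continue
                dosage[j] = sum(1 for a in gt if a == 1)
            if malformed:
                logger.warning(
                    "rejecting %s:%d: GT arity not in %s",
                    rec.chrom,
                    rec.pos,
                    _ALLOWED_PLOIDY,
                )
                continue
            low = []
            if pop_cols is not None:
                for label, cols in pop_cols.items():
                    if int((dosage[cols] != MISSING).sum()) < min_individuals:
                        low.append(label)
            yield VariantRecord(
                scaffold=rec.chrom,
                position=rec.pos,
                ref_allele=rec.ref,
                alt_allele=rec.alts[0],
                dosage=dosage,
                ploidy=ploidy,
                depth=depth,
                low_sample_pops=low,
            )


def read_genotype_matrix(
    path, populations=None, min_depth: int = 4, min_individuals: int = 5
) -> GenotypeMatrix:
    """Load a whole VCF into a :class:`GenotypeMatrix`."""
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
    records = list(
        read_vcf(path, min_depth=min_depth, min_individuals=min_individuals,
                 populations=populations)
    )
    if not records:
        raise ValueError(f"no usable biallelic SNPs in {path}")
    sites = pd.DataFrame(
        {
            "scaffold": [r.scaffold for r in records],
            "position": [r.position for r in records],
            "ref": [r.ref_allele for r in records],
            "alt": [r.alt_allele for r in records],
        }
    )
    dosage = np.stack([r.dosage for r in records])
    # per-sample ploidy: maximum observed arity (0 rows are no-calls)
    ploidy = np.max(np.stack([r.ploidy for r in records]), axis=0)
    order = np.lexsort((sites["position"].to_numpy(), sites["scaffold"].to_numpy()))
    return GenotypeMatrix(
        sites=sites.iloc[order].reset_index(drop=True),
        dosage=dosage[order],
        samples=samples,
        ploidy=ploidy,
        populations=dict(populations or {}),
    )


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as VCF 4.2 with tetraploid GT fields."""
    header = pysam.VariantHeader()
    for scaffold, sub in gm.sites.groupby("scaffold", sort=True):
        header.add_line(
            f"##contig=<ID={scaffold},length={int(sub['position'].max()) + 1000}>"
        )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in gm.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(gm.n_sites):
            row = gm.sites.iloc[i]
            rec = out.new_record(
                contig=row["scaffold"],
                start=int(row["position"]) - 1,
                stop=int(row["position"]),
                alleles=(row["ref"], row["alt"]),
            )
            for j, s in enumerate(gm.samples):
                k = int(gm.ploidy[j])
                d = int(gm.dosage[i, j])
                if d == MISSING:
                    rec.samples[s]["GT"] = (None,) * k
                else:
                    rec.samples[s]["GT"] = (0,) * (k - d) + (1,) * d
                rec.samples[s].phased = False
            out.write(rec)


def read_gff_genes(path) -> list:
    """Parse gene features from a GFF3 file.

    Returns :class:`GeneAnnotation` records sorted by (scaffold, start),
    deduplicated. Duplicate gene IDs raise; a file without gene features
    returns an empty list with a warning.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    genes = {}
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        ann = GeneAnnotation(
            gene_id=gid,
            scaffold=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand or ".",
        )
        if gid in genes:
            prev = genes[gid]
            if (prev.scaffold, prev.start, prev.end) != (
                ann.scaffold,
                ann.start,
                ann.end,
            ):
                raise ValueError(f"duplicate gene_id {gid!r} with conflicting spans")
            continue
        genes[gid] = ann
    if not genes:
        logger.warning("no gene features found in %s", path)
    return sorted(genes.values(), key=lambda g: (g.scaffold, g.start, g.gene_id))


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic TSV: header, NA for missing, 6-significant-digit floats."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def write_bed(windows, path) -> None:
    """Export windows as BED (0-based, half-open) spans."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.scaffold}\t{w.start_bp - 1}\t{w.end_bp}\t{w.n_snps}\n")
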