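"""Readers and writers for the pipeline's on-disk formats.

SNP genotypes travel as a minimal unphased VCF (11 biallelic sites, GT
field); HLA typings, phenotypes/covariates, truth tables, spectra and
association results are tab-separated tables. Writing then reading a
dataset is the identity on all fields.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .haplotypes import HLA_LOCI, N_SNPS, normalize_allele
from .simulate import GenotypeRecord

log = logging.getLogger("cehkit")

#: marker identifiers of the 11 Class II SNPs (window around HLA-DRB1)
SNP_IDS = (
    "rs2395173", "rs2395174", "rs3129871", "rs7192", "rs3129890", "rs9268832",
    "rs532098", "rs17533090", "rs2187668", "rs1063355", "rs9275141",
)
#: synthetic 1-based coordinates: evenly spaced placeholders on chromosome 6
SNP_POSITIONS = tuple(32_400_000 + 24_000 * i for i in range(N_SNPS))

MISSING = "NA"


def write_vcf(records: Sequence[GenotypeRecord], path) -> None:
    """Write the 11-SNP genotypes as a minimal unphased VCF (GT only)."""
    path = Path(path)
    samples = [r.sample_id for r in records]
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=6>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for s in range(N_SNPS):
            cells = []
            for r in records:
                if r.snps is None:
                    cells.append("./.")
                else:
                    a, b = r.snps[s]
                    cells.append(f"{a}/{b}")
            fh.write(
                f"6\t{SNP_POSITIONS[s]}\t{SNP_IDS[s]}\tA\tG\t.\tPASS\t.\tGT\t"
                + "\t".join(cells)
                + "\n"
            )


def read_vcf(path) -> dict[str, Optional[tuple[tuple[str, str], ...]]]:
    """Read the minimal VCF back: sample id -> 11 sorted allele pairs.

    Phased separators ("|") are accepted and treated as unphased. A sample
    with any missing site gets None (the SNP haplotype is unusable).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"duplicate sample ids in VCF: {dupes}")
    per_site: list[list[Optional[tuple[str, str]]]] = []
    for variant in vcf:
        row: list[Optional[tuple[str, str]]] = []
        for a, b, _phased in (g[:3] for g in variant.genotypes):
            if a < 0 or b < 0:
                row.append(None)
            else:
                row.append(tuple(sorted((str(a), str(b)))))  # type: ignore[arg-type]
        per_site.append(row)
    vcf.close()
    if len(per_site) != N_SNPS:
        raise ValueError(f"expected {N_SNPS} SNP sites, found {len(per_site)}")
    out: dict[str, Optional[tuple[tuple[str, str], ...]]] = {}
    for j, sid in enumerate(samples):
        pairs = [per_site[s][j] for s in range(N_SNPS)]
        out[sid] = None if any(p is None for p in pairs) else tuple(pairs)
    return out


def write_hla_tsv(records: Sequence[GenotypeRecord], path) -> None:
    rows = []
    for r in records:
        for locus in HLA_LOCI:
            pair = r.hla.get(locus)
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "locus": locus,
                    "allele1": pair[0] if pair else MISSING,
                    "allele2": pair[1] if pair else MISSING,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_phenotypes_tsv(records: Sequence[GenotypeRecord], path) -> None:
    n_cov = max((len(r.covariates) for r in records), default=0)
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "phenotype": {1: "case", 0: "control", None: MISSING}[r.phenotype],
            "region": r.region if r.region is not None else MISSING,
            "sex": r.sex if r.sex is not None else MISSING,
        }
        for k in range(n_cov):
            row[f"pc{k + 1}"] = r.covariates[k] if k < len(r.covariates) else MISSING
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_dataset(vcf_path, hla_path, pheno_path) -> list[GenotypeRecord]:
    """Join the SNP VCF, HLA TSV and phenotype TSV into GenotypeRecords.

    Raises on duplicate sample ids or on sample-id mismatches between the
    three files (listing the offenders); logs per-locus missingness.
    """
    snps = read_vcf(vcf_path)
    hla_df = pd.read_csv(hla_path, sep="\t", dtype=str)
    pheno_df = pd.read_csv(pheno_path, sep="\t", dtype=str)

    if pheno_df["sample_id"].duplicated().any():
        dupes = sorted(pheno_df.loc[pheno_df["sample_id"].duplicated(), "sample_id"])
        raise ValueError(f"duplicate sample ids in phenotype table: {dupes}")

    vcf_ids = set(snps)
    hla_ids = set(hla_df["sample_id"])
    ph_ids = set(pheno_df["sample_id"])
    if not (vcf_ids == hla_ids == ph_ids):
        offenders = sorted(vcf_ids ^ hla_ids | vcf_ids ^ ph_ids | hla_ids ^ ph_ids)
        raise ValueError(f"sample ids disagree between inputs: {offenders[:20]}")

    hla_map: dict[str, dict[str, Optional[tuple[str, str]]]] = {}
    for row in hla_df.itertuples(index=False):
        locus = row.locus
        if locus not in HLA_LOCI:
            raise ValueError(f"unknown HLA locus {locus!r}")
        pair: Optional[tuple[str, str]]
        if row.allele1 == MISSING or row.allele2 == MISSING:
            pair = None
        else:
            pair = tuple(
                sorted(normalize_allele(locus, a) for a in (row.allele1, row.allele2))
            )  # type: ignore[assignment]
        hla_map.setdefault(row.sample_id, {})[locus] = pair

    records = []
    miss_counts = {locus: 0 for locus in HLA_LOCI}
    miss_counts["SNP"] = 0
    for row in pheno_df.itertuples(index=False):
        sid = row.sample_id
        hla = {locus: hla_map.get(sid, {}).get(locus) for locus in HLA_LOCI}
        for locus in HLA_LOCI:
            if hla[locus] is None:
                miss_counts[locus] += 1
        if snps[sid] is None:
            miss_counts["SNP"] += 1
        pcs = tuple(
            float(getattr(row, f)) for f in pheno_df.columns if f.startswith("pc")
        )
        records.append(
            GenotypeRecord(
                sample_id=sid,
                hla=hla,
                snps=snps[sid],
                phenotype={"case": 1, "control": 0}.get(row.phenotype),
                region=None if row.region == MISSING else row.region,
                sex=None if row.sex == MISSING else int(row.sex),
                covariates=pcs,
            )
        )
    for locus, cnt in miss_counts.items():
        if cnt:
            log.info("missing %s calls for %d of %d samples", locus, cnt, len(records))
    return records


def write_dataset(records: Sequence[GenotypeRecord], outdir) -> dict[str, str]:
    """Write vcf + hla + phenotype files into ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": str(outdir / "snps.vcf"),
        "hla": str(outdir / "hla.tsv"),
        "phenotypes": str(outdir / "phenotypes.tsv"),
    }
    write_vcf(records, paths["vcf"])
    write_hla_tsv(records, paths["hla"])
    write_phenotypes_tsv(records, paths["phenotypes"])
    return paths


def write_assignments_tsv(assignments, path) -> None:
    """Write per-sample phased pairs: sample_id, hap1, hap2, posterior."""
    rows = [
        {
            "sample_id": sid,
            "hap1": dip.hap1.key,
            "hap2": dip.hap2.key,
            "posterior": post,
        }
        for sid, (dip, post) in assignments.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_assignments_tsv(path):
    from .haplotypes import CEH, Diplotype

    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    out = {}
    for row in df.itertuples(index=False):
        dip = Diplotype(CEH.from_string(row.hap1), CEH.from_string(row.hap2))
        out[row.sample_id] = (dip, float(row.posterior))
    return out
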