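"""Readers and writers for the pipeline's file formats.

Formats are plain text throughout: local-ancestry tracts as a tab-separated
"msp-like" long table (one row per tract, optional posterior column),
dosages as VCF (read via cyvcf2, written as uncompressed VCF 4.2 text) or a
wide TSV, phenotypes as CSV, marker maps and results as TSV.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (DEFAULT_ANCESTRIES, CohortTable, DosageMatrix,
                        FormatError, GenomicMap, GlobalAncestry,
                        LocalAncestrySet, RegionSet, ScanResult)

logger = logging.getLogger("admixkit")

# ---------------------------------------------------------------- marker map


def write_genomic_map(gmap: GenomicMap, path) -> None:
    pd.DataFrame({"chrom": gmap.chrom, "pos": gmap.pos, "cm": gmap.cm}).to_csv(
        path, sep="\t", index=False)


def read_genomic_map(path) -> GenomicMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return GenomicMap(df["chrom"].to_numpy(object),
                      df["pos"].to_numpy(np.int64),
                      df["cm"].to_numpy(float))


# ------------------------------------------------------- local ancestry TSV

TRACT_HEADER = ["chm", "spos", "epos", "individual", "hap", "ancestry",
                "posterior"]


def write_local_ancestry(la: LocalAncestrySet, path) -> None:
    """Write tracts as a tab-separated long table.

    The first line is a comment naming the ancestry codes, mirroring the
    subpopulation-order header of RFMix msp output.
    """
    with open(path, "w") as fh:
        fh.write("#ancestries: " + " ".join(la.ancestries) + "\n")
        fh.write("\t".join(TRACT_HEADER) + "\n")
        t = la.tracts
        for row in t.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.spos}\t{row.epos}\t"
                     f"{row.individual}\t{row.haplotype}\t{row.ancestry}\t"
                     f"{row.posterior:.6g}\n")


def read_local_ancestry(path, gmap: GenomicMap | None = None,
                        marker_spacing_bp: int = 50_000) -> LocalAncestrySet:
    """Read a tract file into a :class:`LocalAncestrySet`.

    The file must start with a ``#ancestries:`` comment naming the codes.
    A missing posterior column defaults to 1.0. If no marker grid is given,
    an evenly spaced grid (``marker_spacing_bp``) is laid over the tract
    span of each chromosome under a constant 1 cM/Mb map.
    """
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#ancestries:"):
            raise FormatError(
                "tract file must start with '#ancestries:' naming codes")
        ancestries = tuple(first.split(":", 1)[1].split())
        df = pd.read_csv(fh, sep="\t", dtype={"chm": str, "individual": str})
    if "posterior" not in df.columns:
        df["posterior"] = 1.0
    df = df.rename(columns={"chm": "chrom", "hap": "haplotype"})
    if gmap is None:
        spans = df.groupby("chrom").agg(lo=("spos", "min"), hi=("epos", "max"))
        chroms, poss = [], []
        for c, row in spans.iterrows():
            p = np.arange(row["lo"], row["hi"] + 1, marker_spacing_bp,
                          dtype=np.int64)
            chroms.append(np.full(len(p), c, dtype=object))
            poss.append(p)
        pos = np.concatenate(poss)
        gmap = GenomicMap(np.concatenate(chroms), pos, pos / 1e6)
    return LocalAncestrySet(df, gmap, ancestries)


# ------------------------------------------------------------------ dosages


def write_dosages_tsv(dm: DosageMatrix, path) -> None:
    head = dm.variants[["chrom", "pos", "ref", "alt", "info"]].copy()
    if "id" in dm.variants.columns:
        head.insert(2, "id", dm.variants["id"])
    wide = pd.concat(
        [head,
         pd.DataFrame(dm.dosages.T, columns=[str(s) for s in dm.samples])],
        axis=1)
    wide.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_dosages_tsv(path) -> DosageMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = [c for c in ("chrom", "pos", "id", "ref", "alt", "info")
                 if c in df.columns]
    samples = [c for c in df.columns if c not in meta_cols]
    variants = df[meta_cols].copy()
    dosages = df[samples].to_numpy(float).T
    return DosageMatrix(variants, samples, dosages)


def write_vcf(dm: DosageMatrix, path) -> None:
    """Write dosages as uncompressed VCF 4.2 with DS and (if integral) GT."""
    hard = np.all(np.isin(dm.dosages[~np.isnan(dm.dosages)], (0.0, 1.0, 2.0)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(dm.variants["chrom"]):
            stop = int(dm.variants.loc[dm.variants["chrom"] == c,
                                       "pos"].max())
            fh.write(f"##contig=<ID={c},length={stop + 1}>\n")
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,'
                 'Description="Imputation quality score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Expected alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in dm.samples) + "\n")
        ids = (dm.variants["id"] if "id" in dm.variants.columns
               else [f"var{i}" for i in range(dm.n_variants)])
        gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, (vid, row) in enumerate(zip(ids, dm.variants.itertuples())):
            ds = dm.dosages[:, j]
            if hard:
                sample_f = "\t".join(
                    f"{gt_of[int(d)]}:{d:g}" if np.isfinite(d) else "./.:."
                    for d in ds)
                fmt = "GT:DS"
            else:
                sample_f = "\t".join(
                    f"{d:.4g}" if np.isfinite(d) else "." for d in ds)
                fmt = "DS"
            fh.write(f"{row.chrom}\t{row.pos}\t{vid}\t{row.ref}\t{row.alt}\t"
                     f".\t.\tINFO={row.info:.4g}\t{fmt}\t{sample_f}\n")


def read_vcf_dosages(path) -> DosageMatrix:
    """Read a VCF into a DosageMatrix (DS field preferred, else GT).

    Indels are skipped with a logged count; a missing imputation INFO score
    defaults to 1.0; multi-allelic records are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, cols = [], []
    n_indels = 0
    for v in vcf:
        if len(v.ALT) != 1:
            raise FormatError(
                f"multi-allelic record at {v.CHROM}:{v.POS}")
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_indels += 1
            continue
        info = v.INFO.get("INFO")
        if info is None:
            info = v.INFO.get("R2", 1.0)
        try:
            ds = np.asarray(v.format("DS"), dtype=float).ravel()
        except KeyError:
            # gts012: 0/1/2 = alt-allele count, 3 = missing
            gt = np.asarray(v.gt_types, dtype=float)
            ds = np.where(gt == 3, np.nan, gt)
        bad = np.nonzero(np.isfinite(ds) & ((ds < 0) | (ds > 2)))[0]
        if len(bad):
            raise FormatError(
                f"dosage {ds[bad[0]]} outside [0,2] at {v.CHROM}:{v.POS}")
        rows.append((v.CHROM, v.POS, v.ID or f"{v.CHROM}:{v.POS}",
                     v.REF, v.ALT[0], float(info)))
        cols.append(ds)
    if n_indels:
        logger.info("read_vcf_dosages: skipped %d indel record(s)", n_indels)
    variants = pd.DataFrame(
        rows, columns=["chrom", "pos", "id", "ref", "alt", "info"])
    return DosageMatrix(variants, samples, np.asarray(cols, dtype=float).T)


def read_dosages(path) -> DosageMatrix:
    """Dispatch on extension: ``.vcf`` via cyvcf2, anything else as TSV."""
    p = str(path)
    if p.endswith(".vcf") or p.endswith(".vcf.gz"):
        return read_vcf_dosages(p)
    return read_dosages_tsv(p)


# ---------------------------------------------------------------- phenotypes


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.data.to_csv(path, index_label="individual")


def read_cohort(path, trait_types: dict[str, str] | None = None
                ) -> CohortTable:
    df = pd.read_csv(path, index_col="individual")
    return CohortTable(df, trait_types or {})


# ----------------------------------------------------------- result tables


def write_global_ancestry(ga: GlobalAncestry, path) -> None:
    ga.proportions.to_csv(path, sep="\t", index_label="individual",
                          float_format="%.10g")


def read_global_ancestry(path) -> GlobalAncestry:
    return GlobalAncestry(pd.read_csv(path, sep="\t", index_col="individual"))


def write_scan_result(scan: ScanResult, path) -> None:
    t = scan.table.copy()
    t["neglog10p"] = -np.log10(t["p"])
    with open(path, "w") as fh:
        fh.write(f"#model: {scan.model}\n")
        fh.write(f"#covariates: {','.join(scan.covariates)}\n")
        if scan.conditioning:
            fh.write(f"#conditioning: {','.join(scan.conditioning)}\n")
        t.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def read_scan_result(path) -> ScanResult:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, val = line[1:].strip().partition(": ")
            meta[key] = val
            pos = fh.tell()
        t = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    cov = tuple(v for v in meta.get("covariates", "").split(",") if v)
    cond = tuple(v for v in meta.get("conditioning", "").split(",") if v)
    return ScanResult(t.drop(columns=["neglog10p"], errors="ignore"),
                      model=meta.get("model", ""), covariates=cov,
                      conditioning=cond)


def write_regions(rs: RegionSet, path) -> None:
    rs.regions.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_regions(path) -> RegionSet:
    return RegionSet(pd.read_csv(path, sep="\t", dtype={"chrom": str}))
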