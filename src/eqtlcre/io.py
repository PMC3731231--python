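"""Readers/writers for the on-disk formats: TSV matrices, BED3+ tracks,
recombination maps, gene models, truth tables, and a plain-text VCF subset.

Coordinates are 0-based half-open on disk (BED convention); dosage TSVs have
samples as rows and SNPs as columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix, RecombinationMap

__all__ = [
    "read_bed", "write_bed",
    "read_dosage_tsv", "write_dosage_tsv",
    "read_snp_map", "write_snp_map",
    "read_expression_tsv", "write_expression_tsv",
    "read_gene_models", "write_gene_models",
    "read_recomb_map", "write_recomb_map",
    "read_vcf",
    "write_json", "read_json",
]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Parse BED3+ (tab-separated, no header) into a chrom/start/end(/name) frame."""
    rows = []
    names = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            rows.append((parts[0], start, end))
            names.append(parts[3] if len(parts) > 3 else "")
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if any(names):
        out["name"] = names
    return out.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def write_bed(intervals: pd.DataFrame, path: str | Path,
              name: str | None = None) -> None:
    iv = intervals.sort_values(["chrom", "start", "end"])
    with open(path, "w") as fh:
        for _, row in iv.iterrows():
            cols = [str(row["chrom"]), str(int(row["start"])), str(int(row["end"]))]
            if name is not None:
                cols.append(name)
            elif "name" in iv.columns:
                cols.append(str(row["name"]))
            fh.write("\t".join(cols) + "\n")


def write_dosage_tsv(gt: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(gt.dosages, index=gt.sample_ids, columns=gt.snp_ids)
    df.to_csv(path, sep="\t", index_label="sample_id", float_format="%.6g")


def read_dosage_tsv(path: str | Path,
                    snp_map: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Dosage TSV (rows samples, cols SNP ids) -> GenotypeMatrix.

    Coordinates/alleles come from ``snp_map`` when given, else placeholders.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if np.any((finite < 0) | (finite > 2)):
        raise ValueError(f"{path}: dosages outside [0, 2]")
    m = df.shape[1]
    if snp_map is not None:
        sm = snp_map.set_index("snp_id").loc[df.columns]
        chroms = sm["chrom"].to_numpy()
        pos = sm["pos"].to_numpy(dtype=np.int64)
        major = sm.get("major", pd.Series(["A"] * m)).to_numpy()
        minor = sm.get("minor", pd.Series(["C"] * m)).to_numpy()
    else:
        chroms = np.full(m, "chrUn", dtype=object)
        pos = np.arange(m, dtype=np.int64)
        major = np.full(m, "A", dtype=object)
        minor = np.full(m, "C", dtype=object)
    return GenotypeMatrix(list(df.index.astype(str)), list(df.columns),
                          chroms, pos, major, minor, vals)


def write_snp_map(snp_map: pd.DataFrame, path: str | Path) -> None:
    snp_map.to_csv(path, sep="\t", index=False)


def read_snp_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression_tsv(expr: pd.DataFrame, path: str | Path,
                         stage: str | None = None) -> None:
    expr.to_csv(path, sep="\t", index_label="sample_id", float_format="%.8g")
    if stage is not None:
        write_json({"stage": stage}, str(path) + ".meta.json")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_gene_models(gene_models: pd.DataFrame, path: str | Path) -> None:
    cols = ["gene_id", "chrom", "strand", "start", "end"]
    gene_models[cols].to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> pd.DataFrame:
    from .simulate import annotate_tss_tes
    gm = pd.read_csv(path, sep="\t")
    bad = gm[gm["start"] >= gm["end"]]
    if len(bad):
        raise ValueError(f"{path}: gene models with start >= end")
    return annotate_tss_tes(gm)


def write_recomb_map(rmap: RecombinationMap, path: str | Path) -> None:
    rmap.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_recomb_map(path: str | Path) -> RecombinationMap:
    df = pd.read_csv(path, sep="\t")
    chrom = str(df["chrom"].iloc[0])
    return RecombinationMap(chrom, df["pos"].to_numpy(np.int64),
                            df["rate_to_next"].to_numpy(float)[:-1])


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Minimal plain-text VCF reader: DS dosage when present, else GT allele count.

    Missing genotypes (./.) become NaN, to be mean-imputed by genotype QC.
    """
    samples: list[str] = []
    snp_ids, chroms, pos, ref, alt, rows = [], [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ValueError(f"{path}:{lineno}: truncated VCF record")
            fmt = parts[8].split(":")
            ds_i = fmt.index("DS") if "DS" in fmt else None
            gt_i = fmt.index("GT") if "GT" in fmt else None
            if ds_i is None and gt_i is None:
                raise ValueError(f"{path}:{lineno}: need GT or DS in FORMAT")
            vals = []
            for cell in parts[9:]:
                fields = cell.split(":")
                if ds_i is not None and ds_i < len(fields) and fields[ds_i] != ".":
                    d = float(fields[ds_i])
                else:
                    g = fields[gt_i].replace("|", "/")
                    if "." in g:
                        d = np.nan
                    else:
                        d = float(sum(int(a) for a in g.split("/")))
                if np.isfinite(d) and not (0 <= d <= 2):
                    raise ValueError(f"{path}:{lineno}: dosage outside [0, 2]")
                vals.append(d)
            snp_ids.append(parts[2] if parts[2] != "." else f"{parts[0]}:{parts[1]}")
            chroms.append(parts[0])
            pos.append(int(parts[1]) - 1)  # VCF is 1-based
            ref.append(parts[3])
            alt.append(parts[4])
            rows.append(vals)
    dosages = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, snp_ids, np.array(chroms, dtype=object),
                          np.array(pos, dtype=np.int64),
                          np.array(ref, dtype=object), np.array(alt, dtype=object),
                          dosages)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
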