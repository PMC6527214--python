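"""Readers and writers for the plain-text formats used across the pipeline.

Tabular data travel as TSV; genotypes as minimal VCF v4.2 with one
sample per inbred line (GT 0/0 or 1/1); gene annotation as BED
(0-based half-open on disk, converted to the package's canonical
1-based inclusive coordinates on read) or GFF3 gene features (already
1-based inclusive); interaction networks as two-column edge lists.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .gwa import GenotypeMatrix

__all__ = [
    "read_consumption", "write_consumption",
    "read_table", "write_table",
    "read_vcf", "write_vcf",
    "read_bed", "write_bed", "read_gff3",
    "read_edges", "write_edges",
    "read_json", "write_json",
]


# -- generic TSV -----------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- raw consumption -------------------------------------------------------

CONSUMPTION_DTYPES = {
    "line_id": str, "sex": str, "exposure": int, "solution": str,
    "vial": int, "capillary1_mm": float, "capillary2_mm": float, "is_control": int,
}


def write_consumption(records: pd.DataFrame, path: str | Path) -> Path:
    return write_table(records[list(CONSUMPTION_DTYPES)], path)


def read_consumption(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=CONSUMPTION_DTYPES)
    missing = [c for c in CONSUMPTION_DTYPES if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing consumption columns {missing}")
    return df


# -- VCF -------------------------------------------------------------------

def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> Path:
    """Write a minimal uncompressed VCF with one sample per line."""
    path = Path(path)
    chroms = genotypes.variants["chrom"].unique()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cafeqg\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.line_ids) + "\n")
        for j, row in enumerate(genotypes.variants.itertuples()):
            gts = []
            for call in genotypes.calls[:, j]:
                if np.isnan(call):
                    gts.append("./.")
                elif call == 2.0:
                    gts.append("1/1")
                else:
                    gts.append("0/0")
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")
    return path


def read_vcf(path: str | Path, heterozygous: str = "error") -> GenotypeMatrix:
    """Read homozygous biallelic calls from a VCF.

    ``heterozygous`` is "error" (default, an inbred panel should contain
    none) or "missing" (treat het calls as missing data).
    """
    if heterozygous not in ("error", "missing"):
        raise ValueError("heterozygous must be 'error' or 'missing'")
    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    var_rows, call_cols = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            continue  # biallelic only
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = np.asarray(v.gt_types, dtype=float)
        if np.any(gt == 1):
            if heterozygous == "error":
                raise ValueError(
                    f"heterozygous call at {v.CHROM}:{v.POS} in an inbred panel"
                )
            gt[gt == 1] = np.nan
        gt[gt == 2] = np.nan
        gt[gt == 3] = 2.0
        var_rows.append((v.CHROM, v.POS, v.ID or f"{v.CHROM}_{v.POS}", v.REF, v.ALT[0]))
        call_cols.append(gt)
    variants = pd.DataFrame(var_rows, columns=["chrom", "pos", "id", "ref", "alt"])
    calls = np.column_stack(call_cols) if call_cols else np.empty((len(line_ids), 0))
    return GenotypeMatrix(variants=variants, calls=calls, line_ids=line_ids)


# -- annotation ------------------------------------------------------------

ANNOTATION_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end", "strand"]


def write_bed(annotation: pd.DataFrame, path: str | Path) -> Path:
    """Write gene intervals as BED6 (0-based half-open)."""
    bed = pd.DataFrame({
        "chrom": annotation["chrom"],
        "start": annotation["start"] - 1,
        "end": annotation["end"],
        "name": annotation["gene_id"],
        "score": 0,
        "strand": annotation["strand"],
    })
    bed.to_csv(path, sep="\t", index=False, header=False)
    return Path(path)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED gene intervals into 1-based inclusive coordinates."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    if bed.shape[1] < 4:
        raise ValueError(f"{path}: BED needs at least chrom,start,end,name")
    out = pd.DataFrame({
        "gene_id": bed[3].astype(str),
        "symbol": bed[3].astype(str),
        "chrom": bed[0].astype(str),
        "start": bed[1].astype(int) + 1,
        "end": bed[2].astype(int),
        "strand": bed[5] if bed.shape[1] > 5 else "+",
    })
    if (out["start"] > out["end"]).any():
        raise ValueError(f"{path}: interval with start > end")
    return out


def _gff3_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        if part.startswith(f"{key}="):
            return part.split("=", 1)[1]
    return None


def read_gff3(path: str | Path, feature: str = "gene") -> pd.DataFrame:
    """Read gene features from GFF3 (1-based inclusive already)."""
    gff = pd.read_csv(path, sep="\t", header=None, comment="#",
                      names=["chrom", "source", "type", "start", "end",
                             "score", "strand", "phase", "attributes"])
    genes = gff[gff["type"] == feature]
    return pd.DataFrame({
        "gene_id": [_gff3_attr(a, "ID") or _gff3_attr(a, "Name") or f"g{i}"
                    for i, a in enumerate(genes["attributes"])],
        "symbol": [_gff3_attr(a, "Name") or _gff3_attr(a, "ID") or f"g{i}"
                   for i, a in enumerate(genes["attributes"])],
        "chrom": genes["chrom"].astype(str).to_numpy(),
        "start": genes["start"].astype(int).to_numpy(),
        "end": genes["end"].astype(int).to_numpy(),
        "strand": genes["strand"].to_numpy(),
    })


# -- interaction network ---------------------------------------------------

def write_edges(graph: nx.Graph, path: str | Path) -> Path:
    """Two-column TSV edge list; isolated nodes appear as self-referential
    placeholder rows are NOT written — node universe is edges' endpoints
    plus a commented node list header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# nodes: " + ",".join(sorted(graph.nodes)) + "\n")
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")
    return path


def read_edges(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# nodes:"):
            g.add_nodes_from(n for n in first.split(":", 1)[1].strip().split(",") if n)
        elif first.strip() and not first.startswith("gene_a"):
            a, b = first.split()[:2]
            g.add_edge(a, b)
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("gene_a"):
                continue
            a, b = line.split("\t")[:2]
            if a != b:
                g.add_edge(a, b)
    return g


# -- JSON ------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=1, sort_keys=True)
    return path


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
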