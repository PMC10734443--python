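"""Readers and writers for the plain-text formats the pipeline exchanges.

GFF3 (gene features only), counts TSV, a VCF v4.2 subset (INFO DP/AF),
growth CSV, region and category TSVs, and JSON for truth/summaries.
"""
from __future__ import annotations

import json
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from .models import (
    CountMatrix,
    GeneModel,
    GenomeAnnotation,
    GrowthSeries,
    RegionDefinition,
    TranscriptionalCluster,
    VariantRecord,
)

# ---------------------------------------------------------------- GFF3


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation:
            fh.write(
                f"{g.contig}\tredoxreg\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def read_gff3(path: str | Path) -> GenomeAnnotation:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes = [
        GeneModel(f.id, f.seqid, f.start, f.end, f.strand)
        for f in db.features_of_type("gene")
    ]
    return GenomeAnnotation(genes)


# ------------------------------------------------------------- counts


def write_counts_tsv(matrix: CountMatrix, path: str | Path) -> None:
    matrix.counts.rename_axis("gene_id").to_csv(path, sep="\t")


def write_conditions_csv(matrix: CountMatrix, path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(matrix.conditions), "condition": list(matrix.conditions.values())}
    ).to_csv(path, index=False)


def read_counts_tsv(counts_path: str | Path, conditions_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    cond = pd.read_csv(conditions_path)
    return CountMatrix(counts, dict(zip(cond["sample"], cond["condition"])))


def write_de_tsv(de: pd.DataFrame, path: str | Path) -> None:
    de.rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.6g")


def read_de_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


# ---------------------------------------------------------------- VCF


def write_vcf(records: list[VariantRecord], path: str | Path, contig_lengths: dict[str, int]) -> None:
    """Minimal VCF v4.2: CHROM POS ID REF ALT QUAL FILTER INFO(DP,AF).

    Deletions with an empty alt are written VCF-style, anchored on a
    placeholder preceding base (N) so the file stays format-valid.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Alt allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(records, key=lambda r: (r.contig, r.position)):
            pos, ref, alt = v.position, v.ref, v.alt
            if alt == "":  # anchor the deletion on a preceding placeholder base
                pos, ref, alt = pos - 1, "N" + ref, "N"
            fh.write(
                f"{v.contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tDP={v.coverage};AF={v.frequency}\n"
            )


def read_vcf(path: str | Path) -> list[VariantRecord]:
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        dp = rec.INFO.get("DP")
        af = rec.INFO.get("AF")
        ref, alt, pos = rec.REF, rec.ALT[0], rec.POS
        if len(ref) == 2 and len(alt) == 1 and ref[0] == alt:  # anchored 1-bp deletion
            pos, ref, alt = pos + 1, ref[1], ""
        out.append(  # AF comes back as float32; restore the written precision
            VariantRecord(rec.CHROM, pos, ref, alt, int(dp or 0), round(float(af or 0.0), 6))
        )
    return out


def write_variants_tsv(records: list[VariantRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "contig": v.contig,
                "position": v.position,
                "ref": v.ref,
                "alt": v.alt,
                "coverage": v.coverage,
                "frequency": v.frequency,
            }
            for v in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        VariantRecord(
            str(r.contig), int(r.position), str(r.ref), str(r.alt), int(r.coverage), float(r.frequency)
        )
        for r in df.itertuples()
    ]


# -------------------------------------------------------------- growth


def write_growth_csv(series: list[GrowthSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for t, a, b in zip(s.time_h, s.od660, s.od880):
            rows.append(
                {
                    "condition": s.condition,
                    "strain": s.strain,
                    "replicate": s.replicate,
                    "time_h": t,
                    "od660": a,
                    "od880": b,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_growth_csv(path: str | Path) -> list[GrowthSeries]:
    df = pd.read_csv(path)
    out = []
    for (condition, strain, replicate), grp in df.groupby(
        ["condition", "strain", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_h")
        out.append(
            GrowthSeries(
                str(condition),
                str(strain),
                str(replicate),
                grp["time_h"].to_numpy(),
                grp["od660"].to_numpy(),
                grp["od880"].to_numpy(),
            )
        )
    return out


# ---------------------------------------------------- regions / categories


def read_regions_tsv(path: str | Path) -> list[RegionDefinition]:
    df = pd.read_csv(path, sep="\t")
    return [
        RegionDefinition(str(r.name), str(r.contig), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def write_regions_tsv(regions: list[RegionDefinition], path: str | Path) -> None:
    pd.DataFrame(
        [{"name": r.name, "contig": r.contig, "start": r.start, "end": r.end} for r in regions]
    ).to_csv(path, sep="\t", index=False)


def read_category_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene_id"].astype(str), df["category"].astype(str)))


def write_category_tsv(category_map: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(category_map), "category": list(category_map.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- misc


def write_tc_tsv(tcs: list[TranscriptionalCluster], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "tc_id": tc.tc_id,
                "contig": tc.contig,
                "strand": tc.strand,
                "direction": tc.direction,
                "size": tc.size,
                "members": ",".join(tc.members),
                "avg_fc": round(tc.avg_fc, 4),
                "span_start": tc.span[0],
                "span_end": tc.span[1],
                "max_internal_gap": tc.max_internal_gap,
            }
            for tc in tcs
        ]
    ).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
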