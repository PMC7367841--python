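"""File-format boundaries: minimal VCF v4.2, UCSC chain text, SEG, GMT.

Internally all coordinates are 0-based half-open; conversions to 1-based
(VCF POS, SEG start/end) happen only here.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample identifier">
##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence annotation">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
"""


def write_vcf(variants: pd.DataFrame, path, contigs: Mapping[str, int] | None = None) -> None:
    """Write a variant table as minimal VCF v4.2 (POS converted to 1-based)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in variants.itertuples(index=False):
            info = [f"SAMPLE={row.sample_id}"]
            vaf = getattr(row, "vaf", None)
            if vaf is not None and pd.notna(vaf):
                info.append(f"VAF={vaf:.6g}")
            csq = getattr(row, "consequence", None)
            if csq:
                info.append(f"CSQ={csq}")
            gene = getattr(row, "gene", None)
            if gene and pd.notna(gene):
                info.append(f"GENE={gene}")
            fh.write(
                f"{row.chrom}\t{int(row.pos) + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                + ";".join(info)
                + "\n"
            )


def read_vcf(path) -> pd.DataFrame:
    """Read a minimal VCF into a variant table (POS converted to 0-based)."""
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ValueError(f"malformed VCF line: {line!r}")
            chrom, pos, _id, ref, alt, _qual, _filt, info = fields[:8]
            kv = dict(
                item.split("=", 1) for item in info.split(";") if "=" in item
            )
            rows.append(
                {
                    "sample_id": kv.get("SAMPLE", ""),
                    "chrom": chrom,
                    "pos": int(pos) - 1,
                    "ref": ref,
                    "alt": alt,
                    "vaf": float(kv["VAF"]) if "VAF" in kv else None,
                    "consequence": kv.get("CSQ", ""),
                    "gene": kv.get("GENE"),
                }
            )
    return pd.DataFrame(rows)


def read_gmt(path) -> dict[str, list[str]]:
    """Read GMT gene sets: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, list[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_seg(segments: pd.DataFrame, path) -> None:
    """Write segments as SEG (1-based inclusive coordinates on disk)."""
    out = segments.copy()
    out["loc.start"] = out["start"].astype(int) + 1
    out["loc.end"] = out["end"].astype(int)
    cols = ["sample_id", "chrom", "loc.start", "loc.end", "n_bins", "seg_mean"]
    out = out.rename(columns={"n_bins": "num.mark", "seg_mean": "seg.mean"})
    cols = ["sample_id", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
    out[cols].to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    """Read SEG back to 0-based half-open segments."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(
        columns={"loc.start": "start", "loc.end": "end", "num.mark": "n_bins", "seg.mean": "seg_mean"}
    )
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_gmt(sets: Mapping[str, Sequence[str]], path) -> None:
    with Path(path).open("w") as fh:
        for name, genes in sets.items():
            fh.write(name + "\tna\t" + "\t".join(genes) + "\n")
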