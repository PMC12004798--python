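"""Readers and writers for the text formats the pipeline exchanges.

The call format is the whitespace-separated per-line dialect emitted by
SNP-array CNV callers::

    chr1:1000-2000 numsnp=12 length=1001 state2,cn=1 COW001 startsnp=s1 endsnp=s12

All coordinates on disk and in memory are 1-based inclusive, except BED
output which is converted to 0-based half-open.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import pandas as pd

from .genome import GenomeBuild

# caller state codes <-> copy number (no LOH state)
STATE_FROM_CN = {0: 1, 1: 2, 3: 5, 4: 6}
CN_FROM_STATE = {v: k for k, v in STATE_FROM_CN.items()}

CALL_COLUMNS = ["sample_id", "chrom", "start", "end", "state", "numsnp",
                "startsnp", "endsnp", "dataset"]

_RAWCNV_RE = re.compile(
    r"^chr(?P<chrom>\S+):(?P<start>\d+)-(?P<end>\d+)\s+"
    r"numsnp=(?P<numsnp>\d+)\s+length=(?P<length>[\d,]+)\s+"
    r"state(?P<state>\d+),cn=(?P<cn>\d+)\s+(?P<sample>\S+)"
    r"(?:\s+startsnp=(?P<startsnp>\S+))?(?:\s+endsnp=(?P<endsnp>\S+))?\s*$"
)


class FormatError(ValueError):
    """Raised when an input file does not parse."""


def empty_calls() -> pd.DataFrame:
    return pd.DataFrame({
        "sample_id": pd.Series(dtype=str), "chrom": pd.Series(dtype=str),
        "start": pd.Series(dtype="int64"), "end": pd.Series(dtype="int64"),
        "state": pd.Series(dtype="int64"), "numsnp": pd.Series(dtype="int64"),
        "startsnp": pd.Series(dtype=str), "endsnp": pd.Series(dtype=str),
        "dataset": pd.Series(dtype=str),
    })


def read_rawcnv(path: str | Path, dataset: str | None = None) -> pd.DataFrame:
    """Parse a rawcnv call file into a calls DataFrame."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            m = _RAWCNV_RE.match(line)
            if m is None:
                raise FormatError(f"{path}:{lineno}: unparsable call line: {line!r}")
            d = m.groupdict()
            rows.append({
                "sample_id": d["sample"],
                "chrom": d["chrom"],
                "start": int(d["start"]),
                "end": int(d["end"]),
                "state": CN_FROM_STATE.get(int(d["state"]), int(d["cn"])),
                "numsnp": int(d["numsnp"]),
                "startsnp": d["startsnp"] or "",
                "endsnp": d["endsnp"] or "",
                "dataset": dataset or "",
            })
    if not rows:
        return empty_calls()
    df = pd.DataFrame(rows)
    # state column in the file encodes the HMM state; cn is authoritative
    return df[CALL_COLUMNS]


def write_rawcnv(calls: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in calls.itertuples(index=False):
            cn = int(row.state)
            state = STATE_FROM_CN[cn]
            length = int(row.end) - int(row.start) + 1
            fh.write(
                f"chr{row.chrom}:{int(row.start)}-{int(row.end)} "
                f"numsnp={int(row.numsnp)} length={length:,} "
                f"state{state},cn={cn} {row.sample_id} "
                f"startsnp={getattr(row, 'startsnp', '') or 'NA'} "
                f"endsnp={getattr(row, 'endsnp', '') or 'NA'}\n"
            )


# -- signal tracks (GenomeStudio-like per-sample TSV) -----------------------

def write_signal_tsv(track: pd.DataFrame, sample_id: str, path: str | Path) -> None:
    """Write one sample's signal track: Name, Chr, Position, LRR, BAF columns."""
    out = pd.DataFrame({
        "Name": track["snp_id"],
        "Chr": track["chrom"],
        "Position": track["position"],
        f"{sample_id}.Log R Ratio": track["lrr"],
        f"{sample_id}.B Allele Freq": track["baf"],
    })
    out.to_csv(path, sep="\t", index=False)


def read_signal_tsv(path: str | Path) -> tuple[str, pd.DataFrame]:
    """Read a per-sample signal TSV; returns (sample_id, track)."""
    df = pd.read_csv(path, sep="\t")
    lrr_cols = [c for c in df.columns if c.endswith(".Log R Ratio")]
    baf_cols = [c for c in df.columns if c.endswith(".B Allele Freq")]
    if len(lrr_cols) != 1 or len(baf_cols) != 1:
        raise FormatError(f"{path}: expected exactly one LRR and one BAF column")
    sample_id = lrr_cols[0][: -len(".Log R Ratio")]
    track = pd.DataFrame({
        "snp_id": df["Name"].astype(str),
        "chrom": df["Chr"].astype(str),
        "position": df["Position"].astype("int64"),
        "lrr": df[lrr_cols[0]].astype(float),
        "baf": df[baf_cols[0]].astype(float),
    })
    return sample_id, track


# -- small keyed tables -----------------------------------------------------

def write_genome(genome: GenomeBuild, path: str | Path) -> None:
    pd.DataFrame(genome.chromosomes, columns=["chrom", "length"]).to_csv(
        path, sep="\t", index=False)


def read_genome(path: str | Path) -> GenomeBuild:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "length": "int64"})
    return GenomeBuild(tuple(zip(df["chrom"], df["length"])))


def write_pfb(pfb: pd.Series, path: str | Path) -> None:
    pfb.rename("pfb").rename_axis("snp_id").reset_index().to_csv(
        path, sep="\t", index=False)


def read_pfb(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    return pd.Series(df["pfb"].values, index=df["snp_id"].values, name="pfb")


def write_gcmodel(gc: pd.Series, path: str | Path) -> None:
    gc.rename("gc").rename_axis("snp_id").reset_index().to_csv(
        path, sep="\t", index=False)


def read_gcmodel(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    return pd.Series(df["gc"].values, index=df["snp_id"].values, name="gc")


# -- annotations ------------------------------------------------------------

def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene models (one 'gene' feature per record) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            attrs = f"ID=gene:{row.id};Name={row.id}"
            biotype = getattr(row, "biotype", None)
            if biotype:
                attrs += f";biotype={biotype}"
            fh.write(
                f"{row.chrom}\tcnvrkit\tgene\t{int(row.start)}\t{int(row.end)}"
                f"\t.\t+\t.\t{attrs}\n"
            )


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Read gene features from a GFF3 file into (chrom, start, end, id, biotype)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            gid = attrs.get("ID", f"gene{lineno}")
            gid = gid.split(":", 1)[-1]
            rows.append({
                "chrom": parts[0], "start": int(parts[3]), "end": int(parts[4]),
                "id": gid, "biotype": attrs.get("biotype", ""),
            })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "id", "biotype"])


def write_qtls(qtls: pd.DataFrame, path: str | Path) -> None:
    qtls[["chrom", "start", "end", "qtl_id", "trait", "qtl_type"]].to_csv(
        path, sep="\t", index=False)


def read_qtls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={
        "chrom": str, "qtl_id": str, "trait": str, "qtl_type": str})


def write_bed(intervals: pd.DataFrame, path: str | Path,
              name_col: str = "id") -> None:
    """Write 1-based inclusive intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            name = getattr(row, name_col, ".")
            fh.write(f"{row.chrom}\t{int(row.start) - 1}\t{int(row.end)}\t{name}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED into 1-based inclusive (chrom, start, end, id)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            rows.append({
                "chrom": parts[0], "start": int(parts[1]) + 1,
                "end": int(parts[2]),
                "id": parts[3] if len(parts) > 3 else f"iv{lineno}",
            })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "id"])


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
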