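"""Readers and writers for the pipeline's text formats.

Everything is plain TSV/BED. BED is 0-based half-open; interaction rows
carry fragment coordinates (not ids) so files are portable across fragment
maps, and are resolved against a FragmentMap at load time. Malformed rows
raise with the offending line number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genome import AnnotationSet, FragmentMap, GeneModel, GenomicInterval, Interaction

INTERACTION_COLUMNS = [
    "bait_chrom", "bait_start", "bait_end", "bait_gene",
    "oe_chrom", "oe_start", "oe_end", "score",
]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tss"]


def _check_bed_frame(df: pd.DataFrame, path: str | Path) -> None:
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        # +2: header-less BED, report 1-based file line
        raise ValueError(f"{path}: end <= start at line {bad[0] + 1}")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name"][: 4])
    if df["start"].isna().any() or df["end"].isna().any():
        line = int(df.index[df["start"].isna() | df["end"].isna()][0]) + 1
        raise ValueError(f"{path}: malformed BED line {line}")
    _check_bed_frame(df, path)
    return [GenomicInterval(str(r.chrom), int(r.start), int(r.end))
            for r in df.itertuples()]


def write_bed(path: str | Path, intervals: list[GenomicInterval],
              names: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = f"\t{names[i]}" if names is not None else ""
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}{name}\n")


def read_annotation_bed(path: str | Path, name: str) -> AnnotationSet:
    return AnnotationSet(name, read_bed(path))


def write_fragment_map(path: str | Path, fragments: FragmentMap) -> None:
    with open(path, "w") as fh:
        for fid, iv in fragments.intervals_in_order():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tF{fid}\n")


def read_fragment_map(path: str | Path) -> FragmentMap:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name"])
    _check_bed_frame(df, path)
    ids = [int(str(n)[1:]) for n in df["name"]]
    intervals = [GenomicInterval(str(r.chrom), int(r.start), int(r.end))
                 for r in df.itertuples()]
    return FragmentMap(intervals, ids)


def write_interactions(path: str | Path, interactions: list[Interaction],
                       fragments: FragmentMap,
                       bait_genes: dict[int, str] | None = None) -> None:
    rows = []
    for ia in interactions:
        b = fragments.fragment(ia.bait_fragment_id)
        o = fragments.fragment(ia.other_end_fragment_id)
        gene = (bait_genes or {}).get(ia.bait_fragment_id, ".")
        rows.append((b.chrom, b.start, b.end, gene, o.chrom, o.start, o.end, ia.score))
    pd.DataFrame(rows, columns=INTERACTION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_interactions(path: str | Path, fragments: FragmentMap,
                      score_min: float = 5.0) -> list[Interaction]:
    """Load interaction calls, resolving endpoints to fragment ids.

    Rows scoring below ``score_min`` (the interaction caller's significance
    threshold) are dropped. An endpoint that does not match a fragment of
    the map exactly is an error naming the offending coordinates.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(INTERACTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: list[Interaction] = []
    for i, r in enumerate(df.itertuples(), start=2):
        if float(r.score) < score_min:
            continue
        bait = fragments.assign(str(r.bait_chrom), int(r.bait_start))
        oe = fragments.assign(str(r.oe_chrom), int(r.oe_start))
        for fid, chrom, start, end in ((bait, r.bait_chrom, r.bait_start, r.bait_end),
                                       (oe, r.oe_chrom, r.oe_start, r.oe_end)):
            if fid is None or fragments.fragment(fid).end != int(end):
                raise ValueError(
                    f"{path} line {i}: no fragment matches {chrom}:{start}-{end}"
                )
        out.append(Interaction(bait, oe, float(r.score)))
    return out


def write_genes(path: str | Path, genes: list[GeneModel]) -> None:
    rows = [(g.gene_id, g.body.chrom, g.body.start, g.body.end, g.strand, g.tss)
            for g in genes]
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_genes(path: str | Path,
               fragments: FragmentMap | None = None) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        GeneModel.from_coords(str(r.gene_id), str(r.chrom), int(r.start), int(r.end),
                              str(r.strand), tss=int(r.tss), fragment_map=fragments)
        for r in df.itertuples()
    ]


# --- matrices and tables -------------------------------------------------

def write_matrix(path: str | Path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t", index_label=matrix.index.name or "id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
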