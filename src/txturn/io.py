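"""Readers and writers for the package's plain-text interchange formats.

BED (intervals, fragments, window grids, masks), TSV (count and presence
matrices, curves, enrichment tables), Newick (trees, via scikit-bio) and
JSON/YAML (fits, truth, configuration, manifests).  All coordinates are
0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .windows import CommonGenomeMask, CountMatrix


class BedParseError(ValueError):
    pass


def read_bed(path, n_fields: int = 3) -> pd.DataFrame:
    """Read a BED3(+1) file into a sorted interval DataFrame.

    The optional fourth column is returned as ``name`` (used as sample_id
    for fragment tables).  Malformed lines raise BedParseError naming the
    line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < n_fields:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= {n_fields} fields, "
                    f"got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer "
                                    f"coordinates: {line!r}") from exc
            if start < 0 or start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})")
            row = {"chrom": parts[0], "start": start, "end": end}
            if len(parts) > 3:
                row["name"] = parts[3]
            rows.append(row)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]
                      if rows and "name" in rows[0] else
                      ["chrom", "start", "end"])
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def read_fragments(path) -> pd.DataFrame:
    """BED3+1 fragment table; the name column is the sample id."""
    df = read_bed(path, n_fields=4)
    if "name" not in df.columns:
        raise BedParseError(f"{path}: fragment BED needs a 4th (sample_id) column")
    return df.rename(columns={"name": "sample_id"})


def write_bed(df: pd.DataFrame, path, name_col: str | None = None) -> None:
    cols = ["chrom", "start", "end"]
    out = df[cols].copy()
    if name_col is not None and name_col in df.columns:
        out["name"] = df[name_col]
    out.to_csv(path, sep="\t", header=False, index=False)


def write_windows(windows: pd.DataFrame, path) -> None:
    write_bed(windows, path, name_col="index")


def write_mask(mask: CommonGenomeMask, windows: pd.DataFrame, path) -> None:
    out = windows[["chrom", "start", "end"]].copy()
    out["name"] = mask.mask.astype(int)
    out.to_csv(path, sep="\t", header=False, index=False)


def write_count_matrix(counts: CountMatrix, path, meta_path=None) -> None:
    counts.counts.to_csv(path, sep="\t", index_label="window")
    if meta_path is not None:
        counts.samples.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_count_matrix(path, meta_path=None) -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col="window")
    if meta_path is not None:
        samples = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    else:
        samples = pd.DataFrame(
            {"taxon": counts.columns, "tissue": "NA", "replicate": 0},
            index=pd.Index(counts.columns, name="sample_id"))
    return CountMatrix(counts=counts.astype(np.int64), samples=samples)


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path, index_label: str = "id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_newick(tree: TreeNode, path) -> None:
    with open(path, "w") as fh:
        tree.write(fh, format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick", convert_underscores=False)


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
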