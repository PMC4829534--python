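"""Fixed genomic window grids, fragment counting, common-genome masks and
depth normalization.

The unit of analysis throughout the package is a fixed, non-overlapping
200-bp window of the reference genome.  Aligned sequencing fragments (one
interval per read pair) are assigned to exactly one window each, giving a
windows x samples count matrix.  A "common genome" mask restricts analysis
to windows detectably covered by genomic reads in every designated taxon,
so that absence of transcription is distinguishable from absence of the
locus.  Samples are brought to equal depth by subsampling fragments without
replacement.

Coordinates are 0-based, half-open (BED convention) everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WINDOW_COLUMNS = ["chrom", "start", "end", "index"]


@dataclass
class CountMatrix:
    """Windows x samples fragment counts with sample metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts; rows indexed by window index, one
        column per sample id.
    samples : pandas.DataFrame
        One row per sample (index = sample id) with columns ``taxon``,
        ``tissue`` and ``replicate``.  Extra columns are preserved.
    dropped : dict
        Per-sample tally of input fragments that fell outside the window
        grid and were not counted.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    dropped: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("count matrix contains negative entries")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples metadata missing for: {sorted(missing)}")

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def taxa(self) -> list:
        """Distinct taxon codes in column order of first appearance."""
        seen: list = []
        for s in self.counts.columns:
            t = self.samples.loc[s, "taxon"]
            if t not in seen:
                seen.append(t)
        return seen

    def aggregate_taxa(self, tissue: str | None = None) -> pd.DataFrame:
        """Sum sample columns per taxon (optionally restricted to one tissue).

        Returns a windows x taxa DataFrame.  Combining tissues before
        thresholding is the default aggregation for sharing analyses.
        """
        sub = self.samples
        if tissue is not None:
            sub = sub[sub["tissue"] == tissue]
            if sub.empty:
                raise ValueError(f"no samples with tissue {tissue!r}")
        out = {}
        for taxon, grp in sub.groupby("taxon", sort=False):
            cols = [s for s in self.counts.columns if s in grp.index]
            out[taxon] = self.counts[cols].sum(axis=1)
        return pd.DataFrame(out, index=self.counts.index)


@dataclass
class CommonGenomeMask:
    """Boolean per-window mask with its provenance (taxa and threshold)."""

    mask: np.ndarray
    required_taxa: tuple
    min_count: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)


def make_windows(chrom_sizes: dict, window_size: int = 200) -> pd.DataFrame:
    """Tile each chromosome with non-overlapping fixed-size windows.

    Trailing partial windows (< ``window_size`` bp) are dropped so every
    window has the same length and coverage fractions share a uniform
    denominator.

    Returns a DataFrame with columns chrom, start, end, index; sorted by
    (chrom, start) with contiguous indices from 0.
    """
    if window_size < 1:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    rows = []
    for chrom in sorted(chrom_sizes):
        length = int(chrom_sizes[chrom])
        if length < 0:
            raise ValueError(f"negative length for {chrom}")
        n = length // window_size
        if n:
            starts = np.arange(n, dtype=np.int64) * window_size
            rows.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": starts + window_size}
                )
            )
    if not rows:
        return pd.DataFrame(columns=WINDOW_COLUMNS).astype(
            {"start": np.int64, "end": np.int64, "index": np.int64}
        )
    windows = pd.concat(rows, ignore_index=True)
    windows["index"] = np.arange(len(windows), dtype=np.int64)
    return windows


def _window_size_of(windows: pd.DataFrame) -> int:
    sizes = (windows["end"] - windows["start"]).unique()
    if len(sizes) != 1:
        raise ValueError("window grid is not uniform")
    return int(sizes[0])


def assign_windows(fragments: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """Map each fragment to the window holding the majority of its span.

    Implemented as midpoint containment: the window containing the fragment
    midpoint holds at least half the fragment for any span, and exactly the
    strict majority for a fragment overlapping two windows.  Returns the
    window index per fragment, or -1 for fragments outside the grid
    (unknown chromosome or midpoint beyond the tiled region).
    """
    if (fragments["start"] >= fragments["end"]).any():
        bad = fragments.index[fragments["start"] >= fragments["end"]][0]
        raise ValueError(f"malformed interval at record {bad}: start >= end")
    wsize = _window_size_of(windows)
    # per-chromosome window index offset and window count
    chrom_info = (
        windows.groupby("chrom", sort=False)
        .agg(offset=("index", "min"), n=("index", "size"))
    )
    mid = (fragments["start"].to_numpy() + fragments["end"].to_numpy()) // 2
    out = np.full(len(fragments), -1, dtype=np.int64)
    chroms = fragments["chrom"].to_numpy()
    for chrom, info in chrom_info.iterrows():
        sel = chroms == chrom
        if not sel.any():
            continue
        w = mid[sel] // wsize
        ok = (w >= 0) & (w < info["n"])
        idx = np.where(ok, w + info["offset"], -1)
        out[sel] = idx
    return out


def count_fragments(fragments: pd.DataFrame, windows: pd.DataFrame,
                    samples: pd.DataFrame | None = None) -> CountMatrix:
    """Count fragments per window per sample.

    ``fragments`` needs columns chrom, start, end, sample_id.  Each fragment
    increments exactly one window (midpoint rule); fragments wholly outside
    the grid are dropped and tallied per sample in ``CountMatrix.dropped``.
    """
    required = {"chrom", "start", "end", "sample_id"}
    if not required.issubset(fragments.columns):
        raise ValueError(f"fragment table needs columns {sorted(required)}")
    n_windows = len(windows)
    sample_ids = list(pd.unique(fragments["sample_id"]))
    if samples is not None:
        for s in sample_ids:
            if s not in samples.index:
                raise ValueError(f"sample {s!r} missing from metadata")
        sample_ids = [s for s in samples.index]  # keep metadata order
    counts = pd.DataFrame(
        np.zeros((n_windows, len(sample_ids)), dtype=np.int64),
        index=windows["index"].to_numpy() if n_windows else [],
        columns=sample_ids,
    )
    dropped: dict = {s: 0 for s in sample_ids}
    if len(fragments):
        fragments = fragments.reset_index(drop=True)
        widx = assign_windows(fragments, windows)
        for s, grp_idx in fragments.groupby("sample_id", sort=False).groups.items():
            w = widx[np.asarray(grp_idx)]
            dropped[s] = int((w == -1).sum())
            w = w[w >= 0]
            if len(w):
                binc = np.bincount(w, minlength=n_windows)
                counts[s] += binc
    if samples is None:
        samples = pd.DataFrame(
            {"taxon": sample_ids, "tissue": "NA", "replicate": 0},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    return CountMatrix(counts=counts, samples=samples, dropped=dropped)


def common_genome_mask(genomic_counts: CountMatrix, required_taxa,
                       min_count: int = 1) -> CommonGenomeMask:
    """Windows covered by >= ``min_count`` genomic fragments in every
    required taxon.

    An empty ``required_taxa`` leaves every window in the mask (vacuous
    condition).
    """
    required_taxa = tuple(required_taxa)
    per_taxon = genomic_counts.aggregate_taxa()
    for t in required_taxa:
        if t not in per_taxon.columns:
            raise ValueError(f"required taxon {t!r} has no genomic counts")
    mask = np.ones(genomic_counts.n_windows, dtype=bool)
    for t in required_taxa:
        mask &= per_taxon[t].to_numpy() >= min_count
    return CommonGenomeMask(mask=mask, required_taxa=required_taxa,
                            min_count=min_count)


def normalize_by_subsampling(counts: CountMatrix, target_total: int,
                             seed: int) -> CountMatrix:
    """Subsample each sample column to exactly ``target_total`` fragments.

    Fragments (not windows) are drawn without replacement, i.e. each new
    column is a multivariate-hypergeometric draw from the old one, matching
    per-file read subsampling.  Reproducible given the seed.
    """
    rng = np.random.default_rng(seed)
    new = {}
    for s in counts.counts.columns:
        col = counts.counts[s].to_numpy()
        total = int(col.sum())
        if target_total > total:
            raise ValueError(
                f"sample {s!r}: target {target_total} exceeds available {total}"
            )
        if target_total == total:
            new[s] = col.copy()
        else:
            new[s] = rng.multivariate_hypergeometric(col, target_total)
    out = pd.DataFrame(new, index=counts.counts.index)
    return CountMatrix(counts=out, samples=counts.samples.copy(),
                       dropped=dict(counts.dropped))
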