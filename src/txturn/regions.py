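"""Run-length structure of transcribed vs non-transcribed genome, and
permutation-based enrichment of annotation features in window classes.

Run lengths: consecutive common-genome windows in the same presence state
(union across taxa) form runs; runs break at mask gaps and chromosome
boundaries.  The maximum non-transcribed run is the largest "transcriptional
desert" in the common genome.

Enrichment: annotated feature intervals (genes/exons/introns, coding or
non-coding) are shuffled uniformly along the genome — preserving chromosome
and length — and the observed bp overlap with a target window class is
compared to the shuffle null.  Empirical two-sided p-values carry the +1
correction; Benjamini-Hochberg controls the FDR across the whole
feature x target family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .windows import CommonGenomeMask


@dataclass
class RunLengthDistribution:
    runs: pd.DataFrame  # chrom, start, end, state, length_bp, n_windows
    window_size: int

    def lengths(self, state: str) -> np.ndarray:
        return self.runs.loc[self.runs["state"] == state, "length_bp"].to_numpy()

    def max_length(self, state: str) -> int:
        arr = self.lengths(state)
        return int(arr.max()) if len(arr) else 0

    def summary(self) -> pd.DataFrame:
        return (self.runs.groupby("state")["length_bp"]
                .agg(["count", "sum", "mean", "median", "max"]))


def run_lengths(union_presence, windows: pd.DataFrame,
                mask: CommonGenomeMask) -> RunLengthDistribution:
    """Maximal runs of equal presence state over consecutive masked windows.

    ``union_presence`` is a 0/1 array or Series over the masked windows (in
    mask order), typically "present in any taxon".  Runs break wherever
    masked windows are not adjacent on the same chromosome (mask gaps,
    chromosome ends).  Lengths are in bp (#windows x window size).
    """
    idx = mask.indices()
    pres = np.asarray(union_presence).astype(bool).ravel()
    if len(pres) != len(idx):
        raise ValueError("union_presence length must match masked window count")
    wsize = int((windows["end"] - windows["start"]).iloc[0]) if len(windows) else 0
    sub = windows.iloc[idx]
    chroms = sub["chrom"].to_numpy()
    starts = sub["start"].to_numpy()
    rows = []
    if len(idx):
        # block break: different chrom or non-adjacent window
        brk = np.zeros(len(idx), dtype=bool)
        brk[0] = True
        brk[1:] = (chroms[1:] != chroms[:-1]) | (starts[1:] != starts[:-1] + wsize)
        block_id = np.cumsum(brk)
        state_change = np.zeros(len(idx), dtype=bool)
        state_change[0] = True
        state_change[1:] = pres[1:] != pres[:-1]
        run_id = np.cumsum(brk | state_change)
        df = pd.DataFrame({"run": run_id, "block": block_id, "chrom": chroms,
                           "start": starts, "present": pres})
        for _, g in df.groupby("run", sort=True):
            nwin = len(g)
            rows.append({
                "chrom": g["chrom"].iloc[0],
                "start": int(g["start"].iloc[0]),
                "end": int(g["start"].iloc[-1]) + wsize,
                "state": "transcribed" if g["present"].iloc[0] else "non-transcribed",
                "length_bp": nwin * wsize,
                "n_windows": nwin,
            })
    runs = pd.DataFrame(rows, columns=["chrom", "start", "end", "state",
                                       "length_bp", "n_windows"])
    return RunLengthDistribution(runs=runs, window_size=wsize)


# ---------------------------------------------------------------------------
# interval arithmetic helpers (merged intervals + prefix-sum overlap)

def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals per chromosome."""
    out = []
    for chrom, g in df.groupby("chrom", sort=True):
        g = g.sort_values("start")
        s = g["start"].to_numpy()
        e = g["end"].to_numpy()
        cur_s, cur_e = s[0], e[0]
        for i in range(1, len(s)):
            if s[i] <= cur_e:
                cur_e = max(cur_e, e[i])
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s[i], e[i]
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


class _OverlapIndex:
    """Prefix-sum index over merged intervals for O(log n) bp-overlap
    queries."""

    def __init__(self, targets: pd.DataFrame):
        merged = merge_intervals(targets) if len(targets) else targets
        self.by_chrom: dict = {}
        for chrom, g in merged.groupby("chrom", sort=True):
            s = g["start"].to_numpy(dtype=np.int64)
            e = g["end"].to_numpy(dtype=np.int64)
            prefix = np.concatenate([[0], np.cumsum(e - s)])
            self.by_chrom[chrom] = (s, e, prefix)

    def _cum(self, chrom, pos):
        """Total target bp in [0, pos) on chrom (vectorized over pos)."""
        s, e, prefix = self.by_chrom[chrom]
        pos = np.asarray(pos, dtype=np.int64)
        k = np.searchsorted(s, pos, side="left")  # intervals starting < pos
        base = prefix[k]
        # the last started interval may extend past pos: subtract overshoot
        last = np.maximum(k - 1, 0)
        over = np.where(k > 0, np.maximum(0, e[last] - pos), 0)
        return base - over

    def overlap(self, chrom, starts, ends) -> np.ndarray:
        if chrom not in self.by_chrom:
            return np.zeros(len(np.atleast_1d(starts)), dtype=np.int64)
        return self._cum(chrom, ends) - self._cum(chrom, starts)


def total_overlap(features: pd.DataFrame, index: _OverlapIndex) -> int:
    tot = 0
    for chrom, g in features.groupby("chrom", sort=False):
        tot += int(index.overlap(chrom, g["start"].to_numpy(),
                                 g["end"].to_numpy()).sum())
    return tot


@dataclass
class EnrichmentResult:
    feature_class: str
    target_class: str
    observed_bp: int
    expected_mean: float
    expected_sd: float
    ratio: float
    p_value: float
    q_value: float = np.nan
    significant: bool = False
    within_bias_band: bool | None = None
    n_shuffles: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "feature_class", "target_class", "observed_bp", "expected_mean",
            "expected_sd", "ratio", "p_value", "q_value", "significant",
            "within_bias_band", "n_shuffles")}


def shuffle_enrichment(features: pd.DataFrame, targets: pd.DataFrame,
                       chrom_sizes: dict, n_shuffles: int = 1000,
                       seed: int = 0, feature_class: str = "features",
                       target_class: str = "targets") -> EnrichmentResult:
    """Permutation test of feature/target bp overlap against uniform
    placement.

    Each shuffle relocates every feature to a uniform random start on its
    own chromosome, preserving its length (shuffled features may overlap
    each other).  Two-sided empirical p with add-one correction:
    p = (1 + #{more extreme nulls}) / (n_shuffles + 1), where "more
    extreme" is min(#{null >= obs}, #{null <= obs}) doubled and capped
    at 1.
    """
    if len(features) == 0:
        raise ValueError("empty feature set")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    index = _OverlapIndex(targets)
    observed = total_overlap(features, index)
    lengths = (features["end"] - features["start"]).to_numpy(dtype=np.int64)
    chroms = features["chrom"].to_numpy()
    max_start = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64) - lengths
    if (max_start < 0).any():
        bad = features.iloc[int(np.argmin(max_start))]
        raise ValueError(f"feature longer than its chromosome: {bad['chrom']}")
    null = np.empty(n_shuffles, dtype=np.int64)
    uniq = pd.unique(chroms)
    sel_by_chrom = {c: np.flatnonzero(chroms == c) for c in uniq}
    for b in range(n_shuffles):
        starts = (rng.random(len(lengths)) * (max_start + 1)).astype(np.int64)
        tot = 0
        for c in uniq:
            sel = sel_by_chrom[c]
            tot += int(index.overlap(c, starts[sel], starts[sel] + lengths[sel]).sum())
        null[b] = tot
    n_ge = int((null >= observed).sum())
    n_le = int((null <= observed).sum())
    p = min(1.0, 2.0 * (1 + min(n_ge, n_le)) / (n_shuffles + 1))
    p = max(p, 1.0 / (n_shuffles + 1))
    exp_mean = float(null.mean())
    ratio = observed / exp_mean if exp_mean > 0 else np.inf
    return EnrichmentResult(
        feature_class=feature_class, target_class=target_class,
        observed_bp=observed, expected_mean=exp_mean,
        expected_sd=float(null.std(ddof=0)), ratio=float(ratio),
        p_value=float(p), n_shuffles=n_shuffles,
    )


def enrichment_family(feature_sets: dict, target_sets: dict,
                      chrom_sizes: dict, n_shuffles: int = 1000,
                      seed: int = 0, fdr: float = 0.05,
                      bias_band: tuple | None = None) -> pd.DataFrame:
    """Run the full feature-class x target-class enrichment family with one
    BH correction and optional method-bias flagging."""
    rng = np.random.default_rng(seed)
    results = []
    for fname, feats in feature_sets.items():
        for tname, targs in target_sets.items():
            res = shuffle_enrichment(
                feats, targs, chrom_sizes, n_shuffles=n_shuffles,
                seed=int(rng.integers(2**31)), feature_class=fname,
                target_class=tname)
            results.append(res)
    pvals = [r.p_value for r in results]
    reject, qvals, *_ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    for r, q, rej in zip(results, qvals, reject):
        r.q_value = float(q)
        r.significant = bool(rej)
        if bias_band is not None:
            lo, hi = bias_band
            r.within_bias_band = bool(lo <= r.ratio <= hi)
    return pd.DataFrame([r.to_dict() for r in results])


def method_bias_band(feature_sets: dict, total_transcription: pd.DataFrame,
                     chrom_sizes: dict, n_shuffles: int = 1000,
                     seed: int = 0) -> tuple:
    """Observed/expected ratio band of each feature class against total
    transcription across all taxa.

    Since most annotations fall inside transcription somewhere in the taxon
    set, these ratios estimate how far from 1 the shuffling procedure
    itself can drift; downstream ratios inside the band cannot be
    distinguished from method bias.
    """
    rng = np.random.default_rng(seed)
    ratios = []
    for fname, feats in feature_sets.items():
        res = shuffle_enrichment(feats, total_transcription, chrom_sizes,
                                 n_shuffles=n_shuffles,
                                 seed=int(rng.integers(2**31)),
                                 feature_class=fname,
                                 target_class="total_transcription")
        ratios.append(res.ratio)
    return (float(min(ratios)), float(max(ratios)))


def windows_to_intervals(windows: pd.DataFrame, which: np.ndarray
                         ) -> pd.DataFrame:
    """BED-style intervals for a boolean/index selection of windows,
    merged where adjacent."""
    sel = windows.iloc[np.flatnonzero(which)] if np.asarray(which).dtype == bool \
        else windows[windows["index"].isin(which)]
    if sel.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return merge_intervals(sel[["chrom", "start", "end"]])
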