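"""Exome copy-number profiling from tumor/normal window counts.

Follows the aCGH-like approach of building fixed-read-count windows from a
reference alignment, taking log2 tumor/reference count ratios (with a
pseudo-normal reference assembled from unmatched normals when no matched
normal exists), segmenting each chromosome with a recursive binary-split
changepoint search validated by permutation, and thresholding segment
means into gain/loss/neutral calls per gene and across the cohort.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import GeneModel, Segment

logger = logging.getLogger(__name__)

#: conventional log2-ratio thresholds; the underlying study states none
GAIN_THRESHOLD = 0.3
LOSS_THRESHOLD = -0.3
FLOOR_OFFSET = 0.5  # count floor c in log2((t+c)/(r+c))


@dataclass
class CopyRatioProfile:
    """Windowed tumor-vs-reference log2 ratios for one sample."""

    sample_id: str
    windows: pd.DataFrame  # chrom, start, end, tumor, ref, log2
    reference_kind: str = "matched_normal"  # or pseudo_normal

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "tumor", "ref", "log2"}
        missing = required - set(self.windows.columns)
        if missing:
            raise ValueError(f"profile missing columns {sorted(missing)}")
        if not np.isfinite(self.windows["log2"]).all():
            raise ValueError("log2 ratios must be finite")


def make_windows(
    read_starts: Mapping[str, Sequence[int]],
    reads_per_window: int = 1000,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Fixed-read-count window boundaries from reference read starts.

    Every window except the last on each chromosome holds exactly
    ``reads_per_window`` reference reads — extended past ties, since a
    boundary cannot split reads sharing a start coordinate; boundaries
    never cross a chromosome.  A chromosome with fewer reads than one
    window becomes a single whole-chromosome window with a warning.
    """
    if reads_per_window < 50:
        raise ValueError("reads_per_window must be >= 50")
    rows = []
    for chrom, starts in read_starts.items():
        pos = np.sort(np.asarray(starts, dtype=np.int64))
        length = (
            chrom_lengths[chrom]
            if chrom_lengths is not None
            else (int(pos[-1]) if len(pos) else 1)
        )
        if len(pos) < reads_per_window:
            warnings.warn(
                f"{chrom}: fewer than {reads_per_window} reads; single "
                "whole-chromosome window"
            )
            rows.append((chrom, 1, length, len(pos)))
            continue
        bounds = []  # read indices at which a new window starts
        b = 0
        while True:
            nb = b + reads_per_window
            if nb >= len(pos):
                break
            while nb < len(pos) and pos[nb] == pos[nb - 1]:
                nb += 1  # never split reads tied on the boundary coordinate
            if nb >= len(pos):
                break
            bounds.append(nb)
            b = nb
        edges = [0] + bounds + [len(pos)]
        start = 1
        for w in range(len(edges) - 1):
            terminal = w == len(edges) - 2
            end = length if terminal else int(pos[edges[w + 1] - 1])
            rows.append((chrom, start, max(end, start),
                         edges[w + 1] - edges[w]))
            start = max(end, start) + 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_reads"])


def build_pseudo_normal(
    normal_counts: Sequence[np.ndarray] | pd.DataFrame,
) -> np.ndarray:
    """Reference counts from >= 1 normal profiles on identical windows:
    the per-window median of library-size-normalized counts, rescaled to
    the mean library size.  A single normal passes through unchanged."""
    if isinstance(normal_counts, pd.DataFrame):
        mat = normal_counts.to_numpy(dtype=float)
    else:
        arrays = [np.asarray(a, dtype=float) for a in normal_counts]
        if not arrays:
            raise ValueError("need at least one normal profile")
        n = len(arrays[0])
        if any(len(a) != n for a in arrays):
            raise ValueError("normal profiles have mismatched window sets")
        mat = np.column_stack(arrays)
    if mat.ndim != 2 or mat.shape[1] < 1:
        raise ValueError("need at least one normal profile")
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("normal profile with zero total counts")
    normalized = mat / lib
    median = np.median(normalized, axis=1)
    return median * lib.mean()


def compute_log2_ratio(
    tumor_counts: Sequence[float],
    ref_counts: Sequence[float],
    windows: pd.DataFrame,
    sample_id: str = "tumor",
    reference_kind: str = "matched_normal",
    floor_offset: float = FLOOR_OFFSET,
) -> CopyRatioProfile:
    """Median-centered log2((tumor + c)/(ref + c)) per window.

    Median-centering makes the profile invariant to library-size
    differences under the assumption that most of the genome is copy-
    neutral.
    """
    t = np.asarray(tumor_counts, dtype=float)
    r = np.asarray(ref_counts, dtype=float)
    if len(t) != len(r) or len(t) != len(windows):
        raise ValueError("tumor, reference and windows must align")
    if t.sum() == 0:
        raise ValueError("all-zero tumor counts")
    log2 = np.log2((t + floor_offset) / (r + floor_offset))
    log2 = log2 - np.median(log2)
    df = windows[["chrom", "start", "end"]].copy()
    df["tumor"] = t
    df["ref"] = r
    df["log2"] = log2
    return CopyRatioProfile(
        sample_id=sample_id, windows=df, reference_kind=reference_kind
    )


# ---------------------------------------------------------------------------
# Segmentation

def _best_split(values: np.ndarray) -> tuple[int, float]:
    """Best interior split of ``values`` by the two-sample t statistic.

    Returns (split index i giving left=values[:i], right=values[i:],
    t statistic); leftmost maximum on ties.
    """
    n = len(values)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    csq = np.concatenate([[0.0], np.cumsum(values**2)])
    i = np.arange(1, n)
    n_l, n_r = i, n - i
    mean_l = csum[i] / n_l
    mean_r = (csum[n] - csum[i]) / n_r
    ss_l = csq[i] - n_l * mean_l**2
    ss_r = (csq[n] - csq[i]) - n_r * mean_r**2
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = (ss_l + ss_r) / np.maximum(n - 2, 1)
        se = np.sqrt(pooled * (1.0 / n_l + 1.0 / n_r))
        t = np.abs(mean_l - mean_r) / se
    t = np.where(np.isfinite(t), t, np.where(mean_l != mean_r, np.inf, 0.0))
    best = int(np.argmax(t))
    return best + 1, float(t[best])


def _permutation_p(
    values: np.ndarray, observed_t: float, n_perm: int, rng: np.random.Generator
) -> float:
    if not np.isfinite(observed_t):
        return 0.0
    count = 0
    mat = np.tile(values, (n_perm, 1))
    mat = rng.permuted(mat, axis=1)
    for row in mat:
        _, t = _best_split(row)
        if t >= observed_t:
            count += 1
    return (count + 1) / (n_perm + 1)


def segment_profile(
    profile: CopyRatioProfile,
    alpha: float = 0.01,
    min_windows: int = 3,
    n_perm: int = 100,
    perm_seed: int = 13,
    min_gap: float = 0.1,
    gain_thresh: float = GAIN_THRESHOLD,
    loss_thresh: float = LOSS_THRESHOLD,
) -> list[Segment]:
    """Segment each chromosome by recursive binary splitting.

    At each step the boundary maximizing the two-sample t statistic is
    proposed and accepted iff its fixed-seed permutation p-value is below
    ``alpha``; accepted splits recurse into both halves.  Adjacent
    segments whose means differ by less than ``min_gap`` are merged.
    Segment means are thresholded into gain/loss/neutral calls.
    """
    rng = np.random.default_rng(perm_seed)
    segments: list[Segment] = []
    for chrom, sub in profile.windows.groupby("chrom", sort=False):
        values = sub["log2"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        bounds = _segment_recursive(values, 0, len(values), alpha,
                                    min_windows, n_perm, rng)
        pieces = _merge_adjacent(values, bounds, min_gap)
        for lo, hi in pieces:
            mean = float(values[lo:hi].mean())
            segments.append(
                Segment(
                    chrom=chrom,
                    start=int(starts[lo]),
                    end=int(ends[hi - 1]),
                    n_windows=hi - lo,
                    mean_log2=mean,
                    call=_call_from_mean(mean, gain_thresh, loss_thresh),
                )
            )
    return segments


def _segment_recursive(
    values: np.ndarray,
    lo: int,
    hi: int,
    alpha: float,
    min_windows: int,
    n_perm: int,
    rng: np.random.Generator,
) -> list[int]:
    """Interior boundary indices (relative to the chromosome) found by
    recursive splitting of values[lo:hi]."""
    if hi - lo < 2 * min_windows:
        return []
    sub = values[lo:hi]
    if np.allclose(sub, sub[0]):
        return []
    split, t = _best_split(sub)
    # keep both halves at least min_windows wide: clamp the proposal
    if split < min_windows or (len(sub) - split) < min_windows:
        candidates = np.arange(min_windows, len(sub) - min_windows + 1)
        if len(candidates) == 0:
            return []
        csum = np.concatenate([[0.0], np.cumsum(sub)])
        means_l = csum[candidates] / candidates
        means_r = (csum[-1] - csum[candidates]) / (len(sub) - candidates)
        split = int(candidates[np.argmax(np.abs(means_l - means_r))])
        _, t = _best_split(sub)  # keep the unconstrained t for testing
    p = _permutation_p(sub, t, n_perm, rng)
    if p >= alpha:
        return []
    cut = lo + split
    return (
        _segment_recursive(values, lo, cut, alpha, min_windows, n_perm, rng)
        + [cut]
        + _segment_recursive(values, cut, hi, alpha, min_windows, n_perm, rng)
    )


def _merge_adjacent(
    values: np.ndarray, bounds: list[int], min_gap: float
) -> list[tuple[int, int]]:
    edges = [0] + sorted(bounds) + [len(values)]
    pieces = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    merged = [pieces[0]]
    for lo, hi in pieces[1:]:
        plo, phi = merged[-1]
        if abs(values[plo:phi].mean() - values[lo:hi].mean()) < min_gap:
            merged[-1] = (plo, hi)
        else:
            merged.append((lo, hi))
    return merged


def _call_from_mean(
    mean: float, gain_thresh: float, loss_thresh: float
) -> str:
    if mean >= gain_thresh:
        return "gain"
    if mean <= loss_thresh:
        return "loss"
    return "neutral"


# ---------------------------------------------------------------------------
# Per-gene and cohort summaries

def call_gene_copy_number(
    segments: Sequence[Segment],
    genes: Sequence[GeneModel],
    gain_thresh: float = GAIN_THRESHOLD,
    loss_thresh: float = LOSS_THRESHOLD,
) -> dict[str, str]:
    """Copy-number call per gene.

    A gene wholly inside one segment takes that segment's call; a gene
    spanning a boundary takes the overlap-length-weighted mean of the
    segment means, re-thresholded.  A gene outside all segments is an
    error.
    """
    if not (gain_thresh > 0 > loss_thresh):
        raise ValueError("need gain_thresh > 0 > loss_thresh")
    calls: dict[str, str] = {}
    for gene in genes:
        overlaps = [
            (max(gene.start, s.start), min(gene.end, s.end), s)
            for s in segments
            if s.chrom == gene.chrom and s.start <= gene.end and s.end >= gene.start
        ]
        if not overlaps:
            raise ValueError(f"gene {gene.gene_id} outside all segments")
        if len(overlaps) == 1:
            calls[gene.gene_id] = overlaps[0][2].call
        else:  # boundary-spanning gene: overlap-length-weighted mean
            w = np.array([hi - lo + 1 for lo, hi, _ in overlaps], float)
            means = np.array([s.mean_log2 for _, _, s in overlaps])
            mean = float((w * means).sum() / w.sum())
            calls[gene.gene_id] = _call_from_mean(mean, gain_thresh,
                                                  loss_thresh)
    return calls


def cohort_frequency(
    sample_calls: Mapping[str, Mapping[str, str]],
) -> pd.DataFrame:
    """Per-locus gain/loss counts across samples.

    ``sample_calls`` maps sample -> locus -> call; loci are gene ids or
    window labels.  Returns a locus-indexed frame with n_gain, n_loss and
    n_total, the input for a cohort CNA-frequency track.
    """
    if not sample_calls:
        raise ValueError("need at least one sample")
    loci: dict[str, list[int]] = {}
    n_total = len(sample_calls)
    all_loci: list[str] = []
    seen = set()
    for calls in sample_calls.values():
        for locus in calls:
            if locus not in seen:
                seen.add(locus)
                all_loci.append(locus)
    rows = []
    for locus in all_loci:
        n_gain = sum(
            1 for calls in sample_calls.values() if calls.get(locus) == "gain"
        )
        n_loss = sum(
            1 for calls in sample_calls.values() if calls.get(locus) == "loss"
        )
        rows.append((locus, n_gain, n_loss, n_total))
    return pd.DataFrame(
        rows, columns=["locus", "n_gain", "n_loss", "n_total"]
    ).set_index("locus")


def window_calls(
    profile: CopyRatioProfile, segments: Sequence[Segment]
) -> pd.DataFrame:
    """Propagate segment calls back onto the profile's windows."""
    df = profile.windows.copy()
    df["call"] = "neutral"
    df["seg_mean"] = np.nan
    for seg in segments:
        mask = (
            (df["chrom"] == seg.chrom)
            & (df["start"] >= seg.start)
            & (df["end"] <= seg.end)
        )
        df.loc[mask, "call"] = seg.call
        df.loc[mask, "seg_mean"] = seg.mean_log2
    return df
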