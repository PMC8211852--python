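"""Insulation-score boundaries, consensus TADs, domain scores and their
group differentials.

Insulation at bin ``i`` is the mean contact value in the w x w square of
upstream bins (i-w .. i-1) against downstream bins (i+1 .. i+w), log2-scaled
to the chromosome mean (window 1 Mb, mean metric). The delta track is the
mean insulation over the left span minus the right span (span 200 kb);
boundaries sit at downward zero crossings of delta whose local amplitude
exceeds the noise threshold (default 0.1).

The domain score of a TAD in one sample is the intra-TAD contact sum divided
by the sum of all cis contacts with at least one anchor in the TAD, so it
lies in (0, 1] and is invariant under global scaling of the map.

Differential boundaries require a two-sample Welch t-test FDR < 0.01 and a
group-mean difference above the median of all boundaries' absolute
differences; differential domain scores additionally require the absolute
log2 fold change to exceed its 70% quantile across TADs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ContactMatrix

__all__ = [
    "InsulationTrack",
    "Tad",
    "insulation_track",
    "merge_boundaries",
    "differential_boundaries",
    "consensus_tads",
    "domain_score",
    "differential_domain_scores",
]


@dataclass
class InsulationTrack:
    chrom: str
    binsize: int
    insulation: np.ndarray  # log2 ratio to chromosome mean; NaN near ends
    delta: np.ndarray       # left-span minus right-span mean insulation
    boundaries: list[int] = field(default_factory=list)
    strengths: list[float] = field(default_factory=list)
    span_bins: int = 5

    def delta_amplitude(self, b: int) -> float:
        """Local delta amplitude at a bin: max(delta) on the left span minus
        min(delta) on the right span. Used as the per-sample relative
        insulation value when testing boundaries across samples."""
        s = self.span_bins
        lo, hi = max(b - s, 0), min(b + s + 1, len(self.delta))
        left = self.delta[lo : b + 1]
        right = self.delta[b + 1 : hi + 1]
        left = left[~np.isnan(left)]
        right = right[~np.isnan(right)]
        if len(left) == 0 or len(right) == 0:
            return 0.0
        return float(left.max() - right.min())


@dataclass
class Tad:
    chrom: str
    start_bin: int
    end_bin: int  # half-open
    conditions: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.end_bin <= self.start_bin:
            raise ValueError("TAD end must exceed start")


def insulation_track(
    matrix: ContactMatrix,
    chrom: str,
    window: int = 1_000_000,
    delta_span: int = 200_000,
    noise_threshold: float = 0.1,
    balanced: bool = False,
) -> InsulationTrack:
    """Sliding-square insulation with delta-crossing boundary calls."""
    bs = matrix.binsize
    if window % bs or delta_span % bs:
        raise ValueError("window and delta_span must be multiples of the bin size")
    w = window // bs
    s = delta_span // bs
    if w < 2:
        raise ValueError("window must span at least 2 bins")
    dense = matrix.dense(chrom, balanced=balanced)
    if balanced:
        dense = np.nan_to_num(dense, nan=0.0)
    n = dense.shape[0]
    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        raw[i] = dense[i - w : i, i + 1 : i + w + 1].mean()
    ok = ~np.isnan(raw)
    mean = raw[ok].mean() if ok.any() else np.nan
    ins = np.full(n, np.nan)
    if mean and mean > 0:
        with np.errstate(divide="ignore"):
            ins[ok] = np.log2(np.where(raw[ok] > 0, raw[ok] / mean, np.nan))

    delta = np.full(n, np.nan)
    for i in range(n):
        left = ins[max(i - s, 0) : i]
        right = ins[i + 1 : i + 1 + s]
        left = left[~np.isnan(left)]
        right = right[~np.isnan(right)]
        if len(left) and len(right):
            delta[i] = left.mean() - right.mean()

    track = InsulationTrack(chrom, bs, ins, delta, span_bins=s)
    for i in range(n - 1):
        if np.isnan(delta[i]) or np.isnan(delta[i + 1]):
            continue
        if delta[i] > 0 >= delta[i + 1]:  # downward zero crossing
            # boundary at the insulation minimum of the crossing pair
            b = i if (np.isnan(ins[i + 1]) or (not np.isnan(ins[i]) and ins[i] <= ins[i + 1])) else i + 1
            amp = track.delta_amplitude(b)
            if amp > noise_threshold:
                track.boundaries.append(b)
                track.strengths.append(amp)
    return track


def merge_boundaries(tracks: list[InsulationTrack], radius_bins: int = 1) -> list[int]:
    """Pool boundaries across tracks; positions within the radius merge to
    the bin with maximal pooled strength."""
    pooled: dict[int, float] = {}
    for t in tracks:
        for b, s in zip(t.boundaries, t.strengths):
            pooled[b] = pooled.get(b, 0.0) + s
    merged: list[int] = []
    for b in sorted(pooled, key=lambda x: -pooled[x]):
        if all(abs(b - m) > radius_bins for m in merged):
            merged.append(b)
    return sorted(merged)


def differential_boundaries(
    tracks: dict[str, list[InsulationTrack]],
    fdr: float = 0.01,
    diff_quantile: float = 0.5,
) -> pd.DataFrame:
    """Two-group boundary test on per-sample delta amplitudes.

    ``tracks`` maps the two group names to per-sample insulation tracks of
    one chromosome. Returns one row per merged boundary with t-test p,
    BH FDR and the differential flag (FDR < cut AND |mean difference| above
    the quantile of all boundaries' |differences|).
    """
    groups = list(tracks)
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    for g in groups:
        if len(tracks[g]) < 2:
            raise ValueError(f"group {g!r} needs >=2 samples")
    all_tracks = tracks[groups[0]] + tracks[groups[1]]
    merged = merge_boundaries(all_tracks)
    rows = []
    for b in merged:
        v1 = np.array([t.delta_amplitude(b) for t in tracks[groups[0]]])
        v2 = np.array([t.delta_amplitude(b) for t in tracks[groups[1]]])
        if np.allclose(v1, v1[0]) and np.allclose(v2, v2[0]) and np.isclose(v1[0], v2[0]):
            p = 1.0
        else:
            p = float(stats.ttest_ind(v1, v2, equal_var=False).pvalue)
            if np.isnan(p):
                p = 1.0
        rows.append({"chrom": all_tracks[0].chrom, "bin": b,
                     "mean_g1": v1.mean(), "mean_g2": v2.mean(),
                     "difference": v1.mean() - v2.mean(), "p": p})
    table = pd.DataFrame(rows)
    if len(table) == 0:
        table["fdr"] = []
        table["differential"] = []
        return table
    table["fdr"] = multipletests(table["p"], method="fdr_bh")[1]
    cut = table["difference"].abs().quantile(diff_quantile)
    table["differential"] = (table["fdr"] < fdr) & (table["difference"].abs() > cut)
    return table


def consensus_tads(
    boundaries_by_condition: dict[str, list[int]],
    chrom: str,
    n_bins: int,
    min_support: int = 2,
    min_bins: int = 3,
    radius_bins: int = 1,
) -> list[Tad]:
    """TADs delimited by boundaries detected in at least ``min_support``
    conditions; domains shorter than ``min_bins`` are discarded."""
    support: dict[int, set[str]] = {}
    for cond, bounds in boundaries_by_condition.items():
        for b in bounds:
            hit = next((k for k in support if abs(k - b) <= radius_bins), None)
            key = hit if hit is not None else b
            support.setdefault(key, set()).add(cond)
    kept = sorted(b for b, conds in support.items() if len(conds) >= min_support)
    edges = [0] + kept + [n_bins]
    tads = []
    for s, e in zip(edges[:-1], edges[1:]):
        if e - s >= min_bins:
            conds = support.get(s, set()) | support.get(e, set())
            tads.append(Tad(chrom, s, e, conds))
    return tads


def domain_score(matrix: ContactMatrix, chrom: str, tads: list[Tad]) -> np.ndarray:
    """Intra-TAD contact fraction per TAD: intra / (contacts touching the TAD).

    Diagonal included; raw counts by default (the ratio is scale-invariant).
    Returns NaN where the denominator is zero.
    """
    dense = matrix.dense(chrom)
    n = dense.shape[0]
    scores = np.full(len(tads), np.nan)
    for k, tad in enumerate(tads):
        if tad.chrom != chrom or tad.end_bin > n:
            raise ValueError(f"TAD {tad} outside matrix for {chrom}")
        s, e = tad.start_bin, tad.end_bin
        sub = dense[s:e, s:e]
        intra = (sub.sum() + np.trace(sub)) / 2.0  # upper triangle incl. diagonal
        touching = dense[s:e, :].sum() - sub.sum() + intra
        if touching > 0:
            scores[k] = intra / touching
    return scores


def differential_domain_scores(
    scores: pd.DataFrame,
    groups: dict[str, list[str]],
    fdr: float = 0.01,
    fc_quantile: float = 0.7,
) -> pd.DataFrame:
    """Two-group test on a TAD x sample domain-score table.

    ``scores`` columns are sample names (rows: TADs); ``groups`` maps the
    two group names to sample-column lists. The flag requires BH FDR below
    the cut AND |log2 fold change| above the given quantile of all TADs'
    |log2 fold changes|; direction is "increased"/"decreased" for the
    second group relative to the first.
    """
    gnames = list(groups)
    if len(gnames) != 2:
        raise ValueError("need exactly two groups")
    for g in gnames:
        if len(groups[g]) < 2:
            raise ValueError(f"group {g!r} needs >=2 samples")
    v1 = scores[groups[gnames[0]]].to_numpy(dtype=float)
    v2 = scores[groups[gnames[1]]].to_numpy(dtype=float)
    pvals = np.ones(len(scores))
    for i in range(len(scores)):
        a, b = v1[i][~np.isnan(v1[i])], v2[i][~np.isnan(v2[i])]
        if len(a) < 2 or len(b) < 2 or (np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0])):
            continue
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
        pvals[i] = 1.0 if np.isnan(p) else float(p)
    m1 = np.nanmean(v1, axis=1)
    m2 = np.nanmean(v2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(m2 / m1)
    out = pd.DataFrame({
        "mean_g1": m1, "mean_g2": m2, "log2fc": log2fc, "p": pvals,
    }, index=scores.index)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    cut = np.nanquantile(np.abs(out["log2fc"]), fc_quantile)
    out["differential"] = (out["fdr"] < fdr) & (np.abs(out["log2fc"]) > cut)
    out["direction"] = np.where(out["log2fc"] > 0, "increased", "decreased")
    out.loc[~out["differential"], "direction"] = ""
    return out
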