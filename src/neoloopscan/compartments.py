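"""A/B compartment tracks, cross-sample consensus and switch calling.

The per-sample track is the leading eigenvector of the Pearson-correlation
matrix of the observed/expected cis map, computed per chromosome at 100-kb
resolution by default. The eigenvector sign is arbitrary, so each track is
oriented against a per-bin activity proxy (gene density in the synthetic
cohorts): the orientation with positive correlation to the proxy is kept
and positive values are labeled A.

Group consensus follows a strict majority rule: a bin is A (or B) only when
the fraction of samples agreeing strictly exceeds the majority threshold
(default 0.7); everything else is "other" and excluded from switch calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ContactMatrix, expected_by_distance, mask_bins

__all__ = ["CompartmentTrack", "ConsensusCompartment", "compartment_track", "consensus_and_switches"]


@dataclass
class CompartmentTrack:
    chrom: str
    binsize: int
    values: np.ndarray  # NaN on masked bins
    labels: np.ndarray  # 'A' | 'B' | 'masked'

    def __post_init__(self) -> None:
        ok = ~np.isnan(self.values)
        assert np.all((self.values[ok] > 0) == (self.labels[ok] == "A"))


@dataclass
class ConsensusCompartment:
    chrom: str
    binsize: int
    labels: np.ndarray     # 'A' | 'B' | 'other'
    agreement: np.ndarray  # fraction of samples supporting the label


def _oe_correlation(dense: np.ndarray, expected: np.ndarray, valid: np.ndarray) -> np.ndarray:
    n = dense.shape[0]
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    exp_mat = expected[np.minimum(d, len(expected) - 1)]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(exp_mat > 0, dense / exp_mat, 0.0)
    sub = oe[np.ix_(valid, valid)]
    sd = sub.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("degenerate observed/expected map: no variance to correlate")
    corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr, nan=0.0)
    return corr


def compartment_track(
    matrix: ContactMatrix,
    chrom: str,
    reference_track: np.ndarray,
    balanced: bool = True,
) -> CompartmentTrack:
    """Leading-eigenvector compartment track for one chromosome.

    ``reference_track`` is a per-bin activity proxy used only to orient the
    eigenvector sign (positive correlation => positive values are A).
    """
    dense = matrix.dense(chrom, balanced=balanced)
    if balanced:
        valid = ~np.isnan(matrix.weights[chrom])
        dense = np.nan_to_num(dense, nan=0.0)
    else:
        valid = mask_bins(dense)
    if valid.sum() < 10:
        raise ValueError(f"{chrom}: fewer than 10 unmasked bins")
    profile = expected_by_distance(matrix, chrom, balanced=balanced)
    corr = _oe_correlation(dense, profile.values, valid)
    evals, evecs = np.linalg.eigh(corr)
    ev1 = evecs[:, -1]
    ref = np.asarray(reference_track, dtype=float)[valid]
    if len(ref) != len(ev1):
        raise ValueError("reference track does not cover the chromosome grid")
    r = np.corrcoef(ev1, ref)[0, 1]
    if np.isfinite(r) and r < 0:
        ev1 = -ev1
    n = dense.shape[0]
    values = np.full(n, np.nan)
    values[valid] = ev1
    labels = np.full(n, "masked", dtype=object)
    labels[valid] = np.where(ev1 > 0, "A", "B")
    return CompartmentTrack(chrom, matrix.binsize, values, np.asarray(labels))


def _group_consensus(
    tracks: list[CompartmentTrack],
    majority: float,
    max_masked_fraction: float = 0.5,
) -> ConsensusCompartment:
    chrom = tracks[0].chrom
    n = len(tracks[0].values)
    lab = np.stack([t.labels for t in tracks])
    n_samples = len(tracks)
    frac_a = (lab == "A").sum(axis=0) / n_samples
    frac_b = (lab == "B").sum(axis=0) / n_samples
    frac_masked = (lab == "masked").sum(axis=0) / n_samples
    labels = np.full(n, "other", dtype=object)
    agreement = np.maximum(frac_a, frac_b)
    labels[frac_a > majority] = "A"
    labels[frac_b > majority] = "B"
    labels[frac_masked >= max_masked_fraction] = "other"
    return ConsensusCompartment(chrom, tracks[0].binsize, labels, agreement)


def consensus_and_switches(
    tracks_by_group: dict[str, list[CompartmentTrack]],
    majority: float = 0.7,
) -> tuple[dict[str, ConsensusCompartment], pd.DataFrame]:
    """Per-group consensus labels and the A/B switch table between two groups.

    Switches are reported for the first group relative to the second
    (direction "A-to-B" means group1 A, group2 B); bins "other" in either
    group never switch.
    """
    groups = list(tracks_by_group)
    if len(groups) != 2:
        raise ValueError("switch calling requires exactly two groups")
    for g in groups:
        if len(tracks_by_group[g]) < 2:
            raise ValueError(f"group {g!r} needs >=2 samples")
        grids = {(t.chrom, t.binsize, len(t.values)) for t in tracks_by_group[g]}
        if len(grids) != 1:
            raise ValueError(f"group {g!r} tracks are on mismatched bin grids")
    g1, g2 = groups
    grid1 = (tracks_by_group[g1][0].chrom, tracks_by_group[g1][0].binsize, len(tracks_by_group[g1][0].values))
    grid2 = (tracks_by_group[g2][0].chrom, tracks_by_group[g2][0].binsize, len(tracks_by_group[g2][0].values))
    if grid1 != grid2:
        raise ValueError("groups are on mismatched bin grids")
    cons = {g: _group_consensus(tracks_by_group[g], majority) for g in groups}
    l1, l2 = cons[g1].labels, cons[g2].labels
    rows = []
    for b in range(len(l1)):
        if l1[b] in ("A", "B") and l2[b] in ("A", "B") and l1[b] != l2[b]:
            rows.append({"chrom": cons[g1].chrom, "bin": b,
                         "direction": f"{l1[b]}-to-{l2[b]}"})
    switches = pd.DataFrame(rows, columns=["chrom", "bin", "direction"])
    return cons, switches
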