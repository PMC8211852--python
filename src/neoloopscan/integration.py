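"""Integration of structural changes with gene expression.

Virtual 4C extracts one viewpoint row from a depth-normalized contact
matrix (10-kb bins by default); region interaction scores average the
profile over named intervals and are compared between groups. Per-gene
structural change combines the domain-score p and the loop-strength p by
Fisher's method (chi-square, 4 df) and is correlated with expression log
fold change. The DEG association step applies read filters and DE
thresholds (FDR < 0.01, |fold change| > 2), assigns each gene its
overlapping structural events, and tests each structural class against
stable genes with a one-sided Wilcoxon rank-sum test (direction: B-to-A /
increased D-score / enhanced loop classes are tested for up-shift).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ContactMatrix

__all__ = [
    "V4cProfile",
    "virtual_4c",
    "quantify_region_interactions",
    "combined_structural_p",
    "read_filter",
    "associate_degs",
]


@dataclass
class V4cProfile:
    chrom: str
    viewpoint_bin: int
    binsize: int
    values: np.ndarray
    identity: str = ""


def virtual_4c(
    matrices: dict[str, ContactMatrix],
    chrom: str,
    viewpoint: int,  # bp, 1-based
    groups: dict[str, list[str]] | None = None,
) -> tuple[list[V4cProfile], np.ndarray | None]:
    """Viewpoint interaction profiles, optionally with a group difference.

    Each profile is the depth-normalized matrix row at the viewpoint bin.
    With two groups the difference track is group1 mean minus group2 mean.
    """
    from .matrix import cis_depth_normalize

    samples = list(matrices)
    normed = dict(zip(samples, cis_depth_normalize([matrices[s] for s in samples])))
    bs = next(iter(matrices.values())).binsize
    vb = (viewpoint - 1) // bs
    profiles = []
    for s in samples:
        dense = normed[s].dense(chrom)
        if dense[vb].sum() == 0:
            raise ValueError(f"viewpoint bin {vb} is empty/masked in sample {s}")
        profiles.append(V4cProfile(chrom, vb, bs, dense[vb].copy(), identity=s))
    diff = None
    if groups is not None:
        gnames = list(groups)
        if len(gnames) != 2:
            raise ValueError("group difference requires exactly two groups")
        by = {s: p for s, p in zip(samples, profiles)}
        m1 = np.mean([by[s].values for s in groups[gnames[0]]], axis=0)
        m2 = np.mean([by[s].values for s in groups[gnames[1]]], axis=0)
        diff = m1 - m2
    return profiles, diff


def quantify_region_interactions(
    profiles: dict[str, V4cProfile],
    regions: dict[str, tuple[int, int]],  # name -> (start_bp, end_bp), 0-based half-open
    groups: dict[str, list[str]],
) -> pd.DataFrame:
    """Mean viewpoint-interaction score per named region, with group stats."""
    gnames = list(groups)
    if len(gnames) != 2:
        raise ValueError("need exactly two groups")
    bs = next(iter(profiles.values())).binsize
    rows = []
    for name, (start, end) in regions.items():
        b0, b1 = start // bs, -(-end // bs)
        scores = {s: float(np.nanmean(p.values[b0:b1])) for s, p in profiles.items()}
        v1 = np.array([scores[s] for s in groups[gnames[0]]])
        v2 = np.array([scores[s] for s in groups[gnames[1]]])
        if np.allclose(v1, v1[0]) and np.allclose(v2, v2[0]) and np.isclose(v1[0], v2[0]):
            p = 1.0
        else:
            p = float(stats.ttest_ind(v1, v2, equal_var=False).pvalue)
            if np.isnan(p):
                p = 1.0
        rows.append({"region": name, "start": start, "end": end,
                     "mean_g1": v1.mean(), "mean_g2": v2.mean(), "p": p})
    table = pd.DataFrame(rows)
    table["fdr"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


def combined_structural_p(
    dscore_p: pd.Series,
    loop_p: pd.Series,
    expression_logfc: pd.Series | None = None,
    signs: pd.Series | None = None,
    method: str = "fisher",
) -> tuple[pd.DataFrame, float | None]:
    """Fisher (default) or Stouffer combination of per-gene structural p.

    Missing components pass the other through. The signed structural score
    is ``-log10(combined p)`` times the dominant structural direction sign
    (``signs``: +1 up-structure, -1 down). Returns the per-gene table and,
    when expression log fold changes are supplied, the Pearson correlation
    between the signed score and the logFC.
    """
    genes = dscore_p.index.union(loop_p.index)
    d = dscore_p.reindex(genes)
    l = loop_p.reindex(genes)
    for series in (d, l):
        bad = series.dropna()
        if ((bad <= 0) | (bad > 1)).any():
            raise ValueError("p values must lie in (0, 1]")
    combined = pd.Series(index=genes, dtype=float)
    for g in genes:
        ps = [x for x in (d[g], l[g]) if pd.notna(x)]
        if not ps:
            combined[g] = np.nan
        elif len(ps) == 1:
            combined[g] = ps[0]
        elif method == "fisher":
            chi2 = -2.0 * np.sum(np.log(ps))
            combined[g] = float(stats.chi2.sf(chi2, df=2 * len(ps)))
        elif method == "stouffer":
            z = np.sum(stats.norm.isf(ps)) / np.sqrt(len(ps))
            combined[g] = float(stats.norm.sf(z))
        else:
            raise ValueError(f"unknown combination method {method!r}")
    table = pd.DataFrame({"dscore_p": d, "loop_p": l, "combined_p": combined})
    sgn = signs.reindex(genes).fillna(1.0) if signs is not None else pd.Series(1.0, index=genes)
    with np.errstate(divide="ignore"):
        table["signed_score"] = -np.log10(combined.clip(lower=1e-300)) * sgn
    r = None
    if expression_logfc is not None:
        lfc = expression_logfc.reindex(genes)
        ok = table["signed_score"].notna() & lfc.notna()
        if ok.sum() >= 3:
            r = float(stats.pearsonr(table.loc[ok, "signed_score"], lfc[ok])[0])
    return table, r


def read_filter(
    counts: pd.DataFrame,
    min_reads: int = 5,
    max_low_fraction: float = 0.2,
    min_mean: float = 2.0,
) -> pd.Series:
    """Keep genes unless >20% of samples have <5 reads or the mean is <2."""
    low_frac = (counts < min_reads).mean(axis=1)
    return (low_frac <= max_low_fraction) & (counts.mean(axis=1) >= min_mean)


# direction each structural class is tested for (one-sided Wilcoxon)
_CLASS_DIRECTION = {
    "B-to-A": "up", "A-to-B": "down",
    "increased": "up", "decreased": "down",
    "enhanced": "up", "reduced": "down",
    "boundary": "two-sided",
}


def associate_degs(
    expression: pd.DataFrame,
    genes: pd.DataFrame,
    switches: pd.DataFrame | None = None,
    boundaries: pd.DataFrame | None = None,
    dscores: pd.DataFrame | None = None,
    tads: list | None = None,
    diff_loops: pd.DataFrame | None = None,
    binsize: int | None = None,
    de_fdr: float = 0.01,
    de_fc: float = 2.0,
    promoter_pad: int = 5_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign DEGs to structural-change classes and test each class.

    ``expression`` needs columns ``name, chrom, start, end, strand?, logFC``
    and optionally ``fdr`` plus per-sample ``*_count`` columns for the read
    filter. Compartment switches attach by gene-body bin overlap (majority
    bin label); flagged TAD D-scores by the TSS-containing TAD; loops by
    promoter-window (TSS ± 5 kb) overlap with a differential-loop anchor.

    Returns the per-gene association table and the per-class one-sided
    Wilcoxon rank-sum results against structurally stable genes.
    """
    expr = expression.copy()
    count_cols = [c for c in expr.columns if c.endswith("_count")]
    if count_cols:
        keep = read_filter(expr[count_cols])
        expr = expr[keep.to_numpy()]
    missing = set(expr["name"]) - set(genes["name"])
    if missing:
        raise ValueError(f"genes absent from catalog: {sorted(missing)[:5]}...")
    gcat = genes.set_index("name")
    expr = expr.set_index("name")
    expr["de"] = (expr["fdr"] < de_fdr if "fdr" in expr else True) & (expr["logFC"].abs() > np.log2(de_fc))

    assoc_rows = []
    for gname, row in expr.iterrows():
        g = gcat.loc[gname]
        chrom, gstart, gend = g["chrom"], int(g["start"]), int(g["end"])
        strand = g.get("strand", "+")
        tss = gstart if strand == "+" else gend - 1
        classes: list[str] = []
        if switches is not None and len(switches) and binsize:
            b0, b1 = gstart // binsize, (gend - 1) // binsize + 1
            hits = switches[(switches["chrom"] == chrom)
                            & (switches["bin"] >= b0) & (switches["bin"] < b1)]
            if len(hits):
                classes.append(hits["direction"].mode().iloc[0].replace("-to-", "-to-"))
        if boundaries is not None and len(boundaries) and binsize:
            b0, b1 = gstart // binsize, (gend - 1) // binsize + 1
            hits = boundaries[boundaries.get("differential", False)]
            hits = hits[(hits["chrom"] == chrom) & (hits["bin"] >= b0) & (hits["bin"] < b1)]
            if len(hits):
                classes.append("boundary")
        if dscores is not None and tads is not None and binsize:
            tb = tss // binsize
            for k, tad in enumerate(tads):
                if tad.chrom == chrom and tad.start_bin <= tb < tad.end_bin:
                    if k < len(dscores) and bool(dscores.iloc[k]["differential"]):
                        classes.append(str(dscores.iloc[k]["direction"]))
                    break
        if diff_loops is not None and len(diff_loops):
            p0, p1 = tss - promoter_pad, tss + promoter_pad
            flagged = diff_loops[diff_loops["differential"]]
            for _, lp in flagged.iterrows():
                if lp["chrom"] != chrom:
                    continue
                res = int(lp["resolution"])
                for b in (lp["bin1"], lp["bin2"]):
                    if int(b) * res < p1 and (int(b) + 1) * res > p0:
                        classes.append(str(lp["direction"]))
                        break
        assoc_rows.append({
            "name": gname, "logFC": row["logFC"], "de": bool(row["de"]),
            "classes": sorted(set(classes)) or ["no structural change"],
        })
    assoc = pd.DataFrame(assoc_rows)

    stable = assoc[assoc["classes"].apply(lambda c: c == ["no structural change"])]
    test_rows = []
    for cls, direction in _CLASS_DIRECTION.items():
        members = assoc[assoc["classes"].apply(lambda c: cls in c)]
        if len(members) < 3 or len(stable) < 3:
            continue
        alt = {"up": "greater", "down": "less"}.get(direction, "two-sided")
        p = float(stats.mannwhitneyu(members["logFC"], stable["logFC"], alternative=alt).pvalue)
        test_rows.append({"class": cls, "direction": direction, "n": len(members),
                          "n_stable": len(stable), "p": p,
                          "median_logFC": float(members["logFC"].median())})
    return assoc, pd.DataFrame(test_rows)
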