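"""Translocation discovery, base-pair breakpoint refinement, reassembled
maps and neo-loop (enhancer-hijacking) detection.

Interchromosomal blocks are found by a coarse-to-fine Poisson scan of each
trans matrix against its own uniform trans background; blocks also present
in controls are filtered out. Candidate blocks are refined to single-bp
breakpoints from bridge-linker-free chimeric reads: the modal exact segment
coordinate pair must be supported by strictly more than ``min_support``
(default 3) reads. The fused flanks and fragment orientations are inferred
from the majority read-segment strands.

A refined event defines a two-fragment derivative chromosome; the
coordinate transform between native and reassembled coordinates is a
bijection on the covered intervals. The loop caller runs on the reassembled
matrix restricted to junction-spanning pixels, and calls must additionally
be enriched (default 2x) over control matrices pushed through the same
transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GenomeModel
from .loops import LoopCall, call_loops_at_resolution
from .matrix import ContactMatrix
from .simulate import ChimericRead

__all__ = [
    "CandidateBlock",
    "TranslocationEvent",
    "CoordinateTransform",
    "ReassembledMap",
    "NeoLoop",
    "detect_interchrom_blocks",
    "refine_breakpoints",
    "reassemble_matrix",
    "detect_neo_loops",
    "annotate_event",
]


@dataclass
class CandidateBlock:
    chrom_a: str
    a_start: int  # bp, 0-based half-open
    a_end: int
    chrom_b: str
    b_start: int
    b_end: int
    enrichment: float
    p: float
    q: float
    control_present: bool = False


@dataclass
class TranslocationEvent:
    chrom_a: str
    bp_a: int  # 1-based
    flank_a: str
    chrom_b: str
    bp_b: int
    flank_b: str
    support: int
    enrichment: float
    refined: bool
    control_present: bool = False
    block: CandidateBlock | None = None

    @property
    def inverted(self) -> bool:
        return self.flank_a == "right" or self.flank_b == "left"


# ---------------------------------------------------------------------------
# block detection
# ---------------------------------------------------------------------------

def _scan_pair(
    m: np.ndarray,
    coarse_factor: int,
    min_enrichment: float,
    alpha: float,
) -> list[tuple[int, int, int, int, float, float]]:
    """Coarse-to-fine scan of one trans matrix (fine-bin counts).

    Returns fine-bin blocks (a0, a1, b0, b1, enrichment, p)."""
    total = m.sum()
    if total <= 0:
        return []
    n1, n2 = m.shape
    lam_pixel = total / (n1 * n2)
    c1 = -(-n1 // coarse_factor)
    c2 = -(-n2 // coarse_factor)
    coarse = np.zeros((c1, c2))
    areas = np.zeros((c1, c2))
    for i in range(c1):
        for j in range(c2):
            sub = m[i * coarse_factor : (i + 1) * coarse_factor,
                    j * coarse_factor : (j + 1) * coarse_factor]
            coarse[i, j] = sub.sum()
            areas[i, j] = sub.size
    lam = lam_pixel * areas
    pvals = stats.poisson.sf(coarse - 1, lam).ravel()
    qvals = multipletests(pvals, method="fdr_bh")[1].reshape(coarse.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = np.where(lam > 0, coarse / lam, 0.0)
    blocks = []
    sig = (enr >= min_enrichment) & (qvals < alpha)
    for i, j in zip(*np.nonzero(sig)):
        # fine refinement over the block expanded by one coarse block on
        # each side, so hot pixels straddling a coarse boundary are kept
        a0 = max((i - 1) * coarse_factor, 0)
        a1 = min((i + 2) * coarse_factor, n1)
        b0 = max((j - 1) * coarse_factor, 0)
        b1 = min((j + 2) * coarse_factor, n2)
        sub = m[a0:a1, b0:b1]
        hot = sub > lam_pixel * min_enrichment
        if hot.any():
            ii, jj = np.nonzero(hot)
            blocks.append((a0 + int(ii.min()), a0 + int(ii.max()) + 1,
                           b0 + int(jj.min()), b0 + int(jj.max()) + 1,
                           float(enr[i, j]), float(pvals.reshape(coarse.shape)[i, j])))
        else:
            blocks.append((a0, a1, b0, b1, float(enr[i, j]), float(pvals.reshape(coarse.shape)[i, j])))
    return blocks


def _merge_adjacent_blocks(
    blocks: list[tuple[int, int, int, int, float, float]],
    gap: int,
) -> list[tuple[int, int, int, int, float, float]]:
    """Union blocks whose fine-bin footprints touch within ``gap`` bins."""
    merged: list[list] = []
    for b in sorted(blocks, key=lambda x: (x[0], x[2])):
        hit = None
        for mb in merged:
            if not (b[0] > mb[1] + gap or b[1] < mb[0] - gap
                    or b[2] > mb[3] + gap or b[3] < mb[2] - gap):
                hit = mb
                break
        if hit is None:
            merged.append(list(b))
        else:
            hit[0] = min(hit[0], b[0]); hit[1] = max(hit[1], b[1])
            hit[2] = min(hit[2], b[2]); hit[3] = max(hit[3], b[3])
            hit[4] = max(hit[4], b[4]); hit[5] = min(hit[5], b[5])
    return [tuple(m) for m in merged]


def detect_interchrom_blocks(
    sample: ContactMatrix,
    controls: Sequence[ContactMatrix],
    coarse_binsize: int = 1_000_000,
    min_enrichment: float = 5.0,
    alpha: float = 0.01,
) -> list[CandidateBlock]:
    """Candidate translocation blocks from trans-contact enrichment.

    The expected trans intensity for a chromosome pair is the uniform
    background implied by that pair's own total; blocks significant in any
    control at the same location are flagged ``control_present`` (and are
    conventionally excluded downstream).
    """
    bs = sample.binsize
    factor = max(coarse_binsize // bs, 1)
    out: list[CandidateBlock] = []
    for (c1, c2) in list(sample.pairs()):
        if c1 == c2:
            continue
        m = sample.matrix(c1, c2).toarray()
        blocks = _merge_adjacent_blocks(
            _scan_pair(m, factor, min_enrichment, alpha), gap=2)
        if not blocks:
            continue
        ctrl_blocks = []
        for ctrl in controls:
            cm = ctrl.matrix(c1, c2)
            if cm.nnz == 0:
                continue
            ctrl_blocks.extend(_scan_pair(cm.toarray(), factor, min_enrichment, alpha))
        for (a0, a1, b0, b1, enr, p) in blocks:
            present = any(not (a0 >= ca1 or a1 <= ca0 or b0 >= cb1 or b1 <= cb0)
                          for (ca0, ca1, cb0, cb1, _, _) in ctrl_blocks)
            out.append(CandidateBlock(
                c1, a0 * bs, a1 * bs, c2, b0 * bs, b1 * bs,
                enrichment=enr, p=p, q=p, control_present=present))
    return [b for b in out]


# ---------------------------------------------------------------------------
# breakpoint refinement
# ---------------------------------------------------------------------------

def refine_breakpoints(
    candidates: list[CandidateBlock],
    reads: list[ChimericRead],
    genome: GenomeModel,
    min_support: int = 3,
    window: int = 500_000,
) -> list[TranslocationEvent]:
    """Refine candidate blocks to single-bp breakpoints from chimeric reads.

    Bridge-linker reads are religation artifacts and discarded. The modal
    exact coordinate pair must be supported by strictly more than
    ``min_support`` reads; fused flanks come from the majority segment
    strands ('+' on A => left flank fuses; '+' on B => right flank fuses),
    with strand ties leaving the candidate unrefined.
    """
    for r in reads:
        if r.chrom1 not in genome.chromosomes or r.chrom2 not in genome.chromosomes:
            raise ValueError(f"chimeric read on unknown chromosome: {r.read_id}")
    usable = [r for r in reads if not r.linker]
    events: list[TranslocationEvent] = []
    for cand in candidates:
        if cand.control_present:
            continue
        hits: list[tuple[int, int, str, str]] = []
        for r in usable:
            # orient the read to (chrom_a, chrom_b)
            if r.chrom1 == cand.chrom_a and r.chrom2 == cand.chrom_b:
                pa, pb, sa, sb = r.pos1, r.pos2, r.strand1, r.strand2
            elif r.chrom2 == cand.chrom_a and r.chrom1 == cand.chrom_b:
                pa, pb, sa, sb = r.pos2, r.pos1, r.strand2, r.strand1
            else:
                continue
            if (cand.a_start - window < pa <= cand.a_end + window
                    and cand.b_start - window < pb <= cand.b_end + window):
                hits.append((pa, pb, sa, sb))
        refined = False
        bp_a = (cand.a_start + cand.a_end) // 2 + 1
        bp_b = (cand.b_start + cand.b_end) // 2 + 1
        flank_a = flank_b = "left"
        support = 0
        if hits:
            pairs = pd.Series([(h[0], h[1]) for h in hits]).value_counts()
            (mode_a, mode_b), support = pairs.index[0], int(pairs.iloc[0])
            if support > min_support:
                at_mode = [h for h in hits if (h[0], h[1]) == (mode_a, mode_b)]
                sa_plus = sum(1 for h in at_mode if h[2] == "+")
                sb_plus = sum(1 for h in at_mode if h[3] == "+")
                na = len(at_mode)
                if sa_plus * 2 != na and sb_plus * 2 != na:
                    flank_a = "left" if sa_plus * 2 > na else "right"
                    flank_b = "right" if sb_plus * 2 > na else "left"
                    bp_a, bp_b = int(mode_a), int(mode_b)
                    refined = True
        events.append(TranslocationEvent(
            cand.chrom_a, bp_a, flank_a, cand.chrom_b, bp_b, flank_b,
            support=support, enrichment=cand.enrichment,
            refined=refined, control_present=cand.control_present, block=cand))
    return events


# ---------------------------------------------------------------------------
# reassembly
# ---------------------------------------------------------------------------

@dataclass
class Fragment:
    chrom: str
    start: int  # 0-based bp, half-open
    end: int
    orientation: str  # '+' forward | '-' reversed

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoordinateTransform:
    """Bijection between native bp positions (0-based) on the covered
    fragments and the reassembled axis."""

    fragments: list[Fragment]

    def __post_init__(self) -> None:
        self._offsets = np.cumsum([0] + [f.length for f in self.fragments])

    @property
    def length(self) -> int:
        return int(self._offsets[-1])

    def to_reassembled(self, chrom: str, pos: int) -> int:
        for f, off in zip(self.fragments, self._offsets):
            if f.chrom == chrom and f.start <= pos < f.end:
                if f.orientation == "+":
                    return int(off + (pos - f.start))
                return int(off + (f.end - 1 - pos))
        raise ValueError(f"position {chrom}:{pos} not covered by the assembly")

    def to_native(self, rpos: int) -> tuple[str, int]:
        if not (0 <= rpos < self.length):
            raise ValueError(f"reassembled position {rpos} out of range")
        for f, off in zip(self.fragments, self._offsets):
            if off <= rpos < off + f.length:
                local = rpos - off
                if f.orientation == "+":
                    return f.chrom, int(f.start + local)
                return f.chrom, int(f.end - 1 - local)
        raise AssertionError("unreachable")


@dataclass
class ReassembledMap:
    transform: CoordinateTransform
    junction: int  # bp on the reassembled axis (start of fragment 2)
    binsize: int
    dense: np.ndarray
    event: TranslocationEvent | None = None

    @property
    def junction_bin(self) -> int:
        return self.junction // self.binsize

    def to_contact_matrix(self) -> ContactMatrix:
        """Wrap the reassembled map as a one-chromosome contact container."""
        n = self.dense.shape[0]
        genome = GenomeModel({"assembly": n * self.binsize}, binsize=self.binsize)
        cm = ContactMatrix(genome, self.binsize)
        cm._data[("assembly", "assembly")] = sp.csr_matrix(np.triu(self.dense))
        return cm


def _event_fragments(event: TranslocationEvent, genome: GenomeModel, flank: int, binsize: int) -> list[Fragment]:
    frags = []
    bs = binsize
    for chrom, bp, fl, junction_end in (
        (event.chrom_a, event.bp_a, event.flank_a, True),
        (event.chrom_b, event.bp_b, event.flank_b, False),
    ):
        clen = genome.chromosomes[chrom]
        b = (bp - 1) // bs  # bin holding the breakpoint
        if fl == "left":
            start = max(((bp - 1 - flank) // bs) * bs, 0)
            end = min((b + 1) * bs, clen)
            orient = "+" if junction_end else "-"
        else:
            start = b * bs
            end = min(-(-(bp - 1 + flank) // bs) * bs, clen)
            orient = "-" if junction_end else "+"
        frags.append(Fragment(chrom, start, end, orient))
    return frags


def reassemble_matrix(
    matrix: ContactMatrix,
    event: TranslocationEvent,
    genome: GenomeModel,
    flank: int = 4_000_000,
) -> ReassembledMap:
    """Build the derivative-chromosome contact map for a refined event.

    Fragment A ends at breakpoint A and fragment B starts at breakpoint B;
    fragments whose kept flank points away from the junction are
    reverse-oriented. Contacts (cis of each fragment plus trans across the
    pair) are pushed through the coordinate transform; flanks extending
    beyond a chromosome end are clipped.
    """
    bs = matrix.binsize
    frags = _event_fragments(event, genome, flank, bs)
    transform = CoordinateTransform(frags)
    nb = [f.length // bs for f in frags]
    n = sum(nb)
    out = np.zeros((n, n))

    def frag_bins(f: Fragment) -> np.ndarray:
        bins = np.arange(f.start // bs, f.end // bs)
        return bins if f.orientation == "+" else bins[::-1]

    offsets = [0, nb[0]]
    for i, fi in enumerate(frags):
        bi = frag_bins(fi)
        for j, fj in enumerate(frags):
            if j < i:
                continue
            bj = frag_bins(fj)
            if fi.chrom == fj.chrom:
                dense = matrix.dense(fi.chrom)
                sub = dense[np.ix_(bi, bj)]
            else:
                c1, c2, swapped = genome.canonical_pair(fi.chrom, fj.chrom)
                tm = matrix.matrix(c1, c2).toarray()
                sub = tm[np.ix_(bj, bi)].T if swapped else tm[np.ix_(bi, bj)]
            out[offsets[i] : offsets[i] + nb[i], offsets[j] : offsets[j] + nb[j]] = sub
    out = np.triu(out) + np.triu(out, 1).T
    return ReassembledMap(transform, junction=nb[0] * bs, binsize=bs, dense=out, event=event)


def junction_continuity(rmap: ReassembledMap, band: int = 30) -> float:
    """Decay-continuity statistic of a reassembled map.

    Pearson correlation, over junction-crossing pixels within ``band`` bins
    of the junction, between the observed contacts and the power-law decay
    expected if the two fragments were one contiguous chromosome. The true
    fusion configuration maximizes this statistic over the alternatives.
    """
    jb = rmap.junction_bin
    n = rmap.dense.shape[0]
    i0, i1 = max(jb - band, 0), jb
    j0, j1 = jb, min(jb + band, n)
    obs = rmap.dense[i0:i1, j0:j1].ravel()
    di = np.arange(i0, i1)
    dj = np.arange(j0, j1)
    dist = -np.subtract.outer(di, dj)  # j - i
    model = (dist.ravel() + 1.0) ** -1.0
    if obs.std() == 0 or model.std() == 0:
        return 0.0
    return float(np.corrcoef(obs, model)[0, 1])


# ---------------------------------------------------------------------------
# neo-loops
# ---------------------------------------------------------------------------

@dataclass
class NeoLoop:
    reassembled_bin1: int
    reassembled_bin2: int
    binsize: int
    native_anchor1: tuple[str, int, int]  # chrom, start, end (bp)
    native_anchor2: tuple[str, int, int]
    observed: float
    control_value: float
    enrichment_vs_control: float  # inf when the control is empty at the pixel
    q: float
    spans_junction: bool = True
    control_comparable: bool = True
    on_preexisting_anchor: bool = False
    at_ctcf_site: bool = False

    @property
    def anchor1(self) -> tuple[str, int, int]:
        return self.native_anchor1

    @property
    def anchor2(self) -> tuple[str, int, int]:
        return self.native_anchor2


def _native_anchor(rmap: ReassembledMap, rbin: int) -> tuple[str, int, int]:
    bs = rmap.binsize
    chrom, p0 = rmap.transform.to_native(rbin * bs)
    chrom2, p1 = rmap.transform.to_native(min(rbin * bs + bs - 1, rmap.transform.length - 1))
    lo, hi = min(p0, p1), max(p0, p1) + 1
    return (chrom, lo, hi)


def detect_neo_loops(
    sample_map: ReassembledMap,
    control_maps: Sequence[ReassembledMap],
    min_control_enrichment: float = 2.0,
    fdr: float = 0.1,
    preexisting_anchors: list[tuple[str, int, int]] | None = None,
    ctcf_sites: pd.DataFrame | None = None,
    **loop_kwargs,
) -> list[NeoLoop]:
    """Loop calls on the reassembled map restricted to junction-spanning
    pixels, kept only when enriched over the control average."""
    cm = sample_map.to_contact_matrix()
    calls = call_loops_at_resolution(cm, "assembly", fdr=fdr, **loop_kwargs)
    jb = sample_map.junction_bin
    ctrl_avg = None
    if control_maps:
        ctrl_avg = np.mean([c.dense for c in control_maps], axis=0)
    sample_total = sample_map.dense.sum()
    out: list[NeoLoop] = []
    for c in calls:
        if not (c.bin1 < jb <= c.bin2):
            continue
        comparable = True
        if ctrl_avg is None:
            enr, ctrl_val = np.inf, 0.0
            comparable = False
        else:
            ctrl_total = ctrl_avg.sum()
            scale = sample_total / ctrl_total if ctrl_total > 0 else 1.0
            ctrl_val = float(ctrl_avg[c.bin1, c.bin2] * scale)
            if ctrl_val <= 0:
                enr = np.inf
                comparable = False
            else:
                enr = c.observed / ctrl_val
        if comparable and enr < min_control_enrichment:
            continue
        a1 = _native_anchor(sample_map, c.bin1)
        a2 = _native_anchor(sample_map, c.bin2)
        on_anchor = False
        if preexisting_anchors:
            for (ch, s, e) in preexisting_anchors:
                for (ach, asv, aev) in (a1, a2):
                    if ch == ach and s < aev and asv < e:
                        on_anchor = True
        at_ctcf = False
        if ctcf_sites is not None:
            for (ach, asv, aev) in (a1, a2):
                hit = ctcf_sites[(ctcf_sites["chrom"] == ach)
                                 & (ctcf_sites["end"] > asv) & (ctcf_sites["start"] < aev)]
                if len(hit):
                    at_ctcf = True
        out.append(NeoLoop(
            c.bin1, c.bin2, sample_map.binsize, a1, a2,
            observed=c.observed, control_value=ctrl_val,
            enrichment_vs_control=float(enr), q=c.q,
            control_comparable=comparable,
            on_preexisting_anchor=on_anchor, at_ctcf_site=at_ctcf))
    return out


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def annotate_event(
    event: TranslocationEvent,
    genes: pd.DataFrame,
    known_breakpoints: pd.DataFrame | None,
    expression: pd.DataFrame | None = None,
    sample: str | None = None,
    control_samples: Sequence[str] | None = None,
    compartments: dict[str, np.ndarray] | None = None,
    compartment_binsize: int | None = None,
    novelty_distance: int = 100_000,
) -> dict:
    """Annotate one event: nearest genes, novelty, compartments, expression.

    Novelty follows the 100-kb rule (novel iff every breakpoint is farther
    than 100 kb from all known breakpoints of the same chromosome). The
    nearest gene is "up" when its sample FPKM exceeds 1 AND is at least
    twice the control mean; "down" is symmetric.
    """
    if genes is None or len(genes) == 0:
        raise ValueError("gene catalog is empty")
    ann: dict = {"chrom_a": event.chrom_a, "bp_a": event.bp_a,
                 "chrom_b": event.chrom_b, "bp_b": event.bp_b,
                 "refined": event.refined, "support": event.support}
    near_known = False
    for suffix, chrom, bp in (("a", event.chrom_a, event.bp_a), ("b", event.chrom_b, event.bp_b)):
        sub = genes[genes["chrom"] == chrom]
        pos0 = bp - 1
        dists = np.where((sub["start"] <= pos0) & (pos0 < sub["end"]), 0,
                         np.minimum(np.abs(sub["start"] - pos0), np.abs(sub["end"] - 1 - pos0)))
        k = int(np.argmin(dists))
        gene = sub.iloc[k]
        ann[f"nearest_gene_{suffix}"] = gene["name"]
        ann[f"nearest_gene_distance_{suffix}"] = int(dists[k])
        ann[f"noncoding_{suffix}"] = bool(dists[k] > 0)
        if known_breakpoints is not None and len(known_breakpoints):
            kb = known_breakpoints[known_breakpoints["chrom"] == chrom]
            if len(kb) and np.abs(kb["pos"] - bp).min() <= novelty_distance:
                near_known = True
        if compartments is not None and compartment_binsize:
            labels = compartments.get(chrom)
            if labels is not None:
                ann[f"compartment_{suffix}"] = str(labels[min(pos0 // compartment_binsize, len(labels) - 1)])
        if expression is not None and sample and control_samples:
            row = expression[expression["name"] == gene["name"]]
            if len(row):
                fpkm = float(row[f"{sample}_fpkm"].iloc[0])
                ctrl = float(np.mean([row[f"{c}_fpkm"].iloc[0] for c in control_samples]))
                if fpkm > 1 and fpkm >= 2 * ctrl:
                    status = "up"
                elif ctrl > 1 and ctrl >= 2 * fpkm:
                    status = "down"
                else:
                    status = "unchanged"
                ann[f"nearest_gene_expression_{suffix}"] = status
                ann[f"nearest_gene_fpkm_{suffix}"] = fpkm
    ann["novel"] = not near_known
    return ann
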