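"""Synthetic Hi-C cohort generator with planted ground truth.

The generative model for a cis map is multiplicative on bin pairs:

    E[count(i, j)]  ∝  decay(|i-j|) × compartment(i, j) × tad(i, j) × loop(i, j)

with ``decay(d) = (d + 1)^exponent`` (flat cap at one bin, so the diagonal
is included and finite), a symmetric A/B checkerboard factor, block-wise
intra-TAD enrichment and focal loop peaks. Counts are Poisson-sampled at a
target cis depth; every generator is deterministic given its seed.

Rearrangements add junction-centred decay contacts scaled by the clonal
fraction, planted neo-loop peaks across the junction, and chimeric reads
whose two segments sit exactly on the breakpoints (bridge-linker flag
false), plus random religation decoys (flag true).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .matrix import write_pairs

__all__ = [
    "StructureSpec",
    "RearrangementSpec",
    "ChimericRead",
    "CohortConfig",
    "CohortTruth",
    "simulate_contact_map",
    "plant_rearrangement",
    "simulate_expression",
    "simulate_cohort",
    "random_genome",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class StructureSpec:
    """Planted cis structure for one sample.

    ``compartments[chrom]`` is a per-bin label array of 'A'/'B';
    ``tads[chrom]`` is a list of ``(start_bin, end_bin, multiplier)`` with
    half-open bin intervals; ``loops[chrom]`` is a list of
    ``(bin1, bin2, multiplier)``.
    """

    decay_exponent: float = -1.0
    compartments: dict[str, np.ndarray] = field(default_factory=dict)
    compartment_strength: float = 1.0
    tads: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)
    loops: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)

    def validate(self, genome: GenomeModel) -> None:
        if self.compartment_strength < 1:
            raise ValueError("compartment strength must be >= 1")
        for chrom, tads in self.tads.items():
            n = genome.n_bins(chrom)
            last_end = -1
            for s, e, m in sorted(tads):
                if m < 1:
                    raise ValueError("TAD multiplier must be >= 1")
                if not (0 <= s < e <= n):
                    raise ValueError(f"TAD ({s},{e}) outside {chrom} ({n} bins)")
                if s < last_end:
                    raise ValueError(f"overlapping TADs on {chrom}")
                last_end = e
        for chrom, loops in self.loops.items():
            n = genome.n_bins(chrom)
            for b1, b2, m in loops:
                if m < 1:
                    raise ValueError("loop multiplier must be >= 1")
                if not (0 <= b1 <= b2 < n):
                    raise ValueError(f"loop ({b1},{b2}) outside {chrom} ({n} bins)")
        for chrom, labels in self.compartments.items():
            if len(labels) != genome.n_bins(chrom):
                raise ValueError(f"compartment labels on {chrom} do not cover all bins")


@dataclass
class RearrangementSpec:
    """A two-fragment rearrangement joined at a base-pair junction.

    The derivative chromosome is ``fragment A + fragment B`` where fragment
    A ends at ``bp_a`` (its ``flank_a`` side kept: 'left' keeps sequence
    upstream of the breakpoint in native orientation, 'right' keeps the
    downstream sequence reverse-oriented) and fragment B starts at ``bp_b``
    ('right' keeps downstream sequence forward, 'left' keeps upstream
    sequence reverse-oriented). An inversion is the same-chromosome case
    where one fragment is reverse-oriented.
    """

    event_type: str  # "translocation" | "inversion"
    chrom_a: str
    bp_a: int  # 1-based
    chrom_b: str
    bp_b: int
    flank_a: str = "left"   # {'left','right'}: which side of bp_a fuses
    flank_b: str = "right"  # {'left','right'}: which side of bp_b fuses
    clonal_fraction: float = 1.0
    n_chimeric_reads: int = 10
    n_decoy_reads: int = 10
    neo_loops: list[tuple[int, int, float]] = field(default_factory=list)
    # neo_loops: (native 1-based pos on fused side of A, same on B, multiplier)

    @property
    def inverted(self) -> bool:
        """True when one fragment is reverse-oriented in the derivative."""
        return self.flank_a == "right" or self.flank_b == "left"

    def validate(self, genome: GenomeModel) -> None:
        if self.event_type not in ("translocation", "inversion"):
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.event_type == "inversion" and self.chrom_a != self.chrom_b:
            raise ValueError("inversion breakpoints must lie on one chromosome")
        if self.event_type == "translocation" and self.chrom_a == self.chrom_b:
            raise ValueError("translocation breakpoints must lie on two chromosomes")
        if not (0.0 <= self.clonal_fraction <= 1.0):
            raise ValueError("clonal fraction must lie in [0, 1]")
        for chrom, bp in ((self.chrom_a, self.bp_a), (self.chrom_b, self.bp_b)):
            if not (1 <= bp <= genome.chromosomes[chrom]):
                raise ValueError(f"breakpoint {chrom}:{bp} outside chromosome")
        if self.flank_a not in ("left", "right") or self.flank_b not in ("left", "right"):
            raise ValueError("flanks must be 'left' or 'right'")


@dataclass
class ChimericRead:
    read_id: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    linker: bool  # True => bridge-linker religation artifact, not a junction read

    def to_row(self) -> tuple:
        return (
            self.read_id, self.chrom1, self.pos1, self.strand1,
            self.chrom2, self.pos2, self.strand2, int(self.linker),
        )


# ---------------------------------------------------------------------------
# cis map simulation
# ---------------------------------------------------------------------------

def _decay_matrix(n: int, exponent: float) -> np.ndarray:
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    return (d + 1.0) ** exponent


def _expected_cis(genome: GenomeModel, spec: StructureSpec, chrom: str) -> np.ndarray:
    n = genome.n_bins(chrom)
    mu = _decay_matrix(n, spec.decay_exponent)
    labels = spec.compartments.get(chrom)
    if labels is not None and spec.compartment_strength > 1:
        a = np.asarray(labels) == "A"
        same = np.equal.outer(a, a)
        mu = mu * np.where(same, spec.compartment_strength, 1.0 / spec.compartment_strength)
    for s, e, m in spec.tads.get(chrom, []):
        mu[s:e, s:e] *= m
    for b1, b2, m in spec.loops.get(chrom, []):
        mu[b1, b2] *= m
        mu[b2, b1] *= m
    return mu


def simulate_contact_map(
    genome: GenomeModel,
    spec: StructureSpec,
    cis_depth: int,
    seed: int,
) -> list[tuple[str, int, str, int, int]]:
    """Poisson-sample cis contact records at the genome's native bin size.

    Returns 1-based records ``(chrom, pos1, chrom, pos2, count)`` with
    positions at bin midpoints; the expected total over the genome is
    ``cis_depth``, split across chromosomes in proportion to their
    structural intensity mass.
    """
    if cis_depth <= 0:
        raise ValueError("cis_depth must be positive")
    spec.validate(genome)
    rng = np.random.default_rng(seed)
    mus = {c: _expected_cis(genome, spec, c) for c in genome.chromosomes}
    # mass of the upper triangle (incl. diagonal) decides each chromosome's share
    masses = {c: np.triu(mu).sum() for c, mu in mus.items()}
    total_mass = sum(masses.values())
    records: list[tuple[str, int, str, int, int]] = []
    for chrom, mu in mus.items():
        lam = np.triu(mu) * (cis_depth * masses[chrom] / total_mass / masses[chrom])
        counts = rng.poisson(lam)
        ii, jj = np.nonzero(counts)
        for i, j in zip(ii, jj):
            records.append(
                (chrom, genome.bin_mid(chrom, int(i)), chrom, genome.bin_mid(chrom, int(j)),
                 int(counts[i, j]))
            )
    return records


# ---------------------------------------------------------------------------
# rearrangement planting
# ---------------------------------------------------------------------------

def _junction_bins(genome: GenomeModel, chrom: str, bp: int, flank: str) -> tuple[np.ndarray, np.ndarray]:
    """Bins on the fused side of a breakpoint and their distances (in bins)
    to the junction along the derivative chromosome."""
    b = genome.bin_of(chrom, bp)
    n = genome.n_bins(chrom)
    if flank == "left":
        bins = np.arange(0, b + 1)
        dist = b - bins
    else:
        bins = np.arange(b, n)
        dist = bins - b
    return bins, dist


def plant_rearrangement(
    contacts: list[tuple[str, int, str, int, int]],
    genome: GenomeModel,
    rspec: RearrangementSpec,
    seed: int,
) -> tuple[list[tuple[str, int, str, int, int]], list[ChimericRead]]:
    """Add junction-spanning contacts, neo-loop peaks and chimeric reads.

    Junction contacts between a bin at distance ``da`` (in bins, along the
    derivative) from breakpoint A and a bin at ``db`` from breakpoint B get
    expectation ``fraction × A0 × decay(da + db + 1)`` where ``A0`` is the
    sample's diagonal amplitude — i.e. the fused fragments behave as one
    contiguous chromosome in the rearranged cell fraction.
    """
    rspec.validate(genome)
    rng = np.random.default_rng(seed)
    out = list(contacts)
    reads: list[ChimericRead] = []

    if rspec.clonal_fraction == 0.0:
        return out, reads

    # diagonal amplitude of the sample's cis maps, per bin
    diag_counts, diag_bins = 0.0, 0
    for c1, p1, c2, p2, cnt in contacts:
        if c1 == c2 and genome.bin_of(c1, p1) == genome.bin_of(c2, p2):
            diag_counts += cnt
    for c in genome.chromosomes:
        diag_bins += genome.n_bins(c)
    a0 = diag_counts / max(diag_bins, 1)

    bins_a, dist_a = _junction_bins(genome, rspec.chrom_a, rspec.bp_a, rspec.flank_a)
    bins_b, dist_b = _junction_bins(genome, rspec.chrom_b, rspec.bp_b, rspec.flank_b)
    dd = np.add.outer(dist_a, dist_b) + 1.0
    lam = rspec.clonal_fraction * a0 * dd ** (-1.0)

    # neo-loop focal peaks (native coordinates, one per anchor pair)
    bin_index_a = {b: k for k, b in enumerate(bins_a)}
    bin_index_b = {b: k for k, b in enumerate(bins_b)}
    for pos_a, pos_b, mult in rspec.neo_loops:
        ba = genome.bin_of(rspec.chrom_a, pos_a)
        bb = genome.bin_of(rspec.chrom_b, pos_b)
        if ba not in bin_index_a or bb not in bin_index_b:
            raise ValueError("neo-loop anchors must lie on the fused flanks of the junction")
        lam[bin_index_a[ba], bin_index_b[bb]] *= mult

    counts = rng.poisson(lam)
    ii, jj = np.nonzero(counts)
    for i, j in zip(ii, jj):
        pa = genome.bin_mid(rspec.chrom_a, int(bins_a[i]))
        pb = genome.bin_mid(rspec.chrom_b, int(bins_b[j]))
        c1, c2, swapped = genome.canonical_pair(rspec.chrom_a, rspec.chrom_b)
        p1, p2 = (pb, pa) if swapped else (pa, pb)
        if c1 == c2 and p1 > p2:
            p1, p2 = p2, p1
        out.append((c1, p1, c2, p2, int(counts[i, j])))

    # chimeric junction reads: segments sit exactly on the breakpoints
    strand_a = "+" if rspec.flank_a == "left" else "-"
    strand_b = "+" if rspec.flank_b == "right" else "-"
    for k in range(rspec.n_chimeric_reads):
        reads.append(ChimericRead(
            f"junc_{rspec.chrom_a}_{rspec.bp_a}_{k}",
            rspec.chrom_a, rspec.bp_a, strand_a,
            rspec.chrom_b, rspec.bp_b, strand_b,
            linker=False,
        ))
    # religation decoys carry the bridge linker and random positions
    chrom_names = list(genome.chromosomes)
    for k in range(rspec.n_decoy_reads):
        ca, cb = rng.choice(chrom_names, size=2)
        reads.append(ChimericRead(
            f"decoy_{rspec.chrom_a}_{rspec.bp_a}_{k}",
            str(ca), int(rng.integers(1, genome.chromosomes[str(ca)] + 1)), "+",
            str(cb), int(rng.integers(1, genome.chromosomes[str(cb)] + 1)), "+",
            linker=True,
        ))
    return out, reads


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(
    genome: GenomeModel,
    coupling: dict[str, float],
    n_per_group: int,
    dispersion: float,
    seed: int,
    mean_expression: float = 200.0,
    group_names: tuple[str, str] = ("control", "case"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial expression counts with planted per-gene log2FC.

    Returns ``(table, truth)``. ``table`` has one row per gene with
    ``<sample>_count`` and ``<sample>_fpkm`` columns; group 2 means are
    shifted by ``2**logFC`` for coupled genes. ``truth`` lists the planted
    log fold changes.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if genome.genes is None or len(genome.genes) == 0:
        raise ValueError("genome has no gene catalog")
    rng = np.random.default_rng(seed)
    genes = genome.genes.reset_index(drop=True)
    n_genes = len(genes)
    base = rng.lognormal(mean=np.log(mean_expression), sigma=1.0, size=n_genes)
    lfc = np.array([coupling.get(g, 0.0) for g in genes["name"]])

    samples = [f"{group_names[0]}_{i+1}" for i in range(n_per_group)] + \
              [f"{group_names[1]}_{i+1}" for i in range(n_per_group)]
    table = genes[["name", "chrom", "start", "end"]].copy()
    lengths_kb = (genes["end"] - genes["start"]).to_numpy() / 1000.0
    counts = {}
    for si, sample in enumerate(samples):
        mu = base * (2.0 ** lfc if si >= n_per_group else 1.0)
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        counts[sample] = rng.poisson(lam)
    depth = {s: counts[s].sum() for s in samples}
    for sample in samples:
        table[f"{sample}_count"] = counts[sample]
        table[f"{sample}_fpkm"] = counts[sample] / (lengths_kb * depth[sample] / 1e6)
    truth = pd.DataFrame({"name": genes["name"], "logFC": lfc})
    return table, truth


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Declarative description of a two-group synthetic cohort.

    Differential structure is planted in the *second* group (the "case"
    group): boundaries present only there, loop strength gains,
    compartment label flips and rearrangement events.
    """

    chromosomes: dict[str, int]
    binsize: int = 40_000
    groups: dict[str, int] = field(default_factory=lambda: {"control": 2, "case": 2})
    cis_depth: int = 500_000
    decay_exponent: float = -1.0
    n_genes: int = 200
    # shared structure
    boundaries: dict[str, list[int]] = field(default_factory=dict)       # bin positions
    tad_multiplier: float = 2.0
    compartment_block_bins: int = 10
    compartment_strength: float = 1.6
    loops: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)
    # planted group differences (applied to the case group)
    case_boundaries: dict[str, list[int]] = field(default_factory=dict)
    case_tad_gain: dict[str, list[int]] = field(default_factory=dict)    # TAD indices, extra multiplier 2x
    case_loop_gain: dict[str, list[int]] = field(default_factory=dict)   # loop indices, 2x strength
    case_compartment_flips: dict[str, list[tuple[int, int]]] = field(default_factory=dict)  # bin runs
    case_events: list[RearrangementSpec] = field(default_factory=list)
    expression_coupling: dict[str, float] = field(default_factory=dict)
    dispersion: float = 0.1

    def validate(self) -> None:
        if len(self.groups) < 2 or any(n < 2 for n in self.groups.values()):
            raise ValueError("cohort needs >=2 groups with >=2 samples each")


@dataclass
class CohortTruth:
    """Planted ground truth emitted beside the simulated cohort."""

    binsize: int
    boundaries: dict[str, dict[str, list[int]]]          # group -> chrom -> bins
    differential_boundaries: dict[str, list[int]]        # chrom -> case-only bins
    tads: dict[str, dict[str, list[list[int]]]]          # group -> chrom -> [start,end]
    differential_tads: dict[str, list[list[int]]]        # chrom -> case-gained [start,end]
    loops: dict[str, list[list[float]]]                  # chrom -> [b1,b2,mult]
    differential_loops: dict[str, list[int]]             # chrom -> gained loop indices
    compartments: dict[str, dict[str, list[str]]]        # group -> chrom -> labels
    compartment_flips: dict[str, list[list[int]]]        # chrom -> [start,end] flipped runs
    events: list[dict]
    expression_logfc: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def random_genome(
    chromosomes: dict[str, int],
    binsize: int,
    n_genes: int = 200,
    n_motifs: int = 200,
    seed: int = 0,
) -> GenomeModel:
    """Genome model with uniformly placed genes and stranded CTCF motifs."""
    rng = np.random.default_rng(seed)
    chroms = list(chromosomes)
    total = sum(chromosomes.values())
    genes = []
    for k in range(n_genes):
        c = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(5_000, 100_000))
        start = int(rng.integers(0, max(chromosomes[c] - length, 1)))
        genes.append({"name": f"gene{k:04d}", "chrom": c, "start": start,
                      "end": start + length, "strand": "+" if rng.random() < 0.5 else "-"})
    motifs = []
    for k in range(n_motifs):
        c = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chromosomes[c] - 20))
        motifs.append({"chrom": c, "start": start, "end": start + 20,
                       "name": f"ctcf{k:04d}", "score": float(rng.uniform(5, 30)),
                       "strand": "+" if rng.random() < 0.5 else "-"})
    return GenomeModel(
        chromosomes, binsize=binsize,
        genes=pd.DataFrame(genes), motifs=pd.DataFrame(motifs),
    )


def _tads_from_boundaries(boundaries: list[int], n_bins: int, min_bins: int = 3) -> list[tuple[int, int]]:
    edges = [0] + sorted(boundaries) + [n_bins]
    return [(s, e) for s, e in zip(edges[:-1], edges[1:]) if e - s >= min_bins]


def _checkerboard(n_bins: int, block: int) -> np.ndarray:
    labels = np.where((np.arange(n_bins) // block) % 2 == 0, "A", "B")
    return labels


def build_structure_spec(config: CohortConfig, genome: GenomeModel, case: bool) -> StructureSpec:
    """Expand a cohort config into the per-sample structural spec."""
    spec = StructureSpec(decay_exponent=config.decay_exponent,
                         compartment_strength=config.compartment_strength)
    for chrom in config.chromosomes:
        n = genome.n_bins(chrom)
        labels = _checkerboard(n, config.compartment_block_bins).copy()
        if case:
            for s, e in config.case_compartment_flips.get(chrom, []):
                labels[s:e] = np.where(labels[s:e] == "A", "B", "A")
        spec.compartments[chrom] = labels
        bounds = list(config.boundaries.get(chrom, []))
        if case:
            bounds += list(config.case_boundaries.get(chrom, []))
        tads = _tads_from_boundaries(bounds, n)
        gain = set(config.case_tad_gain.get(chrom, [])) if case else set()
        spec.tads[chrom] = [
            (s, e, config.tad_multiplier * (2.0 if ti in gain else 1.0))
            for ti, (s, e) in enumerate(tads)
        ]
        loop_gain = set(config.case_loop_gain.get(chrom, [])) if case else set()
        spec.loops[chrom] = [
            (b1, b2, m * (2.0 if li in loop_gain else 1.0))
            for li, (b1, b2, m) in enumerate(config.loops.get(chrom, []))
        ]
    return spec


def simulate_cohort(
    config: CohortConfig,
    seed: int,
    out_dir: str | Path,
) -> tuple[dict, CohortTruth]:
    """Write a full synthetic cohort to disk and return its ground truth.

    Outputs per sample: a pairs file and (for samples carrying events) a
    chimeric-read TSV; plus genome-wide gene/motif tables, an expression
    table, group assignments and ``truth.json``. Structure placement is
    config-driven; only the Poisson sampling consumes the seed, so two
    seeds give different counts but identical truth.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(seed)
    genome = random_genome(config.chromosomes, config.binsize,
                           n_genes=config.n_genes, seed=int(root.integers(2**31)))

    group_names = list(config.groups)
    manifest: dict = {"samples": {}, "groups": {}, "genome": {
        "chromosomes": config.chromosomes, "binsize": config.binsize}}
    truth_bounds: dict[str, dict[str, list[int]]] = {}
    truth_tads: dict[str, dict[str, list[list[int]]]] = {}
    truth_comp: dict[str, dict[str, list[str]]] = {}
    events_truth: list[dict] = []

    for gi, gname in enumerate(group_names):
        case = gi == len(group_names) - 1
        spec = build_structure_spec(config, genome, case=case)
        truth_bounds[gname] = {
            c: sorted(config.boundaries.get(c, []) + (config.case_boundaries.get(c, []) if case else []))
            for c in config.chromosomes
        }
        truth_tads[gname] = {c: [[s, e] for s, e, _ in spec.tads[c]] for c in config.chromosomes}
        truth_comp[gname] = {c: list(spec.compartments[c]) for c in config.chromosomes}
        for si in range(config.groups[gname]):
            sample = f"{gname}_{si+1}"
            s_seed = int(root.integers(2**31))
            contacts = simulate_contact_map(genome, spec, config.cis_depth, s_seed)
            reads: list[ChimericRead] = []
            if case:
                for ei, ev in enumerate(config.case_events):
                    contacts, ev_reads = plant_rearrangement(
                        contacts, genome, ev, int(root.integers(2**31)))
                    reads.extend(ev_reads)
            pairs_path = out_dir / f"{sample}.pairs"
            write_pairs(contacts, pairs_path, genome, binsize=config.binsize)
            reads_path = out_dir / f"{sample}.chimeric.tsv"
            write_chimeric_reads(reads, reads_path)
            manifest["samples"][sample] = {
                "group": gname, "pairs": pairs_path.name, "chimeric": reads_path.name}
            manifest["groups"].setdefault(gname, []).append(sample)

    for ev in config.case_events:
        events_truth.append({
            "event_type": ev.event_type,
            "chrom_a": ev.chrom_a, "bp_a": ev.bp_a, "flank_a": ev.flank_a,
            "chrom_b": ev.chrom_b, "bp_b": ev.bp_b, "flank_b": ev.flank_b,
            "clonal_fraction": ev.clonal_fraction,
            "neo_loops": [list(x) for x in ev.neo_loops],
        })

    n_per_group = min(config.groups.values())
    expr, expr_truth = simulate_expression(
        genome, config.expression_coupling, n_per_group=n_per_group,
        dispersion=config.dispersion, seed=int(root.integers(2**31)),
        group_names=(group_names[0], group_names[-1]))
    expr.to_csv(out_dir / "expression.tsv", sep="\t", index=False)
    genome.genes.to_csv(out_dir / "genes.tsv", sep="\t", index=False)
    genome.motifs[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        out_dir / "motifs.bed", sep="\t", header=False, index=False)

    diff_tads = {
        c: [truth_tads[group_names[-1]][c][ti] for ti in config.case_tad_gain.get(c, [])]
        for c in config.chromosomes
    }
    truth = CohortTruth(
        binsize=config.binsize,
        boundaries=truth_bounds,
        differential_boundaries={c: sorted(v) for c, v in config.case_boundaries.items()},
        tads=truth_tads,
        differential_tads=diff_tads,
        loops={c: [list(x) for x in v] for c, v in config.loops.items()},
        differential_loops=dict(config.case_loop_gain),
        compartments=truth_comp,
        compartment_flips={c: [list(x) for x in v] for c, v in config.case_compartment_flips.items()},
        events=events_truth,
        expression_logfc=dict(config.expression_coupling),
    )
    truth.to_json(out_dir / "truth.json")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest, truth


def write_chimeric_reads(reads: list[ChimericRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchrom1\tpos1\tstrand1\tchrom2\tpos2\tstrand2\tlinker\n")
        for r in reads:
            fh.write("\t".join(str(x) for x in r.to_row()) + "\n")


def read_chimeric_reads(path: str | Path) -> list[ChimericRead]:
    df = pd.read_csv(path, sep="\t")
    return [
        ChimericRead(str(r.read_id), str(r.chrom1), int(r.pos1), str(r.strand1),
                     str(r.chrom2), int(r.pos2), str(r.strand2), bool(r.linker))
        for r in df.itertuples(index=False)
    ]
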