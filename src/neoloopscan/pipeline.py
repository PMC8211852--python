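"""End-to-end orchestration: simulate -> matrices -> compartments/domains/
loops -> rearrangements -> integration, from one JSON config.

Each stage writes its outputs under the run directory and records input and
output checksums in the manifest; rerunning with an unchanged config and
seed skips completed stages (checksum-gated) and reproduces identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import compartments as comp_mod
from . import domains as dom_mod
from . import integration as int_mod
from . import loops as loop_mod
from . import rearrangements as sv_mod
from .genome import GenomeModel
from .matrix import ContactMatrix, bin_contacts, kr_balance, read_pairs
from .simulate import CohortConfig, RearrangementSpec, read_chimeric_reads, simulate_cohort

log = logging.getLogger("neoloopscan")

__all__ = ["RunConfig", "run_pipeline", "default_demo_config"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class RunConfig:
    """Validated run configuration (one JSON document)."""

    def __init__(self, data: dict, out_dir: str | Path):
        self.data = data
        self.out_dir = Path(out_dir)
        self.seed = int(data.get("seed", 0))
        sim = data.get("simulate")
        if sim is None:
            raise ValueError("config must carry a 'simulate' section")
        events = [RearrangementSpec(**e) if isinstance(e, dict) else e
                  for e in sim.get("case_events", [])]
        sim = {**sim, "case_events": events}
        sim["loops"] = {c: [tuple(x) for x in v] for c, v in sim.get("loops", {}).items()}
        sim["case_compartment_flips"] = {
            c: [tuple(x) for x in v] for c, v in sim.get("case_compartment_flips", {}).items()}
        self.cohort = CohortConfig(**sim)
        self.cohort.validate()
        self.params = data.get("params", {})

    @classmethod
    def from_json(cls, path: str | Path, out_dir: str | Path | None = None) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(data, out_dir or data.get("out", "run_out"))


def default_demo_config(out_dir: str | Path, seed: int = 7) -> RunConfig:
    """Small bundled demo cohort: two chromosomes, 2 vs 2 samples, one
    planted translocation with a neo-loop plus differential structure."""
    chrom_len = 12_000_000
    bs = 40_000
    data = {
        "seed": seed,
        "simulate": {
            "chromosomes": {"chr1": chrom_len, "chr2": chrom_len},
            "binsize": bs,
            "groups": {"control": 2, "case": 2},
            "cis_depth": 800_000,
            "n_genes": 150,
            "boundaries": {"chr1": [40, 80, 120, 200, 240], "chr2": [50, 100, 150, 200, 250]},
            "case_boundaries": {"chr1": [160]},
            "case_tad_gain": {"chr2": [1]},
            "loops": {"chr1": [[30, 60, 6.0], [90, 110, 6.0], [210, 260, 6.0]],
                      "chr2": [[20, 45, 6.0], [120, 140, 6.0]]},
            "case_loop_gain": {"chr1": [0]},
            "case_compartment_flips": {"chr2": [[200, 220]]},
            "case_events": [{
                "event_type": "translocation",
                "chrom_a": "chr1", "bp_a": 6_000_000, "chrom_b": "chr2", "bp_b": 5_000_000,
                "flank_a": "left", "flank_b": "right", "clonal_fraction": 1.0,
                "n_chimeric_reads": 8, "n_decoy_reads": 10,
                "neo_loops": [[5_000_000 + bs // 2, 6_000_000 + bs // 2, 8.0]],
            }],
            "expression_coupling": {"gene0001": 1.5, "gene0002": -1.5},
        },
    }
    return RunConfig(data, out_dir)


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = {"stages": {}}
        if path.exists():
            with open(path) as fh:
                self.data = json.load(fh)

    def stage_done(self, name: str, inputs: dict[str, str]) -> bool:
        st = self.data["stages"].get(name)
        if not st:
            return False
        if st.get("inputs") != inputs:
            return False
        return all(Path(p).exists() for p in st.get("outputs", {}))

    def record(self, name: str, inputs: dict[str, str], outputs: list[Path], wall: float, **extra):
        self.data["stages"][name] = {
            "inputs": inputs,
            "outputs": {str(p): _sha256(p) for p in outputs if p.exists()},
            "wall_seconds": round(wall, 3),
            **extra,
        }
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)


def _load_matrices(sim_dir: Path, genome: GenomeModel, samples: dict) -> dict[str, ContactMatrix]:
    mats = {}
    for sample, meta in samples.items():
        recs, _, _ = read_pairs(sim_dir / meta["pairs"])
        mats[sample] = bin_contacts(recs, genome, genome.binsize)
    return mats


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Execute all stages; returns the manifest dict.

    Stage order: simulate, matrices, compartments, domains, loops, sv,
    integrate. A failing stage raises with the stage name; the manifest is
    written after each completed stage.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    cfg_hash = hashlib.sha256(
        json.dumps(config.data, sort_keys=True, default=str).encode()).hexdigest()
    base_inputs = {"config": cfg_hash, "seed": str(config.seed)}

    # ---- stage: simulate -------------------------------------------------
    sim_dir = out / "sim"
    t0 = time.time()
    if force or not manifest.stage_done("simulate", base_inputs):
        log.info("stage simulate: writing cohort to %s", sim_dir)
        sim_manifest, truth = simulate_cohort(config.cohort, config.seed, sim_dir)
        outputs = sorted(sim_dir.glob("*"))
        manifest.record("simulate", base_inputs, outputs, time.time() - t0, seed=config.seed)
    with open(sim_dir / "manifest.json") as fh:
        sim_manifest = json.load(fh)
    genome_chroms = {k: int(v) for k, v in sim_manifest["genome"]["chromosomes"].items()}
    binsize = int(sim_manifest["genome"]["binsize"])
    genes = pd.read_csv(sim_dir / "genes.tsv", sep="\t")
    motifs = pd.read_csv(sim_dir / "motifs.bed", sep="\t", header=None,
                         names=["chrom", "start", "end", "name", "score", "strand"])
    genome = GenomeModel(genome_chroms, binsize=binsize, genes=genes, motifs=motifs)
    groups = {g: list(s) for g, s in sim_manifest["groups"].items()}
    gnames = list(groups)
    g_ctrl, g_case = gnames[0], gnames[-1]
    samples = sim_manifest["samples"]

    mats = _load_matrices(sim_dir, genome, samples)
    for sample, m in mats.items():
        for chrom in genome.chromosomes:
            try:
                kr_balance(m, chrom)
            except ValueError:
                pass

    sim_inputs = dict(base_inputs)
    for sample, meta in samples.items():
        sim_inputs[sample] = _sha256(sim_dir / meta["pairs"])

    # ---- stage: compartments --------------------------------------------
    t0 = time.time()
    comp_dir = out / "compartments"
    if force or not manifest.stage_done("compartments", sim_inputs):
        comp_dir.mkdir(exist_ok=True)
        switch_frames = []
        consensus_labels: dict[str, dict[str, np.ndarray]] = {g: {} for g in (g_ctrl, g_case)}
        for chrom in genome.chromosomes:
            ref = genome.gene_density(chrom, binsize)
            tracks = {g: [] for g in (g_ctrl, g_case)}
            for g in (g_ctrl, g_case):
                for s in groups[g]:
                    tracks[g].append(comp_mod.compartment_track(mats[s], chrom, ref))
            cons, switches = comp_mod.consensus_and_switches(tracks)
            for g in (g_ctrl, g_case):
                consensus_labels[g][chrom] = cons[g].labels
            switch_frames.append(switches)
            pd.DataFrame({
                "bin": np.arange(len(cons[g_ctrl].labels)),
                f"{g_ctrl}": cons[g_ctrl].labels, f"{g_case}": cons[g_case].labels,
            }).to_csv(comp_dir / f"consensus_{chrom}.tsv", sep="\t", index=False)
        switch_table = pd.concat(switch_frames, ignore_index=True)
        switch_table.to_csv(comp_dir / "switches.tsv", sep="\t", index=False)
        np.save(comp_dir / "consensus.npy", consensus_labels, allow_pickle=True)
        manifest.record("compartments", sim_inputs, sorted(comp_dir.glob("*.tsv")), time.time() - t0)
    switch_table = pd.read_csv(comp_dir / "switches.tsv", sep="\t")
    consensus_labels = np.load(comp_dir / "consensus.npy", allow_pickle=True).item()

    # ---- stage: domains --------------------------------------------------
    t0 = time.time()
    dom_dir = out / "domains"
    if force or not manifest.stage_done("domains", sim_inputs):
        dom_dir.mkdir(exist_ok=True)
        bound_frames, dscore_frames = [], []
        window = int(self_or(config.params, "insulation_window", 1_000_000))
        span = int(self_or(config.params, "delta_span", 200_000))
        for chrom in genome.chromosomes:
            tracks = {g: [dom_mod.insulation_track(mats[s], chrom, window=window, delta_span=span)
                          for s in groups[g]] for g in (g_ctrl, g_case)}
            bt = dom_mod.differential_boundaries(tracks)
            bound_frames.append(bt)
            by_cond = {g: dom_mod.merge_boundaries(tracks[g]) for g in (g_ctrl, g_case)}
            tads = dom_mod.consensus_tads(by_cond, chrom, genome.n_bins(chrom))
            score_cols = {}
            for g in (g_ctrl, g_case):
                for s in groups[g]:
                    score_cols[s] = dom_mod.domain_score(mats[s], chrom, tads)
            st = pd.DataFrame(score_cols)
            st.insert(0, "chrom", chrom)
            st.insert(1, "start_bin", [t.start_bin for t in tads])
            st.insert(2, "end_bin", [t.end_bin for t in tads])
            diff = dom_mod.differential_domain_scores(
                st[[s for g in (g_ctrl, g_case) for s in groups[g]]],
                {g: groups[g] for g in (g_ctrl, g_case)})
            dscore_frames.append(pd.concat([st, diff], axis=1))
        pd.concat(bound_frames, ignore_index=True).to_csv(dom_dir / "boundaries.tsv", sep="\t", index=False)
        pd.concat(dscore_frames, ignore_index=True).to_csv(dom_dir / "dscores.tsv", sep="\t", index=False)
        manifest.record("domains", sim_inputs, sorted(dom_dir.glob("*.tsv")), time.time() - t0)
    boundary_table = pd.read_csv(dom_dir / "boundaries.tsv", sep="\t")
    dscore_table = pd.read_csv(dom_dir / "dscores.tsv", sep="\t")

    # ---- stage: loops ----------------------------------------------------
    t0 = time.time()
    loop_dir = out / "loops"
    if force or not manifest.stage_done("loops", sim_inputs):
        loop_dir.mkdir(exist_ok=True)
        frames = []
        for chrom in genome.chromosomes:
            pooled: dict[str, ContactMatrix] = {}
            union: list[loop_mod.LoopCall] = []
            for g in (g_ctrl, g_case):
                pool = mats[groups[g][0]].copy()
                for s in groups[g][1:]:
                    for key in mats[s].pairs():
                        pool.add_pair(*key, mats[s].matrix(*key))
                pooled[g] = pool
                union.extend(loop_mod.call_loops_at_resolution(pool, chrom, merge_distance=2 * binsize))
            merged = loop_mod._merge_calls(union, 2 * binsize)
            dl = loop_mod.differential_loops(
                merged, {s: mats[s] for g in (g_ctrl, g_case) for s in groups[g]},
                {g: groups[g] for g in (g_ctrl, g_case)})
            frames.append(dl)
        pd.concat(frames, ignore_index=True).to_csv(loop_dir / "diff_loops.tsv", sep="\t", index=False)
        manifest.record("loops", sim_inputs, sorted(loop_dir.glob("*.tsv")), time.time() - t0)
    diff_loops = pd.read_csv(loop_dir / "diff_loops.tsv", sep="\t")

    # ---- stage: sv -------------------------------------------------------
    t0 = time.time()
    sv_dir = out / "sv"
    if force or not manifest.stage_done("sv", sim_inputs):
        sv_dir.mkdir(exist_ok=True)
        controls = [mats[s] for s in groups[g_ctrl]]
        rows, neo_rows = [], []
        for s in groups[g_case]:
            cands = sv_mod.detect_interchrom_blocks(mats[s], controls)
            reads_name = samples[s].get("chimeric")
            reads_path = sim_dir / reads_name if reads_name else None
            reads = read_chimeric_reads(reads_path) if reads_path and reads_path.exists() else []
            events = sv_mod.refine_breakpoints(cands, reads, genome)
            for ev in events:
                ann = sv_mod.annotate_event(
                    ev, genes, None,
                    expression=None, compartments=consensus_labels[g_case],
                    compartment_binsize=binsize)
                rows.append({"sample": s, **{k: v for k, v in ann.items()},
                             "flank_a": ev.flank_a, "flank_b": ev.flank_b})
                if ev.refined:
                    rmap = sv_mod.reassemble_matrix(mats[s], ev, genome)
                    cmaps = [sv_mod.reassemble_matrix(c, ev, genome) for c in controls]
                    neos = sv_mod.detect_neo_loops(rmap, cmaps, ctcf_sites=motifs)
                    for nl in neos:
                        neo_rows.append({
                            "sample": s,
                            "chrom1": nl.native_anchor1[0], "start1": nl.native_anchor1[1],
                            "end1": nl.native_anchor1[2],
                            "chrom2": nl.native_anchor2[0], "start2": nl.native_anchor2[1],
                            "end2": nl.native_anchor2[2],
                            "observed": nl.observed, "enrichment": nl.enrichment_vs_control,
                            "q": nl.q, "at_ctcf": nl.at_ctcf_site})
        pd.DataFrame(rows).to_csv(sv_dir / "events.tsv", sep="\t", index=False)
        pd.DataFrame(neo_rows).to_csv(sv_dir / "neo_loops.tsv", sep="\t", index=False)
        manifest.record("sv", sim_inputs, sorted(sv_dir.glob("*.tsv")), time.time() - t0)

    # ---- stage: integrate ------------------------------------------------
    t0 = time.time()
    int_dir = out / "integrate"
    if force or not manifest.stage_done("integrate", sim_inputs):
        int_dir.mkdir(exist_ok=True)
        expr = pd.read_csv(sim_dir / "expression.tsv", sep="\t")
        ctrl_cols = [c for c in expr.columns if c.startswith(g_ctrl) and c.endswith("_fpkm")]
        case_cols = [c for c in expr.columns if c.startswith(g_case) and c.endswith("_fpkm")]
        l1 = np.log2(expr[ctrl_cols].to_numpy() + 1.0)
        l2 = np.log2(expr[case_cols].to_numpy() + 1.0)
        expr["logFC"] = l2.mean(axis=1) - l1.mean(axis=1)
        with np.errstate(invalid="ignore"):
            p = stats.ttest_ind(l2, l1, axis=1, equal_var=False).pvalue
        expr["p"] = np.where(np.isnan(p), 1.0, p)
        expr["fdr"] = multipletests(expr["p"], method="fdr_bh")[1]
        tad_objs = [dom_mod.Tad(r["chrom"], int(r["start_bin"]), int(r["end_bin"]))
                    for _, r in dscore_table.iterrows()]
        assoc, class_tests = int_mod.associate_degs(
            expr, genes,
            switches=switch_table, boundaries=boundary_table,
            dscores=dscore_table, tads=tad_objs,
            diff_loops=diff_loops, binsize=binsize)
        assoc.to_csv(int_dir / "associations.tsv", sep="\t", index=False)
        class_tests.to_csv(int_dir / "class_tests.tsv", sep="\t", index=False)
        manifest.record("integrate", sim_inputs, sorted(int_dir.glob("*.tsv")), time.time() - t0)

    return manifest.data


def self_or(params: dict, key: str, default):
    return params.get(key, default)
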