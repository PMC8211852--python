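"""Shared fixtures. Heavier simulated cohorts are session-scoped so the
planted-truth recovery tests and the acceptance suite reuse one realization."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from neoloopscan.genome import GenomeModel
from neoloopscan.matrix import ContactMatrix, bin_contacts
from neoloopscan.simulate import StructureSpec, simulate_contact_map


def dense_to_matrix(dense: np.ndarray, binsize: int = 10) -> ContactMatrix:
    """Wrap a symmetric dense array as a one-chromosome ContactMatrix."""
    n = dense.shape[0]
    genome = GenomeModel({"c": n * binsize}, binsize=binsize)
    cm = ContactMatrix(genome, binsize)
    cm._data[("c", "c")] = sp.csr_matrix(np.triu(dense))
    return cm


@pytest.fixture(scope="session")
def loop_genome() -> GenomeModel:
    return GenomeModel({"chr1": 20_000_000}, binsize=10_000)


@pytest.fixture(scope="session")
def planted_loops(loop_genome):
    """20 focal peaks at 5x enrichment, separations 250 kb - 1.5 Mb."""
    n = loop_genome.n_bins("chr1")
    rng = np.random.default_rng(7)
    loops = []
    for _ in range(20):
        b1 = int(rng.integers(50, n - 250))
        sep = int(rng.integers(25, 150))
        loops.append((b1, b1 + sep, 5.0))
    return loops


@pytest.fixture(scope="session")
def loop_map(loop_genome, planted_loops) -> ContactMatrix:
    """Pooled-depth (1e7) map carrying the 20 planted peaks."""
    spec = StructureSpec(loops={"chr1": planted_loops})
    recs = simulate_contact_map(loop_genome, spec, 10_000_000, seed=11)
    return bin_contacts(recs, loop_genome, 10_000)


@pytest.fixture(scope="session")
def null_map(loop_genome) -> ContactMatrix:
    """Pure-decay map with no planted structure, same depth as loop_map."""
    recs = simulate_contact_map(loop_genome, StructureSpec(), 10_000_000, seed=12)
    return bin_contacts(recs, loop_genome, 10_000)


@pytest.fixture(scope="session")
def loop_calls(loop_map):
    from neoloopscan.loops import call_loops_at_resolution

    return call_loops_at_resolution(loop_map, "chr1")


@pytest.fixture(scope="session")
def boundary_genome() -> GenomeModel:
    return GenomeModel({"chr1": 50_000_000}, binsize=40_000)


@pytest.fixture(scope="session")
def boundary_cohort(boundary_genome):
    """4 vs 4 insulation cohort: shared boundaries plus 10 case-only ones."""
    from neoloopscan.domains import insulation_track

    g = boundary_genome
    n = g.n_bins("chr1")
    shared = list(range(55, n - 60, 90))
    case_only = [b + 45 for b in shared[:10]]

    def spec_for(case: bool) -> StructureSpec:
        bounds = sorted(shared + (case_only if case else []))
        edges = [0] + bounds + [n]
        return StructureSpec(tads={"chr1": [(s, e, 2.0) for s, e in zip(edges[:-1], edges[1:])
                                            if e - s >= 3]})

    tracks = {"control": [], "case": []}
    for gi, (gname, case) in enumerate([("control", False), ("case", True)]):
        spc = spec_for(case)
        for si in range(4):
            recs = simulate_contact_map(g, spc, 2_000_000, seed=100 * gi + si)
            tracks[gname].append(insulation_track(bin_contacts(recs, g, 40_000), "chr1"))
    return {"tracks": tracks, "shared": shared, "case_only": case_only}


@pytest.fixture(scope="session")
def dscore_cohort(boundary_genome):
    """4 vs 4 domain-score cohort: 25 TADs, 5 with a 2x case-only gain."""
    import pandas as pd

    from neoloopscan.domains import Tad, domain_score

    g = boundary_genome
    n = g.n_bins("chr1")
    bounds = list(range(48, n - 48, 48))  # 26 TADs: 5 gained, >= 20 unchanged
    edges = [0] + bounds + [n]
    tadlist = [(s, e) for s, e in zip(edges[:-1], edges[1:]) if e - s >= 3]
    gained = set(range(0, 20, 4))
    tads = [Tad("chr1", s, e) for s, e in tadlist]
    cols, groups = {}, {"control": [], "case": []}
    for gi, (gname, case) in enumerate([("control", False), ("case", True)]):
        spec = StructureSpec(tads={"chr1": [
            (s, e, 2.0 * (2.0 if (ti in gained and case) else 1.0))
            for ti, (s, e) in enumerate(tadlist)]})
        for si in range(4):
            recs = simulate_contact_map(g, spec, 2_000_000, seed=500 + 100 * gi + si)
            name = f"{gname}_{si}"
            cols[name] = domain_score(bin_contacts(recs, g, 40_000), "chr1", tads)
            groups[gname].append(name)
    return {"scores": pd.DataFrame(cols), "groups": groups, "gained": gained,
            "n_tads": len(tads), "tads": tads}


@pytest.fixture(scope="session")
def diffloop_cohort(loop_genome):
    """4 vs 4 loop-strength cohort: 100 loops, 20 with a 2x case gain,
    plus 8 extra null samples for label-permutation testing."""
    from neoloopscan.loops import LoopCall

    g = loop_genome
    n = g.n_bins("chr1")
    rng = np.random.default_rng(21)
    base = []
    for _ in range(100):
        b1 = int(rng.integers(50, n - 250))
        sep = int(rng.integers(12, 200))
        base.append((b1, b1 + sep, 5.0))
    gained = set(range(0, 100, 5))

    def make(case: bool, seed: int) -> ContactMatrix:
        lp = [(b1, b2, m * (2.0 if (i in gained and case) else 1.0))
              for i, (b1, b2, m) in enumerate(base)]
        recs = simulate_contact_map(g, StructureSpec(loops={"chr1": lp}), 5_000_000, seed)
        return bin_contacts(recs, g, 10_000)

    mats, groups = {}, {"control": [], "case": []}
    for gname, case, off in (("control", False, 0), ("case", True, 100)):
        for si in range(4):
            s = f"{gname}_{si}"
            mats[s] = make(case, off + si)
            groups[gname].append(s)
    null_mats = {f"s{k}": make(False, 300 + k) for k in range(8)}
    calls = [LoopCall("chr1", b1, b2, 10_000, 0, {}, 0, 0) for (b1, b2, _) in base]
    return {"mats": mats, "groups": groups, "null_mats": null_mats,
            "calls": calls, "gained": gained}


@pytest.fixture(scope="session")
def sv_genome() -> GenomeModel:
    return GenomeModel({"chr1": 12_000_000, "chr2": 12_000_000}, binsize=40_000)


@pytest.fixture(scope="session")
def sv_controls(sv_genome):
    return [bin_contacts(simulate_contact_map(sv_genome, StructureSpec(), 1_000_000, s),
                         sv_genome, 40_000) for s in (901, 902)]
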