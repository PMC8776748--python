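"""Shared fixtures: small synthetic communities simulated once per session."""

from __future__ import annotations

import numpy as np
import pytest

import starterdyn as sd
from starterdyn.snv import annotate_and_filter, call_snvs, lineage_diagnostic_snvs


@pytest.fixture(scope="session")
def toy_genome():
    return sd.generate_reference(20000, 1.0, 2, seed=5)


@pytest.fixture(scope="session")
def lineage_sim():
    """Four lineages at (0.4, 0.3, 0.2, 0.1), 11 samples, depth 100, 0.1% error.

    Returns community, per-sample alignments, the called+filtered SNV
    table, and truth diagnostic SNV sets.
    """
    com = sd.build_community(
        42,
        n_samples=11,
        host_length=30_000,
        minor_length=20_000,
        n_lineages=4,
        snvs_per_lineage=60,
        phage_copies=1.0,
        include_minor_phage=False,
        include_plasmid=False,
    )
    refs = {gid: g.sequence for gid, g in com.genomes.items()}
    alns = {}
    for s in com.sample_ids:
        rd = sd.simulate_sample(com, s, depth=100, error_rate=0.001, seed=1000 + int(s[1:]))
        alns[s] = sd.align_reads(rd, refs)
    host = com.genomes["stherm"]
    pileups = {s: alns[s].pileup_counts("stherm") for s in com.sample_ids}
    table = call_snvs(pileups, host)
    filtered = annotate_and_filter(table, host)
    truth_keys = {
        st.lineage_id: {("stherm", v.pos, v.alt_base) for v in st.snvs}
        for st in com.species[0].strains
    }
    diag = lineage_diagnostic_snvs(truth_keys, {k: k for k in truth_keys})
    return {
        "community": com,
        "alignments": alns,
        "table": table,
        "filtered": filtered,
        "diagnostic": diag,
        "truth_keys": truth_keys,
    }


@pytest.fixture(scope="session")
def default_sim():
    """One error-free sample of the full community (phage, plasmid, minor phage).

    depth 50 on the dominant host; plasmid planted at PCN 0.2.
    """
    com = sd.build_community(
        8,
        n_samples=1,
        host_length=20_000,
        minor_length=15_000,
        phage_copies=10.0,
        integrated_cell_fraction=0.05,
        plasmid_pcn=0.2,
    )
    rd = sd.simulate_sample(com, "s01", depth=50, error_rate=0.0, seed=77)
    refs = {gid: g.sequence for gid, g in com.genomes.items()}
    aln = sd.align_reads(rd, refs)
    return {"community": com, "reads": rd, "alignments": aln, "depth": 50.0}


@pytest.fixture(scope="session")
def spacer_sim():
    """Error-free reads from a community with equal lineage fractions.

    Every strain's private leader spacers are well covered, so extraction
    can be scored for exact recall/precision against the truth catalog.
    """
    com = sd.build_community(
        3,
        n_samples=1,
        host_length=30_000,
        minor_length=20_000,
        n_lineages=4,
        lineage_fractions=(0.25, 0.25, 0.25, 0.25),
        snvs_per_lineage=60,
        phage_copies=1.0,
        include_minor_phage=False,
        include_plasmid=False,
    )
    rd = sd.simulate_sample(
        com, "s01", depth=100, read_len=150, error_rate=0.0, seed=9
    )
    consensi = {
        arr.array_id: arr.repeat for g in com.genomes.values() for arr in g.arrays
    }
    truth = set()
    for sp in com.species:
        for st in sp.strains:
            for seqs in com.strain_array_spacers(st.lineage_id).values():
                truth.update(seqs)
    return {"community": com, "reads": rd, "consensi": consensi, "truth_spacers": truth}


def _phage_run(seed: int, icf: float, depth: float = 100.0, copies: float = 10.0):
    com = sd.build_community(
        100 + seed,
        n_samples=1,
        host_length=12_000,
        include_minor_species=False,
        snvs_per_lineage=20,
        phage_copies=copies,
        integrated_cell_fraction=icf,
    )
    rd = sd.simulate_sample(com, "s01", depth=depth, seed=200 + seed)
    aln = sd.align_reads(rd, {gid: g.sequence for gid, g in com.genomes.items()})
    rep = sd.phage_state_report(aln, "s01", "phiST", "stherm", ["stherm"])
    return com, rep


@pytest.fixture(scope="session")
def phage_sims():
    """Lysogeny recovery runs: integrated fractions {0.02, 0.05, 0.11} x 10 seeds."""
    out = {}
    for icf in (0.02, 0.05, 0.11):
        out[icf] = [_phage_run(seed, icf) for seed in range(10)]
    return out


@pytest.fixture(scope="session")
def zero_lysogeny_sims():
    """20 seeds with integrated fraction 0 (free phage still present)."""
    runs = []
    for seed in range(20):
        com, rep = _phage_run(seed, 0.0, depth=40.0, copies=2.0)
        runs.append(rep)
    return runs


@pytest.fixture(scope="session")
def proto_sim():
    """Single-lineage host with phage-matching array spacers at 20 copies.

    Used for spacer vs protospacer read quantification; truth depth ratio
    between free phage and host is 20.
    """
    com = sd.build_community(
        55,
        n_samples=1,
        host_length=15_000,
        include_minor_species=False,
        n_lineages=1,
        lineage_fractions=(1.0,),
        snvs_per_lineage=10,
        phage_copies=20.0,
        integrated_cell_fraction=0.0,
        n_protospacer_spacers=4,
    )
    rd = sd.simulate_sample(
        com, "s01", depth=40, read_len=250, insert_mean=650, insert_sd=80,
        error_rate=0.0, seed=13,
    )
    return {"community": com, "reads": rd, "truth_ratio": 20.0}
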