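"""SNV gates, annotation filter, phase clustering, lineage quantification,
species abundance, plasmid copy number, and pN/pS."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

import starterdyn as sd
from starterdyn.community import classify_substitution
from starterdyn.dna import encode
from starterdyn.snv import (
    SnvCallingError,
    SnvTable,
    annotate_and_filter,
    annotate_snvs,
    call_snvs,
    cluster_trajectories,
    count_syn_nonsyn_sites,
    explained_snv_fraction,
    lineage_diagnostic_snvs,
    plasmid_copy_number,
    pnps,
    quantify_lineages,
    species_abundance,
)


def _pileup_for(ref_seq, alt_positions):
    """Base-count matrix: depth per (pos -> (alt_count, depth)) spec, ref elsewhere."""
    L = len(ref_seq)
    counts = np.zeros((L, 4), dtype=int)
    codes = encode(ref_seq)
    counts[np.arange(L), codes] = 100
    for pos, (alt_count, depth) in alt_positions.items():
        alt_code = (codes[pos] + 1) % 4
        counts[pos] = 0
        counts[pos, codes[pos]] = depth - alt_count
        counts[pos, alt_code] = alt_count
    return counts


@pytest.fixture(scope="module")
def ref100():
    return "ACGT" * 25  # 100 bp toy reference


def test_call_snvs_thresholds(ref100):
    ref = ("R", ref100)
    # AAF 0.04 in every sample: below the 0.05 gate -> not emitted
    p1 = {"s1": _pileup_for(ref100, {10: (4, 100)}), "s2": _pileup_for(ref100, {10: (4, 100)})}
    assert len(call_snvs(p1, ref)) == 0
    # AAF exactly 0.05 with alt count 5 in one sample: boundary inclusive
    p2 = {"s1": _pileup_for(ref100, {10: (5, 100)}), "s2": _pileup_for(ref100, {})}
    t = call_snvs(p2, ref)
    assert len(t) == 1 and int(t.df.pos.iloc[0]) == 10
    assert t.df["aaf_s1"].iloc[0] == pytest.approx(0.05)
    assert t.df["aaf_s2"].iloc[0] == 0.0  # reported for all samples once emitted
    # depth gate: alt 5 of depth 9 fails min_depth=10
    p3 = {"s1": _pileup_for(ref100, {10: (5, 9)})}
    assert len(call_snvs(p3, ref)) == 0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_call_snvs_monotone_in_min_alt_frac(seed):
    """Raising min_alternate_fraction never adds sites."""
    rng = np.random.default_rng(seed)
    ref_seq = "ACGT" * 25
    counts = rng.integers(0, 30, size=(100, 4))
    piles = {"s1": counts}
    sites = [
        set(map(tuple, call_snvs(piles, ("R", ref_seq), min_alt_frac=f).df[["pos"]].values))
        for f in (0.02, 0.05, 0.10, 0.3)
    ]
    for a, b in zip(sites, sites[1:]):
        assert b <= a


def test_annotate_filter_rules(toy_genome):
    g = toy_genome
    # pick a synonymous change in a single-copy gene and a change in a multi-copy gene
    syn_row = multi_row = None
    for gene in g.genes:
        for pos in range(gene.start, gene.end):
            for alt in "ACGT":
                if alt == g.sequence[pos]:
                    continue
                ann = classify_substitution(g, pos, alt)
                if (
                    syn_row is None
                    and ann.synonymy == "synonymous"
                    and ann.copy_class == "single_copy"
                ):
                    syn_row = (pos, g.sequence[pos], alt)
                if multi_row is None and ann.copy_class == "multi_copy":
                    multi_row = (pos, g.sequence[pos], alt)
        if syn_row and multi_row:
            break
    df = pd.DataFrame(
        [
            {"ref_id": g.genome_id, "pos": p, "ref": r, "alt": a,
             "ao_s1": 10, "dp_s1": 100, "aaf_s1": 0.1}
            for p, r, a in (syn_row, multi_row)
        ]
    )
    out = annotate_and_filter(SnvTable(df, ["s1"]), g)
    assert len(out) == 0  # silent site and multi-copy site both removed


def test_annotate_filter_equals_codon_oracle(toy_genome):
    """Filter output equals brute-force re-translation over random candidate SNVs."""
    g = toy_genome
    rng = np.random.default_rng(2)
    rows = []
    for _ in range(200):
        pos = int(rng.integers(0, len(g.sequence)))
        ref = g.sequence[pos]
        alt = "ACGT"[int(rng.integers(4))]
        if alt == ref:
            continue
        rows.append({"ref_id": g.genome_id, "pos": pos, "ref": ref, "alt": alt,
                     "ao_s1": 10, "dp_s1": 100, "aaf_s1": 0.1})
    table = SnvTable(pd.DataFrame(rows).drop_duplicates(["pos", "alt"]), ["s1"])
    kept = set(annotate_and_filter(table, g).keys())

    def oracle_keep(pos, alt):
        for gene in g.genes:
            if gene.start <= pos < gene.end:
                if gene.copy_class != "single_copy":
                    return False
                wt = g.sequence[gene.start : gene.end]
                mut = list(g.sequence)
                mut[pos] = alt
                mut = "".join(mut)[gene.start : gene.end]
                if gene.strand == "-":
                    wt = str(Seq(wt).reverse_complement())
                    mut = str(Seq(mut).reverse_complement())
                return str(Seq(wt).translate()) != str(Seq(mut).translate())
        return False

    expect = {
        (g.genome_id, int(r.pos), r.alt)
        for r in table.df.itertuples()
        if oracle_keep(int(r.pos), r.alt)
    }
    assert kept == expect


def _traj_table(groups, n_samples, noise_sd, seed, dips=None):
    """Synthetic AAF table: ``groups`` = [(freq, n_snvs), ...]."""
    rng = np.random.default_rng(seed)
    rows = []
    labels = []
    samples = [f"s{i}" for i in range(n_samples)]
    pos = 0
    for gi, (freq, n) in enumerate(groups):
        base = np.full(n_samples, freq)
        if dips and gi in dips:
            for si in dips[gi]:
                base[si] = 0.02
        for _ in range(n):
            traj = np.clip(base + rng.normal(0, noise_sd, n_samples), 0, 1)
            row = {"ref_id": "R", "pos": pos, "ref": "A", "alt": "C"}
            for s, v in zip(samples, traj):
                row[f"ao_{s}"] = int(v * 100)
                row[f"dp_{s}"] = 100
                row[f"aaf_{s}"] = v
            rows.append(row)
            labels.append(gi)
            pos += 1
    return SnvTable(pd.DataFrame(rows), samples), labels


def test_cluster_three_groups_exact_recovery():
    table, labels = _traj_table([(0.6, 50), (0.25, 50), (0.1, 50)], 11, 0.02, seed=1)
    res = cluster_trajectories(table)
    assert len(res.phases) == 3
    assert not res.unexplained_index
    for phase in res.phases:
        grp = {labels[i] for i in phase.member_index}
        assert len(grp) == 1  # 100% membership accuracy


def test_cluster_single_trajectory_one_phase():
    table, _ = _traj_table([(0.4, 10)], 5, 0.01, seed=2)
    res = cluster_trajectories(table)
    assert len(res.phases) == 1
    assert res.phases[0].n_members == 10


def test_cluster_phase_with_detection_dip_stays_contiguous():
    """A group dipping below the detection limit in two samples stays one phase."""
    table, labels = _traj_table(
        [(0.5, 40), (0.2, 40)], 11, 0.02, seed=3, dips={1: [3, 4]}
    )
    res = cluster_trajectories(table)
    assert len(res.phases) == 2
    dipped = [p for p in res.phases if p.centroid[3] < 0.05][0]
    assert {labels[i] for i in dipped.member_index} == {1}
    assert dipped.n_members == 40


def test_cluster_requires_three_samples():
    table, _ = _traj_table([(0.4, 10)], 2, 0.01, seed=4)
    with pytest.raises(SnvCallingError):
        cluster_trajectories(table)


def test_lineage_diagnostic_set_oracle():
    """Diagnostic sets equal brute-force intersection/difference on a toy panel."""
    rng = np.random.default_rng(6)
    lineages = {f"L{i}": [f"L{i}_iso{j}" for j in range(3)] for i in range(4)}
    assign = {iso: lin for lin, isos in lineages.items() for iso in isos}
    universe = [("R", p, "A") for p in range(200)]
    core = {lin: set(map(tuple, rng.choice(universe, 30))) for lin in lineages}
    haps = {}
    for lin, isos in lineages.items():
        for iso in isos:
            extra = set(map(tuple, rng.choice(universe, 10)))
            haps[iso] = core[lin] | extra
    result = lineage_diagnostic_snvs(haps, assign)
    for lin, isos in lineages.items():
        inter = set.intersection(*(haps[i] for i in isos))
        others = set().union(*(haps[i] for i in haps if assign[i] != lin))
        assert result[lin] == inter - others


def test_lineage_diagnostic_examples():
    haps = {f"i{j}": {("R", 1, "A")} for j in range(5)}
    haps["other"] = {("R", 2, "C")}
    assign = {f"i{j}": "L3" for j in range(5)}
    assign["other"] = "L4"
    res = lineage_diagnostic_snvs(haps, assign)
    assert ("R", 1, "A") in res["L3"]
    # shared with one L4 isolate -> no longer diagnostic
    haps["other"].add(("R", 1, "A"))
    with pytest.warns(UserWarning):
        res2 = lineage_diagnostic_snvs(haps, assign)
    assert ("R", 1, "A") not in res2["L3"]


def test_quantify_lineages_mean():
    rows = []
    for pos, aaf in [(1, 0.18), (2, 0.20), (3, 0.22)]:
        rows.append({"ref_id": "R", "pos": pos, "ref": "A", "alt": "C",
                     "ao_s1": int(aaf * 100), "dp_s1": 100, "aaf_s1": aaf})
    table = SnvTable(pd.DataFrame(rows), ["s1"])
    diag = {"L1": [("R", 1, "C"), ("R", 2, "C"), ("R", 3, "C")]}
    out = quantify_lineages(table, diag)
    assert out.abundance.iloc[0] == pytest.approx(0.20)
    assert out.n_snvs_used.iloc[0] == 3


def test_quantify_lineages_not_determined_without_coverage():
    rows = [{"ref_id": "R", "pos": 1, "ref": "A", "alt": "C",
             "ao_s1": 2, "dp_s1": 5, "aaf_s1": 0.4}]
    table = SnvTable(pd.DataFrame(rows), ["s1"])
    out = quantify_lineages(table, {"L1": [("R", 1, "C")]}, min_depth=10)
    assert np.isnan(out.abundance.iloc[0])
    assert out.n_snvs_used.iloc[0] == 0


def test_absent_lineage_estimated_near_zero():
    """A lineage at true fraction 0 gets an abundance estimate <= 0.02."""
    com = sd.build_community(
        21, n_samples=3, host_length=20000, include_minor_species=False,
        n_lineages=4, lineage_fractions=(0.5, 0.3, 0.2, 0.0),
        snvs_per_lineage=30, phage_copies=1.0,
    )
    host = com.genomes["stherm"]
    refs = {gid: g.sequence for gid, g in com.genomes.items()}
    piles = {}
    for s in com.sample_ids:
        rd = sd.simulate_sample(com, s, depth=100, error_rate=0.001, seed=500 + int(s[1:]))
        piles[s] = sd.align_reads(rd, refs).pileup_counts("stherm")
    table = call_snvs(piles, host)
    truth_keys = {
        st.lineage_id: {("stherm", v.pos, v.alt_base) for v in st.snvs}
        for st in com.species[0].strains
    }
    # quantify the absent lineage against all sites, forcing report of its SNVs
    diag = {"STL4": truth_keys["STL4"]}
    out = quantify_lineages(table, diag)
    est = out.abundance.dropna()
    assert (est <= 0.02).all()


def test_explained_snv_fraction_arithmetic():
    meta = [("R", p, "A") for p in range(100)]
    assert explained_snv_fraction(meta, meta) == 1.0
    assert explained_snv_fraction(meta, meta[:97]) == pytest.approx(0.97)
    with pytest.raises(ValueError):
        explained_snv_fraction([], meta)


def test_species_abundance():
    assert species_abundance({"a": 90.0, "b": 10.0}) == {"a": 0.9, "b": 0.1}
    assert species_abundance({"a": 5.0, "b": 5.0}) == {"a": 0.5, "b": 0.5}
    with pytest.raises(ValueError):
        species_abundance({"a": 0.0, "b": 0.0})


def test_species_abundance_recovered_from_sim(default_sim):
    com = default_sim["community"]
    aln = default_sim["alignments"]
    depths = {
        sp.species_id: aln.coverage_stats(sp.chromosome_id)["mean_depth"]
        for sp in com.species
    }
    ab = species_abundance(depths)
    assert abs(ab["st"] - 0.8) < 0.03 and abs(ab["ld"] - 0.2) < 0.03


def test_plasmid_copy_number(default_sim):
    assert plasmid_copy_number(320.0, 100.0) == pytest.approx(3.2)
    assert plasmid_copy_number(7.0, 7.0) == 1.0
    with pytest.raises(ValueError):
        plasmid_copy_number(10.0, 0.0)
    # simulated PCN 0.2 recovered within +-20%
    aln = default_sim["alignments"]
    pcn = plasmid_copy_number(
        aln.coverage_stats("pWS58L")["mean_depth"],
        aln.coverage_stats("ldelb")["mean_depth"],
    )
    assert abs(pcn - 0.2) / 0.2 < 0.20


def test_pnps_arithmetic_and_undefined(toy_genome):
    g = toy_genome
    gene = next(gn for gn in g.genes if gn.copy_class == "single_copy")
    # two nonsyn and two syn observations inside one gene
    rows = []
    found_syn = found_nonsyn = 0
    for pos in range(gene.start, gene.end):
        for alt in "ACGT":
            if alt == g.sequence[pos]:
                continue
            ann = classify_substitution(g, pos, alt)
            if ann.synonymy == "synonymous" and found_syn < 2:
                found_syn += 1
            elif ann.synonymy == "non_synonymous" and found_nonsyn < 2:
                found_nonsyn += 1
            else:
                continue
            rows.append({"ref_id": g.genome_id, "pos": pos, "ref": g.sequence[pos],
                         "alt": alt, "ao_s1": 10, "dp_s1": 100, "aaf_s1": 0.1})
        if found_syn == 2 and found_nonsyn == 2:
            break
    table = annotate_snvs(SnvTable(pd.DataFrame(rows).drop_duplicates(["pos", "alt"]), ["s1"]), g)
    out = pnps(table, g)
    row = out[out.gene_id == gene.gene_id].iloc[0]
    n_sites, s_sites = count_syn_nonsyn_sites(g, gene)
    assert row.pnps == pytest.approx((2 / n_sites) / (2 / s_sites))
    # empty observation set -> undefined, not infinite
    empty = SnvTable(pd.DataFrame(columns=table.df.columns), ["s1"])
    out2 = pnps(annotate_snvs(empty, g), g)
    assert np.isnan(out2[out2.gene_id == gene.gene_id].pnps.iloc[0])


def test_site_counts_match_exhaustive_enumeration(toy_genome):
    """N/S site counts equal exhaustive 3-substitutions-per-position enumeration."""
    g = toy_genome
    gene = g.genes[0]
    n_sites, s_sites = count_syn_nonsyn_sites(g, gene)
    seq = g.sequence[gene.start : gene.end]
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    n = s = 0
    for ci in range(0, len(seq), 3):
        codon = seq[ci : ci + 3]
        aa = str(Seq(codon).translate())
        for p in range(3):
            for b in "ACGT":
                if b == codon[p]:
                    continue
                alt = codon[:p] + b + codon[p + 1 :]
                if str(Seq(alt).translate()) == aa:
                    s += 1
                else:
                    n += 1
    assert n_sites == pytest.approx(n / 3)
    assert s_sites == pytest.approx(s / 3)
    assert n_sites + s_sites == pytest.approx(gene.length)
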