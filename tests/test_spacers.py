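"""CRISPR array detection, spacer fishing, dereplication, ANI, turnover, dating."""

import numpy as np
import pytest

import starterdyn as sd
from starterdyn.community import simulate_spacer_acquisition
from starterdyn.dna import random_seq, revcomp
from starterdyn.spacers import (
    SpacerRecord,
    compute_ani,
    dereplicate_spacers,
    extract_metagenomic_spacers,
    find_crispr_arrays,
    metagenome_isolate_accounting,
    novel_spacers,
    shared_spacer_fraction,
    spacer_age,
    spacer_turnover_rate,
    ungapped_identity,
)


def _planted_array(rng, n_repeats, repeat_len=36, spacer_len=30, mutate=False):
    """Random genome with one planted array; returns (seq, repeat, spacers, start)."""
    repeat = random_seq(rng, repeat_len)
    spacers = [random_seq(rng, spacer_len) for _ in range(n_repeats - 1)]
    body = "".join(repeat + s for s in spacers) + repeat
    if mutate:
        body = list(body)
        for i in range(n_repeats):
            off = i * (repeat_len + spacer_len)
            j = int(rng.integers(0, repeat_len))
            body[off + j] = "ACGT"[("ACGT".index(body[off + j]) + 1) % 4]
        body = "".join(body)
    left = random_seq(rng, 3000)
    right = random_seq(rng, 3000)
    return left + body + right, repeat, spacers, len(left)


def test_planted_array_detected_with_spacers_verbatim():
    rng = np.random.default_rng(1)
    seq, repeat, spacers, start = _planted_array(rng, 10)
    arrays = find_crispr_arrays(seq)
    assert len(arrays) == 1
    arr = arrays[0]
    assert arr.repeat == repeat
    assert arr.spacers == spacers  # exactly 9 spacers, verbatim
    assert arr.start == start


def test_two_repeat_copies_not_reported():
    rng = np.random.default_rng(2)
    seq, _, _, _ = _planted_array(rng, 2)
    assert find_crispr_arrays(seq, min_repeats=3) == []


def test_mutated_repeats_consensus_and_recall():
    """1 mismatch per repeat copy: consensus equals planted repeat, 100% recall."""
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        seq, repeat, spacers, _ = _planted_array(rng, 8, mutate=True)
        arrays = find_crispr_arrays(seq)
        assert len(arrays) == 1, seed
        assert arrays[0].repeat == repeat, seed
        assert arrays[0].spacers == spacers, seed


def test_extract_exact_construct_and_strand():
    rng = np.random.default_rng(3)
    repeat = random_seq(rng, 36)
    spacer = random_seq(rng, 30)
    read = repeat + spacer + repeat
    res = extract_metagenomic_spacers([("r1", read)], {"CR1": repeat})
    assert [r.sequence for r in res.records] == [spacer]
    assert res.records[0].array_id == "CR1"
    # reverse complement read emits the spacer in canonical orientation
    res_rc = extract_metagenomic_spacers([("r1", revcomp(read))], {"CR1": repeat})
    assert [r.sequence for r in res_rc.records] == [spacer]


def test_extract_partial_flanks_and_ambiguity():
    rng = np.random.default_rng(4)
    r1, r2 = random_seq(rng, 36), random_seq(rng, 36)
    spacer = random_seq(rng, 30)
    # 12 bp of repeat on each side is enough (min_flank=10)
    read = r1[-12:] + spacer + r1[:12]
    res = extract_metagenomic_spacers([("r", read)], {"CR1": r1})
    assert [r.sequence for r in res.records] == [spacer]
    # a read matching repeats of two different arrays is skipped
    chimeric = r1 + spacer + r2
    res2 = extract_metagenomic_spacers([("r", chimeric)], {"CR1": r1, "CR2": r2})
    assert res2.records == [] and res2.n_ambiguous == 1


def test_extraction_recall_and_precision_on_simulation(spacer_sim):
    res = extract_metagenomic_spacers(spacer_sim["reads"], spacer_sim["consensi"])
    got = {r.sequence for r in res.records}
    truth = spacer_sim["truth_spacers"]
    assert len(truth & got) / len(truth) == 1.0  # recall
    assert len(got & truth) / len(got) == 1.0  # precision


def test_dereplicate_identity_boundary():
    a = "A" * 27 + "CCC"
    b3 = "A" * 27 + "GGG"  # 27/30 = 90.0% identical -> same cluster (inclusive)
    recs = [SpacerRecord(s, "CR1", "metagenome", "m") for s in (a, b3)]
    assert len(dereplicate_spacers(recs)) == 1
    b4 = "A" * 26 + "GGGG"  # 26/30 = 86.7% -> below threshold, separate
    recs2 = [SpacerRecord(s, "CR1", "metagenome", "m") for s in (a, b4)]
    assert len(dereplicate_spacers(recs2)) == 2


def _oracle_greedy(seqs, identity=0.9):
    """Independent greedy clustering with a hand-rolled identity function."""

    def ident(a, b):
        if len(a) > len(b):
            a, b = b, a
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[c] for c in reversed(a))
        best = 0
        for q in (a, rc):
            for off in range(len(b) - len(q) + 1):
                m = sum(1 for x, y in zip(q, b[off : off + len(q)]) if x == y)
                best = max(best, m)
        return best / len(a)

    ordered = sorted(seqs, key=lambda s: (-len(s), s))
    reps = []
    assign = []
    for s in ordered:
        for ci, r in enumerate(reps):
            if ident(s, r) >= identity:
                assign.append(ci)
                break
        else:
            reps.append(s)
            assign.append(len(reps) - 1)
    return len(reps), assign


def test_greedy_clustering_matches_exhaustive_oracle():
    """200 random + 50 mutated spacers: cluster count equals pairwise oracle."""
    rng = np.random.default_rng(5)
    seqs = [random_seq(rng, int(rng.integers(25, 46))) for _ in range(200)]
    for _ in range(50):
        src = seqs[int(rng.integers(0, 200))]
        m = list(src)
        for _ in range(int(rng.integers(0, max(1, len(m) // 10) + 1))):
            j = int(rng.integers(0, len(m)))
            m[j] = "ACGT"[int(rng.integers(4))]
        seqs.append("".join(m))
    recs = [SpacerRecord(s, "CR1", "metagenome", "m") for s in seqs]
    clusters = dereplicate_spacers(recs)
    n_oracle, _ = _oracle_greedy(seqs)
    assert len(clusters) == n_oracle


def test_dereplication_idempotent():
    rng = np.random.default_rng(6)
    seqs = [random_seq(rng, 30) for _ in range(80)]
    recs = [SpacerRecord(s, "CR1", "metagenome", "m") for s in seqs]
    clusters = dereplicate_spacers(recs)
    reps = [c.representative for c in clusters]
    assert len(dereplicate_spacers(reps)) == len(clusters)


def test_shared_spacer_fraction():
    rng = np.random.default_rng(7)
    a = [SpacerRecord(random_seq(rng, 30), "CR1", "isolate_genome", "A") for _ in range(20)]
    same = [SpacerRecord(r.sequence, "CR1", "isolate_genome", "B") for r in a]
    assert shared_spacer_fraction(a, same) == 1.0
    disjoint = [SpacerRecord(random_seq(rng, 30), "CR1", "isolate_genome", "B") for _ in range(20)]
    assert shared_spacer_fraction(a, disjoint) == 0.0
    b = same[:10] + [
        SpacerRecord(random_seq(rng, 30), "CR1", "isolate_genome", "B") for _ in range(10)
    ]
    assert shared_spacer_fraction(a, b) == pytest.approx(10 / 30)
    # symmetric
    assert shared_spacer_fraction(b, a) == pytest.approx(10 / 30)


def test_compute_ani():
    rng = np.random.default_rng(8)
    a = random_seq(rng, 20000)
    assert compute_ani(a, a) == 100.0
    # 1% planted substitutions -> ANI 99.0 +- 0.2
    b = list(a)
    nmut = 0
    for i in range(len(b)):
        if rng.random() < 0.01:
            b[i] = "ACGT"[("ACGT".index(b[i]) + 1 + int(rng.integers(3))) % 4]
            nmut += 1
    ani = compute_ani(a, "".join(b))
    assert ani == pytest.approx(100.0 * (1 - nmut / len(b)), abs=0.05)
    assert abs(ani - 99.0) < 0.2
    # unrelated sequences -> undefined
    assert compute_ani(a, random_seq(np.random.default_rng(9), 20000)) is None


def test_ani_monotone_in_mutation_rate():
    rng = np.random.default_rng(10)
    a = random_seq(rng, 10000)
    anis = []
    for rate in (0.0, 0.01, 0.03, 0.08):
        b = [
            ("ACGT"[(("ACGT".index(c)) + 1 + int(rng.integers(3))) % 4] if rng.random() < rate else c)
            for c in a
        ]
        anis.append(compute_ani(a, "".join(b)))
    assert all(x >= y for x, y in zip(anis, anis[1:]))


def test_novel_spacers_rules():
    rng = np.random.default_rng(11)
    base_seqs = [random_seq(rng, 30) for _ in range(20)]
    base = dereplicate_spacers(
        [SpacerRecord(s, "CR1", "isolate_genome", "iso") for s in base_seqs]
    )
    # all sample spacers in baseline -> nothing new
    sample = dereplicate_spacers(
        [SpacerRecord(s, "CR1", "metagenome", "s1") for s in base_seqs[:5]]
    )
    assert novel_spacers(sample, base) == []
    # exactly 10% divergent from a baseline spacer -> NOT new (inclusive)
    m = list(base_seqs[0])
    for j in (0, 10, 20):
        m[j] = {"A": "C", "C": "A", "G": "T", "T": "G"}[m[j]]
    near = dereplicate_spacers([SpacerRecord("".join(m), "CR1", "metagenome", "s1")])
    assert novel_spacers(near, base) == []
    # a genuinely new spacer is reported
    fresh = dereplicate_spacers(
        [SpacerRecord(random_seq(rng, 30), "CR1", "metagenome", "s1")]
    )
    assert len(novel_spacers(fresh, base)) == 1


def test_private_leader_spacers_detected_as_novel(spacer_sim):
    """Lineage-private leader spacers are new relative to the base-array catalog."""
    com = spacer_sim["community"]
    res = extract_metagenomic_spacers(spacer_sim["reads"], spacer_sim["consensi"])
    sample_clusters = dereplicate_spacers(res.records)
    base_records = [
        SpacerRecord(s, arr.array_id, "isolate_genome", g.genome_id)
        for g in com.genomes.values()
        for arr in g.arrays
        for s in arr.spacers
    ]
    baseline = dereplicate_spacers(base_records)
    new = novel_spacers(sample_clusters, baseline)
    private = {
        s
        for sp in com.species
        for st in sp.strains
        for seqs in st.private_spacers.values()
        for s in seqs
    }
    assert {c.representative.sequence for c in new} == private


def test_turnover_rate_examples():
    # 17 new spacers spread singly over 5 replicate samples, ~123 generations
    est = spacer_turnover_rate([4, 4, 3, 3, 3], 123)
    assert round(est.mean_rate, 3) == 0.028
    assert spacer_turnover_rate([0, 0, 0], 123).mean_rate == 0.0
    est2 = spacer_turnover_rate([2, 3, 4, 3, 5], 100)
    assert est2.mean_rate == pytest.approx(0.034)
    rates = np.array([2, 3, 4, 3, 5]) / 100
    assert est2.sd_rate == pytest.approx(float(np.std(rates, ddof=1)))
    with pytest.raises(ValueError):
        spacer_turnover_rate([1], 0)


def test_spacer_age_arithmetic():
    assert spacer_age(0, 0.024) == 0.0
    assert spacer_age(24, 0.024) == pytest.approx(1000.0)
    with pytest.raises(ValueError):
        spacer_age(5, 0.0)


def test_spacer_age_against_acquisition_simulation():
    """Leader-distance dating tracks true acquisition ages for distances >= 10."""
    rng = np.random.default_rng(12)
    rate, generations = 0.05, 2000.0
    rel_errors = []
    for _ in range(30):
        ages = simulate_spacer_acquisition(rate, generations, rng)
        for dist, true_age in enumerate(ages):
            if dist >= 10:
                est = spacer_age(dist, rate)
                rel_errors.append(abs(est - true_age) / true_age)
    assert np.median(rel_errors) <= 0.30


def test_accounting_worked_examples():
    out = metagenome_isolate_accounting(354, 121)
    assert round(out["percent_absent"]) == 34
    out2 = metagenome_isolate_accounting(131, 64)
    assert round(out2["percent_absent"]) == 49
    assert metagenome_isolate_accounting(50, 0)["percent_absent"] == 0.0
    with pytest.raises(ValueError):
        metagenome_isolate_accounting(0, 0)


def test_accounting_from_clusters():
    rng = np.random.default_rng(13)
    iso = [SpacerRecord(random_seq(rng, 30), "CR1", "isolate_genome", "iso") for _ in range(10)]
    meta_seqs = [r.sequence for r in iso[:6]] + [random_seq(rng, 30) for _ in range(4)]
    meta = dereplicate_spacers(
        [SpacerRecord(s, "CR1", "metagenome", "m") for s in meta_seqs]
    )
    out = metagenome_isolate_accounting(meta, iso)
    assert out["n_metagenome"] == 10
    assert out["n_absent_from_isolates"] == 4
    assert out["percent_absent"] == pytest.approx(40.0)


def test_ungapped_identity_symmetry():
    rng = np.random.default_rng(14)
    for _ in range(20):
        a = random_seq(rng, int(rng.integers(20, 40)))
        b = random_seq(rng, int(rng.integers(20, 40)))
        assert ungapped_identity(a, b) == pytest.approx(ungapped_identity(b, a))
        assert ungapped_identity(a, revcomp(a)) == 1.0
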