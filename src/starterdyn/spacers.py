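"""CRISPR array detection, metagenomic spacer fishing, dereplication,
turnover rates, and leader-distance spacer dating.

Arrays are found by locating regularly spaced near-identical repeats
(>= ``min_repeats`` copies, 20-50 nt, members >= 90% identical to a
column-majority consensus) separated by 20-60 nt spacers.  Metagenomic
spacers are fished from raw reads by matching the repeat consensus on
both strands and emitting the sequence between two repeat anchors (or a
full spacer flanked by at least ``min_flank`` repeat bases on each side).
Dereplication is greedy longest-first clustering at 90% ungapped identity
over the shorter sequence, both orientations, mirroring cd-hit-est
conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import edlib
import numpy as np

from .community import CrisprArray, Genome
from .dna import decode, encode, kmer_codes, revcomp
from .simulate import SampleReads


@dataclass
class SpacerRecord:
    sequence: str  # canonical orientation = orientation of the repeat consensus
    array_id: Optional[str]
    source: str  # isolate_genome | metagenome
    source_id: str
    leader_distance: Optional[int] = None  # 0 = newest; None = unknown


@dataclass
class SpacerCluster:
    cluster_id: str
    representative: SpacerRecord
    members: List[SpacerRecord]
    identity_threshold: float = 0.90

    @property
    def sources(self) -> Set[str]:
        return {m.source for m in self.members}

    @property
    def source_ids(self) -> Set[str]:
        return {m.source_id for m in self.members}


@dataclass
class TurnoverEstimate:
    species_id: str
    new_counts: List[int]
    generations: float
    per_sample_rates: List[float]
    mean_rate: float
    sd_rate: float


# ---------------------------------------------------------------------------
# identity


def ungapped_identity(a: str, b: str) -> float:
    """Best ungapped identity over the shorter sequence, both orientations."""
    if not a or not b:
        return 0.0
    if len(a) > len(b):
        a, b = b, a
    ea = encode(a)
    best = 0
    for query in (ea, (3 - ea)[::-1]):
        eb = encode(b)
        la = len(query)
        for s in range(len(eb) - la + 1):
            m = int(np.count_nonzero(eb[s : s + la] == query))
            if m > best:
                best = m
        if best == la:
            break
    return best / len(a)


# ---------------------------------------------------------------------------
# array detection in assembled genomes


def _sliding_mismatches(seq_codes: np.ndarray, pattern_codes: np.ndarray) -> np.ndarray:
    """Mismatch count of ``pattern`` at every offset of ``seq`` (ungapped)."""
    k = len(pattern_codes)
    if len(seq_codes) < k:
        return np.empty(0, dtype=np.int32)
    windows = np.lib.stride_tricks.sliding_window_view(seq_codes, k)
    return (windows != pattern_codes).sum(axis=1).astype(np.int32)


def _refine_repeat(
    codes: np.ndarray,
    occ: List[int],
    length: int,
    max_repeat_len: int,
    n: int,
    threshold: float = 0.7,
) -> Tuple[List[int], str]:
    """Trim/extend repeat boundaries by column conservation over all copies."""

    def col(off: int) -> Tuple[float, int]:
        vals = [codes[p + off] for p in occ if 0 <= p + off < n]
        if len(vals) < len(occ):
            return 0.0, 0
        u, c = np.unique(vals, return_counts=True)
        j = int(c.argmax())
        return c[j] / len(vals), int(u[j])

    left, right = 0, length
    while right - left > 20 and col(left)[0] < threshold:
        left += 1
    while right - left > 20 and col(right - 1)[0] < threshold:
        right -= 1
    while right - left < max_repeat_len and col(left - 1)[0] >= threshold:
        left -= 1
    while right - left < max_repeat_len and col(right)[0] >= threshold:
        right += 1
    consensus = decode(np.array([col(o)[1] for o in range(left, right)], dtype=np.uint8))
    return [p + left for p in occ], consensus


def find_crispr_arrays(
    genome: Union[Genome, str],
    min_repeats: int = 3,
    k: int = 20,
    min_period: int = 40,
    max_period: int = 120,
    max_repeat_len: int = 50,
    min_spacer_len: int = 15,
    max_spacer_len: int = 70,
) -> List[CrisprArray]:
    """Detect CRISPR arrays as regularly alternating repeat/spacer runs.

    Returns arrays with locus, column-majority repeat consensus, and
    ordered spacers.  Leader side cannot be inferred from sequence alone
    and is reported as "left" by convention (spacer order follows genome
    coordinates).
    """
    seq = genome.sequence if isinstance(genome, Genome) else genome
    gid = genome.genome_id if isinstance(genome, Genome) else "seq"
    codes = encode(seq)
    n = len(codes)
    if n < k:
        return []
    kms = kmer_codes(codes, k)
    order = np.argsort(kms, kind="stable")
    sorted_k = kms[order]
    # groups of identical k-mers with >= 2 occurrences and CRISPR-like spacing
    boundaries = np.nonzero(np.diff(sorted_k))[0] + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(sorted_k)]))
    anchors: List[np.ndarray] = []
    for s, e in zip(starts, ends):
        if e - s < 2:
            continue
        pos = np.sort(order[s:e])
        gaps = np.diff(pos)
        if ((gaps >= min_period) & (gaps <= max_period)).sum() >= 1:
            anchors.append(pos)
    if not anchors:
        return []
    # merge anchor intervals into candidate regions
    intervals = sorted((int(p[0]), int(p[-1]) + k, i) for i, p in enumerate(anchors))
    regions: List[Tuple[int, int, List[int]]] = []
    for s, e, i in intervals:
        if regions and s <= regions[-1][1] + max_period:
            rs, re, idxs = regions[-1]
            regions[-1] = (rs, max(re, e), idxs + [i])
        else:
            regions.append((s, e, [i]))

    arrays: List[CrisprArray] = []
    for rs, re, idxs in regions:
        # best anchor: most occurrences with CRISPR-like spacing
        best = max(
            (anchors[i] for i in idxs),
            key=lambda p: (
                ((np.diff(p) >= min_period) & (np.diff(p) <= max_period)).sum(),
                len(p),
                -int(p[0]),
            ),
        )
        pos = [int(p) for p in best]
        m = len(pos)
        # column-wise extension of the aligned seed block
        def col_score(off: int) -> Tuple[float, int]:
            col = [codes[p + off] for p in pos if 0 <= p + off < n]
            if len(col) < m:
                return 0.0, 0
            vals, cnt = np.unique(col, return_counts=True)
            j = int(cnt.argmax())
            return cnt[j] / len(col), int(vals[j])

        left, right = 0, k  # consensus spans [left, right) relative to seed
        cons = [codes[pos[0] + o] for o in range(k)]
        window: List[float] = []
        off = k
        while right - left < max_repeat_len:
            sc, base = col_score(off)
            window = (window + [sc])[-4:]
            if sc < 2 / 3 or (len(window) == 4 and np.mean(window) < 0.75):
                break
            cons.append(base)
            right = off + 1
            off += 1
        window = []
        off = -1
        while right - left < max_repeat_len:
            sc, base = col_score(off)
            window = (window + [sc])[-4:]
            if sc < 2 / 3 or (len(window) == 4 and np.mean(window) < 0.75):
                break
            cons.insert(0, base)
            left = off
            off -= 1
        consensus = decode(np.array(cons, dtype=np.uint8))
        if not (20 <= len(consensus) <= max_repeat_len):
            continue
        # rescan the neighbourhood for all consensus occurrences
        lo = max(0, rs - 2 * max_period)
        hi = min(n, re + 2 * max_period)
        sub = codes[lo:hi]
        mm = _sliding_mismatches(sub, np.array(cons, dtype=np.uint8))
        thr = int(np.floor(0.1 * len(consensus)))
        occ: List[int] = []
        i = 0
        while i < len(mm):
            if mm[i] <= thr:
                # take the local best within the repeat span
                j = int(np.argmin(mm[i : i + len(consensus)])) + i
                occ.append(lo + j)
                i = j + len(consensus) + min_spacer_len
            else:
                i += 1
        if len(occ) < min_repeats:
            continue
        # refine boundaries using every recovered copy: the seed block may
        # hold too few copies to call the repeat edges reliably
        occ, consensus = _refine_repeat(
            codes, occ, len(consensus), max_repeat_len, n
        )
        if not (20 <= len(consensus) <= max_repeat_len) or len(occ) < min_repeats:
            continue
        spacers = []
        ok = True
        for a, b in zip(occ, occ[1:]):
            gap = b - (a + len(consensus))
            if not (min_spacer_len <= gap <= max_spacer_len):
                ok = False
                break
            spacers.append(seq[a + len(consensus) : b])
        if not ok or not spacers:
            continue
        arrays.append(
            CrisprArray(
                f"{gid}_array{len(arrays) + 1}",
                consensus,
                spacers,
                "left",
                occ[0],
                occ[-1] + len(consensus),
                0,
            )
        )
    arrays.sort(key=lambda a: a.start)
    for i, a in enumerate(arrays):
        a.array_id = f"{gid}_array{i + 1}"
    return arrays


def isolate_spacer_records(
    arrays: Iterable[CrisprArray], source_id: str, leader_known: bool = True
) -> List[SpacerRecord]:
    """Flatten detected/known arrays into spacer records (isolate source)."""
    out = []
    for arr in arrays:
        for i, s in enumerate(arr.spacers):
            out.append(
                SpacerRecord(
                    s, arr.array_id, "isolate_genome", source_id,
                    i if leader_known else None,
                )
            )
    return out


# ---------------------------------------------------------------------------
# metagenomic spacer fishing


@dataclass
class ExtractionResult:
    records: List[SpacerRecord]
    n_ambiguous: int = 0
    n_reads_scanned: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _repeat_anchors(
    read: np.ndarray, rep: np.ndarray, max_mm_frac: float, min_flank: int
) -> List[Tuple[int, int, bool, bool]]:
    """Repeat matches in a read: (start, end, covers_rep_end, covers_rep_start).

    Includes partial matches at read edges (>= min_flank repeat bases).
    """
    L, rl = len(read), len(rep)
    anchors = []
    if L >= rl:
        mm = _sliding_mismatches(read, rep)
        thr = int(np.floor(max_mm_frac * rl))
        for i in np.nonzero(mm <= thr)[0]:
            anchors.append((int(i), int(i) + rl, True, True))
    # read starts inside a repeat: read prefix == repeat suffix
    for l in range(min(rl - 1, L), min_flank - 1, -1):
        thr = int(np.floor(max_mm_frac * l))
        if int(np.count_nonzero(read[:l] != rep[rl - l :])) <= thr:
            anchors.append((0, l, True, False))
            break
    # read ends inside a repeat: read suffix == repeat prefix
    for l in range(min(rl - 1, L), min_flank - 1, -1):
        thr = int(np.floor(max_mm_frac * l))
        if int(np.count_nonzero(read[L - l :] != rep[:l])) <= thr:
            anchors.append((L - l, L, False, True))
            break
    anchors.sort()
    return anchors


def _seed_strings(repeat: str, seed_len: int = 10) -> List[str]:
    """Fast prefilter seeds: prefix, middle, suffix of the repeat.

    Prefix/suffix seeds of ``min_flank`` length keep reads whose only
    repeat content is a short edge flank detectable.
    """
    if len(repeat) <= seed_len:
        return [repeat]
    offs = {0, (len(repeat) - seed_len) // 2, len(repeat) - seed_len}
    return [repeat[o : o + seed_len] for o in sorted(offs)]


def extract_metagenomic_spacers(
    reads: Union[SampleReads, Iterable[Tuple[str, str]]],
    repeat_consensi: Mapping[str, str],
    max_mismatch_frac: float = 0.1,
    min_flank: int = 10,
    min_spacer_len: int = 20,
    max_spacer_len: int = 60,
    sample_id: Optional[str] = None,
) -> ExtractionResult:
    """Fish repeat-flanked spacers out of raw reads.

    A spacer is emitted when a read contains repeat-spacer-repeat, or a
    full spacer flanked by >= ``min_flank`` repeat bases on each side; it
    is assigned to the array of the matching repeat and emitted in the
    orientation of that repeat consensus.  Reads matched by repeats of two
    different arrays are skipped and counted as ambiguous.
    """
    if isinstance(reads, SampleReads):
        sid = sample_id or reads.sample_id
        pairs = [
            (f"{n}/1", reads.r1[i]) for i, n in enumerate(reads.names)
        ] + [(f"{n}/2", reads.r2[i]) for i, n in enumerate(reads.names)]
    else:
        sid = sample_id or "metagenome"
        pairs = [(n, encode(s)) for n, s in reads]
    reps = {
        aid: (encode(rep), encode(revcomp(rep))) for aid, rep in repeat_consensi.items()
    }
    seeds = {
        aid: (
            _seed_strings(rep, max(8, min_flank)),
            _seed_strings(revcomp(rep), max(8, min_flank)),
        )
        for aid, rep in repeat_consensi.items()
    }
    records: List[SpacerRecord] = []
    n_ambiguous = 0
    for name, codes in pairs:
        read_str = decode(codes)
        hit_arrays = []
        for aid, (fwd_seeds, rev_seeds) in seeds.items():
            if any(s in read_str for s in fwd_seeds):
                hit_arrays.append((aid, 0))
            elif any(s in read_str for s in rev_seeds):
                hit_arrays.append((aid, 1))
        if not hit_arrays:
            continue
        if len({a for a, _ in hit_arrays}) > 1:
            n_ambiguous += 1
            continue
        aid, orient = hit_arrays[0]
        q = codes if orient == 0 else (3 - codes)[::-1]
        rep = reps[aid][0]
        anchors = _repeat_anchors(q, rep, max_mismatch_frac, min_flank)
        for (s1, e1, covers_end, _), (s2, e2, _, covers_start) in zip(
            anchors, anchors[1:]
        ):
            if not (covers_end and covers_start):
                continue
            gap = s2 - e1
            if min_spacer_len <= gap <= max_spacer_len and (e1 - s1) >= min_flank and (
                e2 - s2
            ) >= min_flank:
                records.append(
                    SpacerRecord(decode(q[e1:s2]), aid, "metagenome", sid, None)
                )
    return ExtractionResult(records, n_ambiguous, len(pairs))


# ---------------------------------------------------------------------------
# dereplication and set comparisons


def dereplicate_spacers(
    records: Sequence[SpacerRecord], identity: float = 0.90
) -> List[SpacerCluster]:
    """Greedy longest-first clustering at ``identity`` (inclusive boundary).

    Each record joins the first existing cluster whose representative it
    matches at >= identity (ungapped, over the shorter sequence, both
    orientations); otherwise it founds a new cluster.  Order: length
    descending, ties by lexicographic sequence — deterministic.
    """
    if not records:
        raise ValueError("no spacer records to dereplicate")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.sequence))
    clusters: List[SpacerCluster] = []
    for rec in ordered:
        placed = False
        for cl in clusters:
            if ungapped_identity(rec.sequence, cl.representative.sequence) >= identity:
                cl.members.append(rec)
                placed = True
                break
        if not placed:
            clusters.append(
                SpacerCluster(f"SC{len(clusters) + 1}", rec, [rec], identity)
            )
    return clusters


def shared_spacer_fraction(
    genome_a_spacers: Sequence[SpacerRecord],
    genome_b_spacers: Sequence[SpacerRecord],
    identity: float = 0.90,
    denominator: str = "union",
) -> float:
    """Fraction of 90%-identity spacer clusters shared between two genomes.

    ``denominator="union"`` gives the Jaccard form |shared| / |union
    clusters|; ``denominator="a"`` gives |shared| / |clusters with an A
    member|.
    """
    if not genome_a_spacers or not genome_b_spacers:
        raise ValueError("both genomes need at least one spacer")
    tagged = [
        SpacerRecord(r.sequence, r.array_id, r.source, "_A", r.leader_distance)
        for r in genome_a_spacers
    ] + [
        SpacerRecord(r.sequence, r.array_id, r.source, "_B", r.leader_distance)
        for r in genome_b_spacers
    ]
    clusters = dereplicate_spacers(tagged, identity)
    shared = sum(1 for c in clusters if {"_A", "_B"} <= c.source_ids)
    if denominator == "union":
        return shared / len(clusters)
    if denominator == "a":
        with_a = sum(1 for c in clusters if "_A" in c.source_ids)
        return shared / with_a
    raise ValueError("denominator must be 'union' or 'a'")


def compute_ani(
    genome_a: Union[Genome, str],
    genome_b: Union[Genome, str],
    fragment: int = 1000,
    min_fragment_identity: float = 0.80,
) -> Optional[float]:
    """Fragment-mapping average nucleotide identity, in percent.

    Tiles each genome into ``fragment``-length pieces, aligns each piece to
    its best locus in the other genome (edit distance, both strands), and
    averages the identities of pieces aligning at >= 80%; the reported ANI
    is the mean of both directions.  Returns None when no fragment aligns.
    """

    def _seq(g):
        return g.sequence if isinstance(g, Genome) else g

    a, b = _seq(genome_a), _seq(genome_b)
    if len(a) < 2 * fragment or len(b) < 2 * fragment:
        raise ValueError("genomes must span at least two fragments")

    def _direction(src: str, dst: str) -> List[float]:
        idents = []
        dst_rc = revcomp(dst)
        for s in range(0, len(src) - fragment + 1, fragment):
            frag = src[s : s + fragment]
            best = None
            for target in (dst, dst_rc):
                res = edlib.align(frag, target, mode="HW", task="distance")
                if res["editDistance"] >= 0:
                    ident = 1.0 - res["editDistance"] / fragment
                    best = ident if best is None else max(best, ident)
            if best is not None and best >= min_fragment_identity:
                idents.append(best)
        return idents

    fw = _direction(a, b)
    bw = _direction(b, a)
    if not fw and not bw:
        return None
    means = [100.0 * float(np.mean(d)) for d in (fw, bw) if d]
    return float(np.mean(means))


def novel_spacers(
    sample_clusters: Sequence[SpacerCluster],
    baseline_clusters: Sequence[SpacerCluster],
    identity: float = 0.90,
) -> List[SpacerCluster]:
    """Sample clusters with no member matching any baseline cluster at >= 90%."""
    baseline_seqs = [m.sequence for c in baseline_clusters for m in c.members]
    out = []
    for cl in sample_clusters:
        hit = any(
            ungapped_identity(m.sequence, b) >= identity
            for m in cl.members
            for b in baseline_seqs
        )
        if not hit:
            out.append(cl)
    return out


def spacer_turnover_rate(
    new_counts: Sequence[int],
    generations: float = 123.0,
    species_id: str = "species",
) -> TurnoverEstimate:
    """Per-sample rate = new spacers / generations; mean and SD over samples."""
    if generations <= 0:
        raise ValueError("generations must be positive")
    if not len(new_counts):
        raise ValueError("need at least one propagation sample")
    rates = [c / generations for c in new_counts]
    sd = float(np.std(rates, ddof=1)) if len(rates) > 1 else 0.0
    return TurnoverEstimate(
        species_id, list(new_counts), generations, rates, float(np.mean(rates)), sd
    )


def spacer_age(leader_distance: int, rate: float) -> float:
    """Generations since acquisition: leader distance / turnover rate.

    Distance is counted in spacer positions from the leader (0 = newest).
    Ages are minimum estimates: distal spacer loss is not modelled.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if leader_distance < 0:
        raise ValueError("leader_distance must be >= 0")
    return leader_distance / rate


def metagenome_isolate_accounting(
    metagenome_clusters: Union[int, Sequence[SpacerCluster]],
    isolates: Union[int, Sequence[SpacerRecord]],
    identity: float = 0.90,
) -> Dict[str, float]:
    """How many metagenomic spacer clusters are absent from the isolates.

    Accepts either counts (n_metagenome, n_absent) or a cluster list plus
    isolate spacer records to compare against.
    """
    if isinstance(metagenome_clusters, (int, np.integer)):
        n_meta = int(metagenome_clusters)
        n_absent = int(isolates)
    else:
        iso_seqs = [r.sequence for r in isolates]
        n_meta = len(metagenome_clusters)
        n_absent = 0
        for cl in metagenome_clusters:
            if not any(
                ungapped_identity(m.sequence, s) >= identity
                for m in cl.members
                for s in iso_seqs
            ):
                n_absent += 1
    if n_meta == 0:
        raise ValueError("no metagenomic spacers")
    return {
        "n_metagenome": n_meta,
        "n_absent_from_isolates": n_absent,
        "percent_absent": 100.0 * n_absent / n_meta,
    }


def rarefy_records(
    records_by_sample: Mapping[str, Sequence[SpacerRecord]], seed: int = 0
) -> Dict[str, List[SpacerRecord]]:
    """Optional subsampling to the smallest per-sample spacer count (seeded)."""
    rng = np.random.default_rng(seed)
    floor = min(len(v) for v in records_by_sample.values())
    out = {}
    for s, recs in sorted(records_by_sample.items()):
        idx = rng.choice(len(recs), size=floor, replace=False)
        out[s] = [recs[i] for i in sorted(idx)]
    return out
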