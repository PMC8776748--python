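"""Temperate phage state estimation from read mappings.

Free and integrated phage are quantified from three signals: genome
coverage ratios (phage depth / host depth = copies per bacterium),
phage-bacteria spanning read pairs (one mate primary on a phage replicon,
the other on a bacterial replicon — evidence of an integrated prophage and
of its attB site), and spacer vs protospacer read support against a
repeat-spacer-repeat construct database (repeat-flanked matches evidence
the host array; spacer-only matches evidence free phage).

The lysogeny fractions convert spanning-pair counts into a junction depth:
a fully-host/fully-phage mate pair requires a fragment longer than two
read lengths, so the effective window per junction is E[(F - 2R)+] under
the Normal insert model; with two junctions per integration site the
estimator  junction_depth = n_pairs * 2R / (2 * E[(F - 2R)+])  is unbiased
for the depth of lysogen molecules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import norm

from .dna import decode, encode, revcomp
from .mapping import AlignmentSet
from .simulate import SampleReads
from .snv import SnvKey
from .spacers import SpacerCluster, _sliding_mismatches


@dataclass
class IntegrationSite:
    host_ref_id: str
    host_pos: int  # estimated attB junction, 0-based
    phage_ref_id: str
    phage_end: str  # 'left' or 'right' (dominant junction side)
    spanning_pair_count: int
    n_left: int = 0
    n_right: int = 0
    lineage_support: Dict[str, int] = field(default_factory=dict)


@dataclass
class PhageStateReport:
    sample_id: str
    phage_id: str
    phage_mean_depth: float
    host_mean_depth: float
    copies_per_bacterium: float
    integrated_cell_fraction: float
    integrated_phage_fraction: float
    sites: List[IntegrationSite] = field(default_factory=list)


@dataclass
class ProtospacerQuant:
    cluster_id: str
    spacer_read_count: int
    protospacer_read_count: int
    sample_id: Optional[str] = None


# ---------------------------------------------------------------------------
# read partition and coverage ratios


def partition_unmapped(
    alignments: AlignmentSet, bacterial_refs: Sequence[str]
) -> Dict[str, object]:
    """Split read pairs by whether any mate primary-aligns to a bacterial replicon."""
    bact = {alignments.ref_ids.index(r) for r in bacterial_refs if r in alignments.ref_ids}
    r1 = np.isin(alignments.ref1, list(bact))
    r2 = np.isin(alignments.ref2, list(bact))
    mapped = r1 | r2
    n = len(alignments)
    return {
        "mapped_pairs": int(mapped.sum()),
        "unmapped_pairs": int(n - mapped.sum()),
        "total_pairs": n,
        "unmapped_fraction": float((n - mapped.sum()) / n) if n else 0.0,
        "unmapped_index": np.nonzero(~mapped)[0],
    }


def copies_per_bacterium(phage_mean_depth: float, host_mean_depth: float) -> float:
    if host_mean_depth <= 0:
        raise ValueError("host depth must be positive")
    return phage_mean_depth / host_mean_depth


# ---------------------------------------------------------------------------
# spanning pairs and integration sites


def find_spanning_pairs(
    alignments: AlignmentSet,
    bacterial_refs: Sequence[str],
    phage_refs: Sequence[str],
    insert_mean: float = 350.0,
    insert_sd: float = 50.0,
    cluster_window: Optional[float] = None,
    diagnostic_sets: Optional[Mapping[str, Iterable[SnvKey]]] = None,
    max_edit_distance: int = 2,
) -> List[IntegrationSite]:
    """Cluster phage-bacteria spanning pairs into integration sites.

    A spanning pair has one mate primary on a phage replicon and the other
    on a bacterial replicon; both mates must align within
    ``max_edit_distance`` mismatches, which excludes reads that overhang
    the junction itself.  Host-side positions within one insert-length
    window are merged into a site; the site's junction position is the
    median of per-pair attB estimates (host mate end + half the expected
    gap for left-junction pairs, symmetric for right).  When
    ``diagnostic_sets`` is given, a pair is attributed to a lineage if its
    host-side mate covers a lineage-diagnostic SNV with the alternative
    base; others count as unassigned.
    """
    R = alignments.read_len
    if cluster_window is None:
        cluster_window = insert_mean + 2 * insert_sd
    bact = {r: alignments.ref_ids.index(r) for r in bacterial_refs if r in alignments.ref_ids}
    phage = {r: alignments.ref_ids.index(r) for r in phage_refs if r in alignments.ref_ids}
    gap_half = max(0.0, (insert_mean - 2 * R) / 2.0)

    # (host_ref, phage_ref, att_estimate, phage_end, pair_index, host_mate)
    hits: List[Tuple[int, int, float, str, int, int]] = []
    for host_mate, (hr, hp, hn), (pr, pp, pn) in (
        (
            1,
            (alignments.ref1, alignments.pos1, alignments.nm1),
            (alignments.ref2, alignments.pos2, alignments.nm2),
        ),
        (
            2,
            (alignments.ref2, alignments.pos2, alignments.nm2),
            (alignments.ref1, alignments.pos1, alignments.nm1),
        ),
    ):
        host_hit = np.isin(hr, list(bact.values())) & (hn <= max_edit_distance)
        phage_hit = np.isin(pr, list(phage.values())) & (pn <= max_edit_distance)
        for i in np.nonzero(host_hit & phage_hit)[0]:
            pref = pr[i]
            plen = alignments.ref_length(alignments.ref_ids[pref])
            phage_mid = pp[i] + R / 2.0
            end = "left" if phage_mid < plen / 2.0 else "right"
            if end == "left":
                att = hp[i] + R + gap_half
            else:
                att = hp[i] - gap_half
            hits.append((int(hr[i]), int(pref), float(att), end, int(i), host_mate))

    sites: List[IntegrationSite] = []
    for (href, pref) in sorted({(h, p) for h, p, *_ in hits}):
        sub = sorted(
            [t for t in hits if t[0] == href and t[1] == pref], key=lambda t: t[2]
        )
        # single-linkage clustering along the host coordinate
        clusters: List[List[Tuple]] = []
        for t in sub:
            if clusters and t[2] - clusters[-1][-1][2] <= cluster_window:
                clusters[-1].append(t)
            else:
                clusters.append([t])
        for cl in clusters:
            atts = [t[2] for t in cl]
            n_left = sum(1 for t in cl if t[3] == "left")
            n_right = len(cl) - n_left
            support: Dict[str, int] = {}
            if diagnostic_sets is not None:
                support = _attribute_lineages(
                    alignments, cl, diagnostic_sets, alignments.ref_ids[href]
                )
            sites.append(
                IntegrationSite(
                    alignments.ref_ids[href],
                    int(round(float(np.median(atts)))),
                    alignments.ref_ids[pref],
                    "left" if n_left >= n_right else "right",
                    len(cl),
                    n_left,
                    n_right,
                    support,
                )
            )
    sites.sort(key=lambda s: (s.host_ref_id, s.host_pos))
    return sites


def _attribute_lineages(
    alignments: AlignmentSet,
    cluster: Sequence[Tuple],
    diagnostic_sets: Mapping[str, Iterable[SnvKey]],
    host_ref_id: str,
) -> Dict[str, int]:
    by_pos: Dict[int, List[Tuple[str, str]]] = {}
    for lin, keys in diagnostic_sets.items():
        for ref, pos, alt in keys:
            if ref == host_ref_id:
                by_pos.setdefault(pos, []).append((lin, alt))
    support: Dict[str, int] = {"unassigned": 0}
    R = alignments.read_len
    for t in cluster:
        _, _, _, _, i, host_mate = t
        if host_mate == 1:
            mat, poss, strands = alignments.reads.r1, alignments.pos1, alignments.strand1
        else:
            mat, poss, strands = alignments.reads.r2, alignments.pos2, alignments.strand2
        row = mat[i]
        if strands[i] == 1:
            row = (3 - row)[::-1]
        start = int(poss[i])
        assigned = None
        for off in range(R):
            pos = start + off
            if pos in by_pos:
                base = "ACGT"[row[off]] if row[off] < 4 else "N"
                for lin, alt in by_pos[pos]:
                    if base == alt:
                        assigned = lin
                        break
            if assigned:
                break
        if assigned:
            support[assigned] = support.get(assigned, 0) + 1
        else:
            support["unassigned"] += 1
    return support


def _junction_window(insert_mean: float, insert_sd: float, read_len: int) -> float:
    """2 * E[(F - 2R)+] under F ~ Normal(insert_mean, insert_sd)."""
    a = 2.0 * read_len
    if insert_sd <= 0:
        return 2.0 * max(insert_mean - a, 0.0)
    z = (insert_mean - a) / insert_sd
    expect = (insert_mean - a) * norm.cdf(z) + insert_sd * norm.pdf(z)
    return 2.0 * float(expect)


def integration_fractions(
    spanning_pair_count: int,
    host_mean_depth: float,
    phage_mean_depth: float,
    insert_mean: float = 350.0,
    insert_sd: float = 50.0,
    read_len: int = 100,
) -> Dict[str, float]:
    """Lysogeny fractions from spanning-pair support and coverage.

    integrated_cell_fraction = junction depth / host depth (fraction of
    host cells carrying the prophage); integrated_phage_fraction =
    junction depth / phage depth (fraction of phage copies that are
    integrated).  Both clipped to [0, 1] with a warning.
    """
    if host_mean_depth <= 0 or phage_mean_depth <= 0:
        raise ValueError("depths must be positive")
    W = _junction_window(insert_mean, insert_sd, read_len)
    if W <= 0:
        raise ValueError("insert size too short to produce spanning pairs")
    junction_depth = spanning_pair_count * 2.0 * read_len / W
    icf = junction_depth / host_mean_depth
    ipf = junction_depth / phage_mean_depth
    out = {}
    for name, val in (("integrated_cell_fraction", icf), ("integrated_phage_fraction", ipf)):
        if val > 1.0:
            warnings.warn(f"{name} ratio {val:.3f} exceeds 1; clipped")
        out[name] = float(min(max(val, 0.0), 1.0))
    out["junction_depth"] = float(junction_depth)
    out["window"] = float(W)
    return out


def phage_state_report(
    alignments: AlignmentSet,
    sample_id: str,
    phage_ref: str,
    host_ref: str,
    bacterial_refs: Sequence[str],
    insert_mean: float = 350.0,
    insert_sd: float = 50.0,
    diagnostic_sets: Optional[Mapping[str, Iterable[SnvKey]]] = None,
) -> PhageStateReport:
    """Full free/integrated state of one phage in one sample."""
    host_depth = alignments.coverage_stats(host_ref)["mean_depth"]
    phage_depth = alignments.coverage_stats(phage_ref)["mean_depth"]
    sites = find_spanning_pairs(
        alignments, bacterial_refs, [phage_ref], insert_mean, insert_sd,
        diagnostic_sets=diagnostic_sets,
    )
    sites = [s for s in sites if s.host_ref_id == host_ref]
    n_span = sum(s.spanning_pair_count for s in sites)
    if host_depth > 0 and phage_depth > 0:
        fr = integration_fractions(
            n_span, host_depth, phage_depth, insert_mean, insert_sd,
            alignments.read_len,
        )
        icf, ipf = fr["integrated_cell_fraction"], fr["integrated_phage_fraction"]
    else:
        icf = ipf = 0.0
    return PhageStateReport(
        sample_id,
        phage_ref,
        phage_depth,
        host_depth,
        copies_per_bacterium(phage_depth, host_depth) if host_depth > 0 else np.nan,
        icf,
        ipf,
        sites,
    )


# ---------------------------------------------------------------------------
# spacer / protospacer quantification


@dataclass
class ProtospacerConstruct:
    cluster_id: str
    array_id: str
    repeat: str
    spacer: str

    @property
    def sequence(self) -> str:
        return self.repeat + self.spacer + self.repeat


def build_protospacer_db(
    spacer_clusters: Sequence[SpacerCluster],
    repeat_consensi: Mapping[str, str],
) -> List[ProtospacerConstruct]:
    """One repeat-spacer-repeat construct per cluster (representative spacer)."""
    out = []
    for cl in spacer_clusters:
        aid = cl.representative.array_id
        if aid is None or aid not in repeat_consensi:
            warnings.warn(f"cluster {cl.cluster_id} has no array assignment; skipped")
            continue
        out.append(
            ProtospacerConstruct(
                cl.cluster_id, aid, repeat_consensi[aid], cl.representative.sequence
            )
        )
    return out


def quantify_spacer_protospacer(
    reads: SampleReads,
    constructs: Sequence[ProtospacerConstruct],
    min_flank: int = 10,
    max_mismatch_frac: float = 0.1,
    sample_id: Optional[str] = None,
) -> List[ProtospacerQuant]:
    """Classify reads as spacer support (repeat-flanked) or protospacer support.

    A read covering a construct's full spacer with >= ``min_flank`` matched
    repeat bases on both sides is a spacer read; covering the full spacer
    with fewer matched repeat bases on either side is a protospacer read.
    Each read counts once, for the best-matching construct (fewest spacer
    mismatches, ties by construct order).
    """
    sid = sample_id or reads.sample_id
    specs = []
    for ci, c in enumerate(constructs):
        sp = encode(c.spacer)
        rep = encode(c.repeat)
        seed_len = min(14, len(c.spacer))
        off = (len(c.spacer) - seed_len) // 2
        seed_f = c.spacer[off : off + seed_len]
        seed_r = revcomp(c.spacer)[off : off + seed_len]
        specs.append((ci, sp, rep, seed_f, seed_r))
    counts = {c.cluster_id: [0, 0] for c in constructs}
    mats = [reads.r1, reads.r2]
    for mat in mats:
        for i in range(mat.shape[0]):
            codes = mat[i]
            read_str = decode(codes)
            best = None  # (mm, ci, orient, offset)
            for ci, sp, rep, seed_f, seed_r in specs:
                for orient, seed in ((0, seed_f), (1, seed_r)):
                    if seed not in read_str:
                        continue
                    q = codes if orient == 0 else (3 - codes)[::-1]
                    if len(q) < len(sp):
                        continue
                    mm = _sliding_mismatches(q, sp)
                    thr = int(np.floor(max_mismatch_frac * len(sp)))
                    j = int(mm.argmin())
                    if mm[j] <= thr:
                        cand = (int(mm[j]), ci, orient, j)
                        if best is None or cand < best:
                            best = cand
            if best is None:
                continue
            mmv, ci, orient, j = best
            _, sp, rep, _, _ = specs[ci]
            q = codes if orient == 0 else (3 - codes)[::-1]
            # matched repeat bases flanking the spacer occurrence
            left_avail = min(min_flank, j)
            right_avail = min(min_flank, len(q) - j - len(sp))
            left_match = int(
                np.count_nonzero(q[j - left_avail : j] == rep[len(rep) - left_avail :])
            ) if left_avail > 0 else 0
            right_match = int(
                np.count_nonzero(
                    q[j + len(sp) : j + len(sp) + right_avail] == rep[:right_avail]
                )
            ) if right_avail > 0 else 0
            cid = constructs[ci].cluster_id
            if left_match >= min_flank and right_match >= min_flank:
                counts[cid][0] += 1
            else:
                counts[cid][1] += 1
    return [
        ProtospacerQuant(cid, c[0], c[1], sid) for cid, c in sorted(counts.items())
    ]


def spacer_protospacer_relation(
    quants: Sequence[ProtospacerQuant],
) -> Optional[Dict[str, float]]:
    """OLS of log10(protospacer+1) on log10(spacer+1) with Pearson r.

    Returns None with fewer than 3 clusters with nonzero totals.
    """
    pts = [
        (q.spacer_read_count, q.protospacer_read_count)
        for q in quants
        if q.spacer_read_count + q.protospacer_read_count > 0
    ]
    if len(pts) < 3:
        return None
    x = np.log10(np.array([p[0] for p in pts], dtype=float) + 1.0)
    y = np.log10(np.array([p[1] for p in pts], dtype=float) + 1.0)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return {"pearson_r": np.nan, "slope": 0.0, "intercept": float(y.mean()), "n": len(pts)}
    res = stats.linregress(x, y)
    return {
        "pearson_r": float(res.rvalue),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "n": len(pts),
    }
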