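"""Collinear block detection and syntenic-depth analysis.

Homolog anchor pairs are chained per chromosome pair and orientation with
a dynamic program over gene rank (order index, not bp): a chain's score is
the sum of its anchor scores minus a penalty per skipped rank, with rank
gaps bounded on both genomes. Chains are extracted greedily by score with
used anchors removed, so each anchor belongs to at most one block; blocks
below the minimum pair count are discarded.

Syntenic depth — the number of blocks of the other genome covering each
reference gene — is the package's ploidy-ratio evidence: a modal depth of
2 with little mass above it indicates a 1:2 gene copy ratio, i.e. one
whole-genome duplication on top of the reference's history.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneLocus", "SyntenyBlock", "build_loci", "chain_anchors",
    "syntenic_depth", "depth_ratio_test",
]


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    seq_id: str
    start: int  # 1-based inclusive bp
    end: int
    strand: str
    rank: int  # 0-based order index along its sequence


@dataclass
class SyntenyBlock:
    chrom_a: str
    chrom_b: str
    pairs: list[tuple[str, str]]
    orientation: str = "same"  # same | inverted
    score: float = 0.0
    ranks_a: list[int] = field(default_factory=list)
    ranks_b: list[int] = field(default_factory=list)

    @property
    def span_a(self) -> tuple[int, int]:
        return min(self.ranks_a), max(self.ranks_a)


def build_loci(features: pd.DataFrame,
               id_attr: str = "ID") -> dict[str, GeneLocus]:
    """Locus table (with dense per-chromosome ranks) from a gene GFF3 table."""
    loci: dict[str, GeneLocus] = {}
    genes = features[features["type"] == "gene"]
    for seq_id, grp in genes.groupby("seq_id", sort=True):
        grp = grp.sort_values("start", kind="stable")
        for rank, row in enumerate(grp.itertuples(index=False)):
            gid = row.attributes.get(id_attr)
            if gid is None:
                raise ValueError(f"gene feature without {id_attr} attribute")
            loci[gid] = GeneLocus(gene_id=gid, seq_id=seq_id,
                                  start=int(row.start), end=int(row.end),
                                  strand=str(row.strand), rank=rank)
    return loci


def _best_chain(items: list[tuple[int, int, float, int]], inverted: bool,
                max_gap: int, gap_penalty: float) -> tuple[float, list[int]]:
    """Best-scoring chain over anchors (ra, rb, score, idx).

    Consecutive chain members must advance strictly in rank on both
    genomes (decreasing on b when inverted) with at most ``max_gap``
    skipped ranks per genome; each junction costs ``gap_penalty`` per
    skipped rank. Returns (score, member indices in chain order).
    """
    items = sorted(items, key=lambda t: (t[0], -t[1] if inverted else t[1], t[3]))
    n = len(items)
    dp = [it[2] for it in items]
    back = [-1] * n
    for i in range(n):
        ra_i, rb_i, s_i, _ = items[i]
        for j in range(i):
            ra_j, rb_j, _, _ = items[j]
            da = ra_i - ra_j
            db = (rb_j - rb_i) if inverted else (rb_i - rb_j)
            if da < 1 or db < 1 or da - 1 > max_gap or db - 1 > max_gap:
                continue
            cand = dp[j] + s_i - gap_penalty * ((da - 1) + (db - 1))
            if cand > dp[i] + 1e-12:
                dp[i] = cand
                back[i] = j
    best_i = max(range(n), key=lambda i: (dp[i], -items[i][0]))
    chain = []
    i = best_i
    while i != -1:
        chain.append(items[i][3])
        i = back[i]
    chain.reverse()
    return dp[best_i], chain


def chain_anchors(anchors: Iterable[tuple],
                  loci_a: Mapping[str, GeneLocus],
                  loci_b: Mapping[str, GeneLocus],
                  max_gap: int = 25, min_pairs: int = 5,
                  gap_penalty: float = 1.0) -> list[SyntenyBlock]:
    """Chain homolog anchors into collinear blocks.

    ``anchors`` yields ``(gene_a, gene_b)`` or ``(gene_a, gene_b, score)``
    tuples (score defaults to 1). In self-comparisons (``loci_a is
    loci_b``) trivial self-pairs are dropped and unordered duplicates
    deduplicated, so mirror blocks are not produced. Blocks are reported
    sorted by (chrom_a, chrom_b, first rank_a).
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    if min_pairs < 2:
        raise ValueError("min_pairs must be >= 2")
    self_cmp = loci_a is loci_b
    norm: list[tuple[str, str, float]] = []
    seen_pairs: set[frozenset] = set()
    for anc in anchors:
        ga, gb = anc[0], anc[1]
        score = float(anc[2]) if len(anc) > 2 else 1.0
        if ga not in loci_a:
            raise ValueError(f"anchor references unknown gene {ga!r}")
        if gb not in loci_b:
            raise ValueError(f"anchor references unknown gene {gb!r}")
        if self_cmp:
            if ga == gb:
                continue
            la, lb = loci_a[ga], loci_b[gb]
            if (lb.seq_id, lb.rank) < (la.seq_id, la.rank):
                ga, gb = gb, ga
            key = frozenset((ga, gb))
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
        norm.append((ga, gb, score))

    groups: dict[tuple[str, str], list[tuple[int, int, float, int]]] = {}
    gene_pairs: list[tuple[str, str]] = []
    for idx, (ga, gb, score) in enumerate(
            sorted(norm, key=lambda t: (loci_a[t[0]].seq_id, loci_a[t[0]].rank,
                                        loci_b[t[1]].seq_id, loci_b[t[1]].rank))):
        la, lb = loci_a[ga], loci_b[gb]
        groups.setdefault((la.seq_id, lb.seq_id), []).append(
            (la.rank, lb.rank, score, idx))
        gene_pairs.append((ga, gb))

    blocks: list[SyntenyBlock] = []
    for (ca, cb) in sorted(groups):
        pool = list(groups[(ca, cb)])
        while pool:
            best = None
            for orient in ("same", "inverted"):
                score, chain = _best_chain(pool, orient == "inverted",
                                           max_gap, gap_penalty)
                first_ra = min(ra for ra, _, _, i in pool if i in set(chain))
                key = (-score, first_ra, orient)
                if best is None or key < best[0]:
                    best = (key, score, chain, orient)
            _, score, chain, orient = best
            chain_set = set(chain)
            members = [it for it in pool if it[3] in chain_set]
            pool = [it for it in pool if it[3] not in chain_set]
            if len(chain) >= min_pairs:
                members.sort(key=lambda t: t[0])
                blocks.append(SyntenyBlock(
                    chrom_a=ca, chrom_b=cb,
                    pairs=[gene_pairs[i[3]] for i in members],
                    orientation=orient, score=score,
                    ranks_a=[i[0] for i in members],
                    ranks_b=[i[1] for i in members],
                ))
    blocks.sort(key=lambda b: (b.chrom_a, b.chrom_b, b.ranks_a[0]))
    return blocks


def syntenic_depth(blocks: Sequence[SyntenyBlock],
                   ref_loci: Mapping[str, GeneLocus],
                   ) -> tuple[pd.DataFrame, dict[int, int]]:
    """Per-gene syntenic depth over the reference (chrom_a) genome.

    A gene's depth is the number of blocks whose chrom_a rank span contains
    the gene's rank. Returns the per-gene table and a depth histogram.
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for blk in blocks:
        lo, hi = blk.span_a
        spans.setdefault(blk.chrom_a, []).append((lo, hi))
    rows = []
    for gid in sorted(ref_loci):
        loc = ref_loci[gid]
        depth = sum(lo <= loc.rank <= hi
                    for lo, hi in spans.get(loc.seq_id, ()))
        rows.append({"gene_id": gid, "seq_id": loc.seq_id,
                     "rank": loc.rank, "depth": depth})
    df = pd.DataFrame(rows)
    hist = df["depth"].value_counts().sort_index().to_dict() if len(df) else {}
    return df, {int(k): int(v) for k, v in hist.items()}


def depth_ratio_test(histogram: Mapping[int, int],
                     max_excess_frac: float = 0.1) -> dict:
    """Modal-depth test for a 1:2 syntenic ratio (one extra WGD).

    Returns the modal nonzero depth, the cumulative fraction of genes at
    depths up to the mode, and the fraction above depth 2. The comparison
    is called "duplication consistent" when the modal depth is exactly 2
    and less than ``max_excess_frac`` of genes lie at depth >= 3 (the
    sharp decline past 2x that marks a clean 1:2 ratio).
    """
    if not histogram:
        raise ValueError("empty depth histogram")
    total = sum(histogram.values())
    nonzero = {d: c for d, c in histogram.items() if d > 0}
    if not nonzero:
        return {"modal_depth": 0, "consistent": False, "call": "no signal",
                "frac_le_modal": histogram.get(0, 0) / total,
                "frac_ge3": 0.0, "n_genes": total}
    max_count = max(nonzero.values())
    modal = min(d for d, c in nonzero.items() if c == max_count)
    frac_le = sum(c for d, c in histogram.items() if d <= modal) / total
    frac_ge3 = sum(c for d, c in histogram.items() if d >= 3) / total
    consistent = modal == 2 and frac_ge3 < max_excess_frac
    return {
        "modal_depth": int(modal),
        "frac_le_modal": frac_le,
        "frac_ge3": frac_ge3,
        "consistent": bool(consistent),
        "call": ("duplication consistent" if consistent
                 else "not consistent with 1:2"),
        "n_genes": total,
        "threshold_frac_ge3": max_excess_frac,
    }
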