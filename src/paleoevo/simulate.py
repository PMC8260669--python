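"""Synthetic genomes with known molecular-evolution ground truth.

This module plants the three signal classes the rest of the package
recovers:

* intact LTR retrotransposons whose two LTRs were identical at insertion
  time ``T`` years ago and have since diverged independently at rate ``r``
  substitutions/site/year (pairwise Jukes-Cantor distance ``2 r T``), with
  TG...CA termini and identical target-site duplications;
* a whole-genome-duplication paralog set in which each duplicate has
  accumulated strictly synonymous substitutions until its realized
  Nei-Gojobori Ks (computed with this package's own estimator) matches a
  target, with a controlled transversion share at third codon positions;
* collinear gene order between the pre-duplication reference and the
  duplicated genome, with configurable gene loss.

The mutation model is site-independent Jukes-Cantor with no indels, so the
JC correction applied downstream is exactly the right estimator and every
recovery test has a closed-form expectation. All outputs are deterministic
functions of the seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import ksdist
from .ksdist import CODON_AA

__all__ = [
    "SimConfig", "Gene", "PlantedElement", "WgdResult", "TruthSet",
    "stage_rng", "mutate_jc", "random_genome", "random_gene_set",
    "simulate_ltr_element", "insert_elements", "simulate_wgd",
    "lineage_exemplars", "gene_features", "LINEAGES", "DOMAIN_MOTIFS",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_SENSE_CODONS = sorted(c for c, aa in CODON_AA.items() if aa != "*")

#: fixed 30-bp marker motifs standing in for protein-domain hits; the
#: superfamily classifier keys on their order only.
DOMAIN_MOTIFS = {
    "GAG": "ATGGGACAGACTCATCCAGAAGCTCGTACA",
    "PR":  "GACACTGGTGCTGATGTTACTGTTATCTCA",
    "INT": "CATCACGGTGGTCTTCCAGGTATGAGACTT",
    "RT":  "TTGGATCTTAAAGATGCTTACTGGCAAGTT",
    "RH":  "GTTGAATGGAAGACTCCTAAGAATGCAACT",
}

#: phylogenetic lineages within each superfamily (RT-tree subdivisions)
LINEAGES = {
    "copia": ["Angela", "Ale", "Bianca", "Ivana", "Maximus", "TAR"],
    "gypsy": ["Tekay", "Galadriel", "CRM", "Reina", "Athila", "Tat"],
}

_DOMAIN_ORDER = {
    "copia": ["GAG", "PR", "INT", "RT", "RH"],
    "gypsy": ["GAG", "PR", "RT", "RH", "INT"],
}


class PlacementError(ValueError):
    """Invalid element insertion layout."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    ``r`` is the neutral substitution rate in substitutions/site/year; the
    default is the rate used for LTR insertion dating throughout the
    package. Lengths are in bp.
    """

    seed: int = 0
    r: float = 7.0e-9
    ltr_length: int = 300
    internal_length: int = 1000
    tsd_length: int = 5
    background_gc: float = 0.37
    ks_target: float = 0.3
    transversion_fraction: float = 0.5
    loss_rate: float = 0.0

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("substitution rate r must be > 0")
        for name in ("ltr_length", "internal_length", "tsd_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("background_gc", "transversion_fraction", "loss_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.ks_target < 0:
            raise ValueError("ks_target must be >= 0")


@dataclass
class Gene:
    gene_id: str
    seq_id: str
    cds: str


@dataclass
class PlantedElement:
    """One planted LTR retrotransposon and its ground truth.

    ``seq`` is the full insert ``TSD + LTR5 + internal + LTR3 + TSD``.
    Relative coordinates are 0-based half-open within ``seq``; after
    :func:`insert_elements` the absolute 1-based inclusive element interval
    (excluding TSDs) is stored in ``seq_id``/``start``/``end``.
    """

    element_id: str
    superfamily: str
    age_years: float
    seq: str
    ltr_length: int
    tsd: str
    domains: list[tuple[str, int, int]]  # (name, start, end) rel. to element
    seq_id: str | None = None
    start: int | None = None  # 1-based inclusive, set on insertion
    end: int | None = None
    position: int | None = None  # 0-based insertion point in host coords

    @property
    def element_seq(self) -> str:
        t = len(self.tsd)
        return self.seq[t:len(self.seq) - t]


@dataclass
class PlantedPair:
    gene_a: str
    gene_b: str
    ks_true: float
    fourfold_sites: int


@dataclass
class WgdResult:
    ref_genes: list[Gene]
    dup_genes: list[Gene]
    pairs: list[PlantedPair]
    anchors: list[tuple[str, str]]
    blocks: list[tuple[str, str, list[tuple[str, str]]]]


@dataclass
class TruthSet:
    """Aggregated simulator ground truth for recovery tests."""

    planted_elements: list[PlantedElement] = field(default_factory=list)
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    planted_blocks: list[tuple[str, str, list[tuple[str, str]]]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# randomness

def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible generator for one pipeline stage.

    Derived by stable hashing of (seed, stage name) so each stage can be
    re-run in isolation with identical randomness.
    """
    return np.random.default_rng([int(seed) % (2 ** 31), zlib.crc32(stage.encode())])


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(int(seed) % (2 ** 31))


# ---------------------------------------------------------------------------
# sequence generation and mutation

def random_genome(sizes: dict[str, int], gc: float = 0.37,
                  rng: np.random.Generator | int = 0) -> dict[str, str]:
    """I.i.d. random chromosomes at the given GC content."""
    rng = _as_rng(rng)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = {}
    for name, n in sizes.items():
        codes = rng.choice(4, size=n, p=p)
        out[name] = _BASES[codes].tobytes().decode("ascii")
    return out


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)].tobytes().decode("ascii")


def mutate_jc(seq: str, d: float, seed) -> str:
    """Apply Jukes-Cantor evolution for an expected ``d`` substitutions/site.

    Each site is independently changed with probability
    ``p = 3/4 (1 - exp(-4 d / 3))`` to a uniformly chosen different base;
    the output has the same length as the input.
    """
    if d < 0:
        raise ValueError("expected divergence d must be >= 0")
    if d == 0 or not seq:
        return seq
    rng = _as_rng(seed)
    p = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    # map ACGT -> 0..3 (other characters left untouched)
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    idx = lut[codes]
    hit = (rng.random(len(seq)) < p) & (idx != 255)
    offset = rng.integers(1, 4, size=len(seq)).astype(np.uint8)
    mutated = (idx + offset) % 4
    codes[hit] = _BASES[mutated[hit]]
    return codes.tobytes().decode("ascii")


def random_gene_set(n_genes: int, n_codons: int = 200, n_chroms: int = 1,
                    rng: np.random.Generator | int = 0,
                    id_prefix: str = "g", chrom_prefix: str = "chr") -> list[Gene]:
    """Random CDS (sense codons only, no stops) in chromosomal order."""
    rng = _as_rng(rng)
    genes = []
    per_chrom = -(-n_genes // n_chroms)
    for i in range(n_genes):
        chrom = f"{chrom_prefix}{i // per_chrom + 1}"
        codons = rng.choice(len(_SENSE_CODONS), size=n_codons)
        cds = "".join(_SENSE_CODONS[c] for c in codons)
        genes.append(Gene(gene_id=f"{id_prefix}{i + 1:04d}", seq_id=chrom, cds=cds))
    return genes


# ---------------------------------------------------------------------------
# LTR elements

def simulate_ltr_element(age_years: float, cfg: SimConfig,
                         superfamily: str = "copia",
                         rng: np.random.Generator | int | None = None,
                         element_id: str = "elem") -> PlantedElement:
    """Plant one intact LTR retrotransposon of known age.

    The ancestral LTR begins ``TG`` and ends ``CA``; the element's two LTR
    copies (and the internal region) then each evolve ``d = r * age_years``.
    The internal region carries ordered 30-bp domain marker motifs (INT
    before RT for copia, RT/RH before INT for gypsy), and the element is
    flanked by identical target-site duplications.
    """
    if age_years < 0:
        raise ValueError("age_years must be >= 0")
    if superfamily not in _DOMAIN_ORDER:
        raise ValueError(f"unknown superfamily {superfamily!r}")
    rng = stage_rng(cfg.seed, "ltr-elements") if rng is None else _as_rng(rng)

    ltr = list(_random_seq(cfg.ltr_length, cfg.background_gc, rng))
    ltr[0], ltr[1] = "T", "G"
    ltr[-2], ltr[-1] = "C", "A"
    ancestral_ltr = "".join(ltr)

    order = _DOMAIN_ORDER[superfamily]
    slot = cfg.internal_length // len(order)
    if slot < 30:
        raise ValueError("internal_length too small to hold domain motifs")
    internal = list(_random_seq(cfg.internal_length, cfg.background_gc, rng))
    domains = []
    for i, name in enumerate(order):
        start = i * slot + (slot - 30) // 2
        internal[start:start + 30] = DOMAIN_MOTIFS[name]
        # element-relative, LTR5 first
        domains.append((name, cfg.ltr_length + start, cfg.ltr_length + start + 30))
    internal_anc = "".join(internal)

    d = cfg.r * age_years
    ltr5 = mutate_jc(ancestral_ltr, d, rng)
    ltr3 = mutate_jc(ancestral_ltr, d, rng)
    internal_seq = mutate_jc(internal_anc, d, rng)
    tsd = _random_seq(cfg.tsd_length, cfg.background_gc, rng)
    seq = tsd + ltr5 + internal_seq + ltr3 + tsd
    return PlantedElement(
        element_id=element_id, superfamily=superfamily, age_years=age_years,
        seq=seq, ltr_length=cfg.ltr_length, tsd=tsd, domains=domains,
    )


def insert_elements(genome: dict[str, str], elements: Sequence[PlantedElement],
                    cfg: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Insert planted elements and emit a ground-truth GFF3 feature table.

    Every element must carry ``seq_id`` and ``position`` (0-based insertion
    point in the original host coordinates). Positions must be distinct per
    sequence and within bounds. Returns the modified genome and a feature
    table (1-based inclusive) with ``LTR_retrotransposon``,
    ``long_terminal_repeat`` and ``target_site_duplication`` rows whose
    coordinates exactly address the inserted copies; element truth
    intervals are filled in place.
    """
    by_seq: dict[str, list[PlantedElement]] = {}
    for el in elements:
        if el.seq_id is None or el.position is None:
            raise PlacementError(f"element {el.element_id} has no placement")
        if el.seq_id not in genome:
            raise PlacementError(f"unknown sequence {el.seq_id!r}")
        if not 0 <= el.position <= len(genome[el.seq_id]):
            raise PlacementError(
                f"element {el.element_id} position {el.position} outside "
                f"{el.seq_id} (length {len(genome[el.seq_id])})")
        by_seq.setdefault(el.seq_id, []).append(el)

    new_genome = dict(genome)
    rows = []
    for seq_id, els in by_seq.items():
        els.sort(key=lambda e: e.position)
        positions = [e.position for e in els]
        if len(set(positions)) != len(positions):
            raise PlacementError(f"overlapping insertion points on {seq_id}")
        host = genome[seq_id]
        parts = []
        prev = 0
        offset = 0
        for el in els:
            parts.append(host[prev:el.position])
            parts.append(el.seq)
            t = len(el.tsd)
            ins_start = el.position + offset          # 0-based start of TSD
            elem_start = ins_start + t                # 0-based start of LTR5
            L = len(el.seq) - 2 * t
            el.start = elem_start + 1                 # 1-based inclusive
            el.end = elem_start + L
            eid = el.element_id
            rows.append(_feat(seq_id, "target_site_duplication", ins_start + 1,
                              ins_start + t, {"Parent": eid}))
            rows.append(_feat(seq_id, "LTR_retrotransposon", el.start, el.end,
                              {"ID": eid, "age_years": f"{el.age_years:g}",
                               "superfamily": el.superfamily}))
            rows.append(_feat(seq_id, "long_terminal_repeat", el.start,
                              elem_start + el.ltr_length, {"Parent": eid}))
            rows.append(_feat(seq_id, "long_terminal_repeat",
                              el.end - el.ltr_length + 1, el.end,
                              {"Parent": eid}))
            rows.append(_feat(seq_id, "target_site_duplication", el.end + 1,
                              el.end + t, {"Parent": eid}))
            prev = el.position
            offset += len(el.seq)
        parts.append(host[prev:])
        new_genome[seq_id] = "".join(parts)
    from .io import GFF_COLUMNS
    df = pd.DataFrame(rows, columns=GFF_COLUMNS)
    if len(df):
        df = df.sort_values(["seq_id", "start"], kind="stable").reset_index(drop=True)
    return new_genome, df


def _feat(seq_id, ftype, start, end, attrs):
    return {"seq_id": seq_id, "source": "paleoevo-sim", "type": ftype,
            "start": int(start), "end": int(end), "score": ".", "strand": "+",
            "phase": ".", "attributes": attrs}


def place_elements(genome: dict[str, str], elements: Sequence[PlantedElement],
                   rng: np.random.Generator | int, min_spacing: int = 100) -> None:
    """Assign random non-overlapping insertion points across the genome."""
    rng = _as_rng(rng)
    seq_ids = sorted(genome)
    lengths = np.array([len(genome[s]) for s in seq_ids], dtype=float)
    probs = lengths / lengths.sum()
    taken: dict[str, list[int]] = {s: [] for s in seq_ids}
    for el in elements:
        for _ in range(1000):
            s = seq_ids[rng.choice(len(seq_ids), p=probs)]
            pos = int(rng.integers(0, len(genome[s]) + 1))
            if all(abs(pos - q) >= min_spacing for q in taken[s]):
                taken[s].append(pos)
                el.seq_id, el.position = s, pos
                break
        else:
            raise PlacementError("could not place element without overlap")


# ---------------------------------------------------------------------------
# WGD simulation

def _diverge_synonymous(cds: str, ks_target: float, tv_fraction: float,
                        rng: np.random.Generator, tol: float = 0.02) -> str:
    """Accumulate strictly synonymous substitutions until the realized
    Nei-Gojobori Ks against the input reaches ``ks_target`` (+/- ``tol``).

    Proposals pick a random third codon position and draw a transition with
    probability ``1 - tv_fraction``, otherwise one of the two transversions;
    a proposal is accepted iff the amino acid is unchanged (rejection
    sampling), which guarantees Ka = 0 by construction.
    """
    if ks_target <= 0:
        return cds
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    n = len(codons)
    orig = list(codons)
    # incremental Nei-Gojobori bookkeeping: only third positions mutate and
    # every accepted change is synonymous, so per-codon difference counts
    # are 0/1 and site counts only change through the b-side codon.
    sites_a = sum(ksdist._SYN_SITES[c] for c in orig)
    sd = np.zeros(n)
    syn_site_b = np.array([ksdist._SYN_SITES[c] for c in orig])

    def current_ks():
        syn_sites = (sites_a + syn_site_b.sum()) / 2.0
        pS = sd.sum() / syn_sites
        if pS >= ksdist.SaturationThreshold:
            return None
        return -0.75 * np.log(1 - 4 * pS / 3)

    max_prop = 2000 * n
    for _ in range(max_prop):
        ks = current_ks()
        if ks is None or ks >= ks_target:
            break
        i = int(rng.integers(0, n))
        codon = codons[i]
        base = codon[2]
        if rng.random() < tv_fraction:
            choices = [b for b in "ACGT" if b != base and b != _TRANSITION[base]]
            new = choices[int(rng.integers(0, 2))]
        else:
            new = _TRANSITION[base]
        cand = codon[:2] + new
        if CODON_AA[cand] != CODON_AA[codon]:
            continue
        prev = (codons[i], syn_site_b[i], sd[i])
        codons[i] = cand
        syn_site_b[i] = ksdist._SYN_SITES[cand]
        if cand == orig[i]:
            sd[i] = 0.0
        else:
            s, _nd = ksdist._pathway_counts(orig[i], cand)
            sd[i] = s
        new_ks = current_ks()
        if new_ks is not None and new_ks >= ks_target:
            # crossed the target: keep whichever side is closer
            if abs(new_ks - ks_target) > abs(ks - ks_target):
                codons[i], syn_site_b[i], sd[i] = prev
            break
    return "".join(codons)


def simulate_wgd(genes: Sequence[Gene], cfg: SimConfig,
                 ks_targets: Sequence[float] | None = None,
                 rng: np.random.Generator | int | None = None) -> WgdResult:
    """Duplicate a gene set with planted synonymous divergence.

    The input genes are the pre-duplication reference genome. The
    duplicated genome carries one chromosome copy per label ``A, B, ...``:
    copy ``A`` is the undiverged duplicate and each further copy has
    accumulated synonymous-only substitutions until its Ks against copy A
    reaches the corresponding entry of ``ks_targets`` (default: one round
    at ``cfg.ks_target``). Genes of the duplicated genome are lost
    independently with ``cfg.loss_rate``. Ground truth (paralog pairs with
    realized Ks, reference-to-duplicate anchors, and collinear block
    layout) is returned alongside.
    """
    if ks_targets is None:
        ks_targets = [cfg.ks_target]
    rng = stage_rng(cfg.seed, "wgd") if rng is None else _as_rng(rng)
    for g in genes:
        ksdist._validate_cds(g.cds, g.gene_id)

    labels = [chr(ord("A") + i) for i in range(len(ks_targets) + 1)]
    copies: dict[str, list[Gene]] = {}
    for li, lab in enumerate(labels):
        out = []
        for g in genes:
            if li == 0:
                cds = g.cds
            else:
                cds = _diverge_synonymous(g.cds, ks_targets[li - 1],
                                          cfg.transversion_fraction, rng)
            out.append(Gene(gene_id=f"{g.gene_id}|{lab}",
                            seq_id=f"{g.seq_id}|{lab}", cds=cds))
        copies[lab] = out

    # independent gene loss in the duplicated genome
    kept: dict[str, np.ndarray] = {}
    for lab in labels:
        kept[lab] = rng.random(len(genes)) >= cfg.loss_rate

    dup_genes = [g for lab in labels
                 for g, keep in zip(copies[lab], kept[lab]) if keep]

    pairs = []
    for i, g in enumerate(genes):
        for li, lab in enumerate(labels[1:], start=1):
            if not (kept["A"][i] and kept[lab][i]):
                continue
            a, b = copies["A"][i], copies[lab][i]
            st = ksdist.ng_distance(a.cds, b.cds, gene_a=a.gene_id,
                                    gene_b=b.gene_id)
            pairs.append(PlantedPair(gene_a=a.gene_id, gene_b=b.gene_id,
                                     ks_true=st.Ks if st.Ks is not None else float("nan"),
                                     fourfold_sites=st.fourfold_sites))

    anchors = []
    blocks: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for i, g in enumerate(genes):
        for lab in labels:
            if not kept[lab][i]:
                continue
            dup = copies[lab][i]
            anchors.append((g.gene_id, dup.gene_id))
            blocks.setdefault((g.seq_id, dup.seq_id), []).append(
                (g.gene_id, dup.gene_id))
    block_list = [(ca, cb, prs) for (ca, cb), prs in sorted(blocks.items())]
    return WgdResult(ref_genes=list(genes), dup_genes=dup_genes,
                     pairs=pairs, anchors=anchors, blocks=block_list)


# ---------------------------------------------------------------------------
# annotation helpers and lineage exemplars

def gene_features(genes: Sequence[Gene], spacer: int = 2000) -> pd.DataFrame:
    """Lay genes out along their chromosomes and return a GFF3-style table.

    Genes are placed in list order per chromosome with ``spacer`` bp between
    consecutive gene starts in addition to the CDS length.
    """
    from .io import GFF_COLUMNS
    rows = []
    cursor: dict[str, int] = {}
    for g in genes:
        start = cursor.get(g.seq_id, 1)
        end = start + len(g.cds) - 1
        cursor[g.seq_id] = end + spacer
        rows.append(_feat(g.seq_id, "gene", start, end, {"ID": g.gene_id}))
    df = pd.DataFrame(rows, columns=GFF_COLUMNS)
    df["strand"] = "+"
    return df


def lineage_exemplars(length: int = 300, seed: int = 0) -> dict[str, str]:
    """One synthetic reverse-transcriptase exemplar per named lineage.

    These are random stand-ins for curated reference RT domains, suitable
    for exercising nearest-reference lineage assignment on simulated data.
    """
    out = {}
    for fam, names in LINEAGES.items():
        for name in names:
            rng = np.random.default_rng([zlib.crc32(name.encode()), seed % (2 ** 31)])
            out[name] = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
    return out
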