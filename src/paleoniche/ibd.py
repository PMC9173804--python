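"""IBD-sharing networks, Weir-Cockerham F_ST and private allelic richness.

Identity-by-descent (IBD) segments shared between individuals from deeply
diverged populations index *recent* contact; segment length (in cM) scales
inversely with the age of the contact.  Segments are merged across short
gaps, binned into length classes [1,5), [5,10) and [10,inf) cM, and
summarised per population pair as the probability that a random individual
from A shares qualifying segments with a random individual from B.  A
minimum-block filter (4 blocks for the 1-5 cM class, 2 otherwise) suppresses
false-positive short segments.

F_ST uses the Weir-Cockerham (1984) variance-components estimator,
aggregated as a ratio of sums across sites.  Private allelic richness is
rarefaction-standardised to g gene copies via hypergeometric subsampling
probabilities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln

log = logging.getLogger(__name__)

LENGTH_CLASSES = ("1-5", "5-10", ">10")
DEFAULT_MIN_BLOCKS = {"1-5": 4, "5-10": 2, ">10": 2}


@dataclass(frozen=True)
class IBDSegment:
    ind_a: str
    ind_b: str
    chrom: str
    start_cm: float
    end_cm: float
    lod: float | None = None

    def __post_init__(self):
        if self.end_cm <= self.start_cm:
            raise ValueError("segment end must exceed start")

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


@dataclass
class PopPairSharing:
    pop_a: str
    pop_b: str
    length_class: str
    connected_pairs: int
    possible_dyads: int
    min_blocks: int

    @property
    def probability(self) -> float:
        return self.connected_pairs / self.possible_dyads


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def merge_segments(segs: list[IBDSegment], gap_cm: float = 0.6,
                   consistency_hook=None) -> list[IBDSegment]:
    """Fuse segments of the same individual pair and chromosome separated by
    at most ``gap_cm`` (transitively); overlaps are fused too.

    ``consistency_hook(seg_left, seg_right) -> bool`` may veto a fusion (e.g.
    a genotype-inconsistency check against an external genotype source);
    default merging is purely gap-based.
    """
    if consistency_hook is None:
        log.info("merge_segments: gap-based merging only (no genotype check)")
    groups: dict[tuple, list[IBDSegment]] = {}
    for s in segs:
        groups.setdefault((_pair_key(s.ind_a, s.ind_b), s.chrom), []).append(s)
    out = []
    for (pair, chrom), group in groups.items():
        group = sorted(group, key=lambda s: (s.start_cm, s.end_cm))
        cur = group[0]
        for nxt in group[1:]:
            can = nxt.start_cm - cur.end_cm <= gap_cm
            if can and consistency_hook is not None:
                can = bool(consistency_hook(cur, nxt))
            if can:
                cur = IBDSegment(ind_a=pair[0], ind_b=pair[1], chrom=chrom,
                                 start_cm=cur.start_cm,
                                 end_cm=max(cur.end_cm, nxt.end_cm))
            else:
                out.append(cur)
                cur = nxt
        out.append(cur)
    return sorted(out, key=lambda s: (s.ind_a, s.ind_b, s.chrom, s.start_cm))


def bin_by_length(segs: list[IBDSegment]) -> dict[str, list[IBDSegment]]:
    """Assign merged segments to half-open length classes [1,5), [5,10),
    [10,inf) cM; segments shorter than 1 cM are discarded."""
    out = {c: [] for c in LENGTH_CLASSES}
    for s in segs:
        ln = s.length_cm
        if ln < 1.0:
            continue
        if ln < 5.0:
            out["1-5"].append(s)
        elif ln < 10.0:
            out["5-10"].append(s)
        else:
            out[">10"].append(s)
    return out


def sharing_network(class_segs: list[IBDSegment], pop_labels: dict[str, str],
                    min_blocks: int, within: bool = False) -> list[PopPairSharing]:
    """Cross-population sharing probabilities for one length class.

    A dyad is connected iff its block count in the class reaches
    ``min_blocks``; the pair probability divides connected cross-population
    dyads by n_a * n_b (or n(n-1)/2 within a population when ``within``).
    """
    counts: dict[tuple[str, str], int] = {}
    for s in class_segs:
        counts[_pair_key(s.ind_a, s.ind_b)] = counts.get(_pair_key(s.ind_a, s.ind_b), 0) + 1
    pops: dict[str, list[str]] = {}
    for ind, pop in pop_labels.items():
        pops.setdefault(pop, []).append(ind)
    results = []
    pop_names = sorted(pops)
    pairs = list(combinations(pop_names, 2))
    if within:
        pairs += [(p, p) for p in pop_names]
    for pa, pb in pairs:
        na, nb = len(pops[pa]), len(pops[pb])
        if na == 0 or nb == 0:
            warnings.warn(f"population pair ({pa},{pb}) has an empty side; skipped")
            continue
        if pa == pb:
            dyads = [(a, b) for a, b in combinations(pops[pa], 2)]
        else:
            dyads = [(a, b) for a in pops[pa] for b in pops[pb]]
        conn = sum(1 for a, b in dyads
                   if counts.get(_pair_key(a, b), 0) >= min_blocks)
        results.append(PopPairSharing(pop_a=pa, pop_b=pb, length_class="",
                                      connected_pairs=conn,
                                      possible_dyads=len(dyads),
                                      min_blocks=min_blocks))
    return results


def sharing_by_class(segs: list[IBDSegment], pop_labels: dict[str, str],
                     min_blocks: dict[str, int] | None = None,
                     gap_cm: float = 0.6) -> dict[str, list[PopPairSharing]]:
    """Full pipeline: merge, bin, and summarise sharing per length class."""
    mb = dict(DEFAULT_MIN_BLOCKS)
    if min_blocks:
        mb.update(min_blocks)
    binned = bin_by_length(merge_segments(segs, gap_cm=gap_cm))
    out = {}
    for cls in LENGTH_CLASSES:
        res = sharing_network(binned[cls], pop_labels, mb[cls])
        for r in res:
            r.length_class = cls
        out[cls] = res
    return out


# ---------------------------------------------------------------------------
# genotype-based statistics


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic sites; values 0/1/2 alt-allele copies, -1 missing."""

    genotypes: np.ndarray
    populations: list[str]
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes)
        n, m = self.genotypes.shape
        if m < 1:
            raise ValueError("need at least one site")
        if len(self.populations) != n:
            raise ValueError("population labels must cover all individuals")
        if not self.individual_ids:
            self.individual_ids = [f"ind{i}" for i in range(n)]

    def pop_names(self) -> list[str]:
        return sorted(set(self.populations))


def _wc_components(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham per-site variance components for r=2 populations.

    ``G`` is a list of two (n_i x m) genotype blocks.  Returns (a, a+b+c)
    per site, with monomorphic-across-both sites masked out (NaN).
    """
    r = len(G)
    n = np.stack([np.sum(g >= 0, axis=0).astype(float) for g in G])  # copies/2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.stack([np.where(ni > 0, np.sum(np.where(g >= 0, g, 0), axis=0) / (2 * ni), np.nan)
                      for g, ni in zip(G, n)])
        h = np.stack([np.where(ni > 0, np.sum(g == 1, axis=0) / ni, np.nan)
                      for g, ni in zip(G, n)])
        nbar = n.sum(axis=0) / r
        nc = (r * nbar - (n ** 2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
    tot = a + b + c
    poly = (pbar > 0) & (pbar < 1) & np.all(n >= 1, axis=0)
    a = np.where(poly, a, np.nan)
    tot = np.where(poly, tot, np.nan)
    return a, tot


def fst_two_pops(ga: np.ndarray, gb: np.ndarray) -> float:
    """Weir-Cockerham theta for two genotype blocks, ratio-of-sums over sites."""
    a, tot = _wc_components([np.asarray(ga), np.asarray(gb)])
    num = np.nansum(a)
    den = np.nansum(tot)
    if den == 0:
        raise ValueError("no polymorphic sites between these populations")
    return float(num / den)


def pairwise_fst(G: GenotypeMatrix) -> pd.DataFrame:
    """Weir-Cockerham F_ST for every pair of populations (symmetric matrix)."""
    pops = G.pop_names()
    labels = np.asarray(G.populations)
    for p in pops:
        if (labels == p).sum() < 2:
            raise ValueError(f"population {p!r} has fewer than 2 individuals")
    M = pd.DataFrame(0.0, index=pops, columns=pops)
    for pa, pb in combinations(pops, 2):
        f = fst_two_pops(G.genotypes[labels == pa], G.genotypes[labels == pb])
        M.loc[pa, pb] = M.loc[pb, pa] = f
    return M


def _prob_present(n_total: int, n_allele: int, g: int) -> float:
    """P(allele appears in a hypergeometric subsample of g of n_total copies)."""
    if n_allele == 0:
        return 0.0
    if n_total - n_allele < g:
        return 1.0

    def logc(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    return float(1.0 - np.exp(logc(n_total - n_allele, g) - logc(n_total, g)))


def private_allelic_richness(G: GenotypeMatrix, g: int,
                             pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Rarefied richness of alleles private to each population pair.

    For allele j in population i (N_ij of N_i non-missing gene copies), the
    probability of appearing in a standardized subsample of g copies is
    1 - C(N_i - N_ij, g)/C(N_i, g).  An allele counts toward pair (A, B)
    when present in subsamples of both (probabilities multiplied) and absent
    from every other population.  Totals are divided by the number of
    variable sites.
    """
    pops = G.pop_names()
    labels = np.asarray(G.populations)
    geno = G.genotypes
    copies = {}
    alt = {}
    for p in pops:
        gp = geno[labels == p]
        copies[p] = 2 * np.sum(gp >= 0, axis=0)
        alt[p] = np.sum(np.where(gp >= 0, gp, 0), axis=0)
    for p in pops:
        if int(copies[p].min(initial=2 * len(geno))) < g or 2 * (labels == p).sum() < g:
            raise ValueError(f"g={g} exceeds available gene copies in {p!r}")
    total_alt = sum(alt[p] for p in pops)
    total_cop = sum(copies[p] for p in pops)
    variable = (total_alt > 0) & (total_alt < total_cop)
    n_var = int(variable.sum())
    if n_var == 0:
        raise ValueError("no variable sites")
    if pairs is None:
        pairs = list(combinations(pops, 2))
    out = pd.DataFrame(0.0, index=[f"{a}|{b}" for a, b in pairs],
                       columns=["private_richness"])
    site_idx = np.where(variable)[0]
    for a, b in pairs:
        others = [p for p in pops if p not in (a, b)]
        tot = 0.0
        for s in site_idx:
            for allele in (0, 1):  # ref and alt of the biallelic site
                def cnt(p):
                    return alt[p][s] if allele == 1 else copies[p][s] - alt[p][s]
                if any(cnt(p) > 0 for p in others):
                    continue
                qa = _prob_present(int(copies[a][s]), int(cnt(a)), g)
                qb = _prob_present(int(copies[b][s]), int(cnt(b)), g)
                tot += qa * qb
        out.loc[f"{a}|{b}", "private_richness"] = tot / n_var
    return out


def read_refined_ibd(path) -> list[IBDSegment]:
    """Parse refinedIBD tab-separated output.

    Columns: ind1, hap1, ind2, hap2, chrom, start_bp, end_bp, LOD, length_cM.
    Genetic coordinates are synthesised from length (start at 0) when only
    physical positions are given alongside length_cM.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["ind1", "hap1", "ind2", "hap2", "chrom",
                            "start_bp", "end_bp", "lod", "length_cm"])
    segs = []
    for rec in df.itertuples(index=False):
        segs.append(IBDSegment(ind_a=str(rec.ind1), ind_b=str(rec.ind2),
                               chrom=str(rec.chrom),
                               start_cm=rec.start_bp * 1e-6,
                               end_cm=rec.start_bp * 1e-6 + rec.length_cm,
                               lod=float(rec.lod)))
    return segs
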