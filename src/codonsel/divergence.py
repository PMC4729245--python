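"""Counting-based synonymous/nonsynonymous distances and clock dating.

Implements Nei–Gojobori (1986) pathway counting: synonymous and
nonsynonymous *sites* per codon by single-change degeneracy fractions
(changes creating stop codons count as nonsynonymous), *differences*
between codon pairs averaged with equal weight over all minimal mutational
pathways that avoid stop codons, and Jukes–Cantor correction of the
resulting proportions.

Node ages follow a strict molecular clock: the mean synonymous distance
dS over all tip pairs whose MRCA is the node, converted to time as
age = dS / (2 * mu) generations (two diverging lineages each accumulate
mu substitutions per site per generation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .seqio import CodonAlignment, LabeledTree
from .genetic_code import BASES, N_CODONS, SENSE_AA, SENSE_CODONS, STOP_CODONS, CODON_TO_AA

#: Drosophila per-site per-generation mutation rate used for dating.
DEFAULT_MU = 8.4e-8


@lru_cache(maxsize=1)
def _site_counts() -> np.ndarray:
    """Synonymous sites per sense codon (out of 3 total)."""
    s = np.zeros(N_CODONS)
    for i, codon in enumerate(SENSE_CODONS):
        syn = 0
        for pos in range(3):
            for b in BASES:
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                if alt not in STOP_CODONS and CODON_TO_AA[alt] == SENSE_AA[i]:
                    syn += 1
        s[i] = syn / 3.0
    return s


def _pathway_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Equal-weight pathway-averaged (synonymous, nonsynonymous) differences.

    Enumerates every order of the differing positions, drops pathways that
    pass through a stop codon, and averages step classifications over the
    remaining pathways. Brute force by construction; used to build the
    61x61 lookup once.
    """
    positions = [k for k in range(3) if codon_a[k] != codon_b[k]]
    if not positions:
        return 0.0, 0.0
    path_sums = []
    for order in itertools.permutations(positions):
        current = codon_a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if CODON_TO_AA[current] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if not blocked:
            path_sums.append((sd, nd))
    if not path_sums:
        # no stop-free minimal pathway: fall back to all pathways, scoring
        # steps into/out of stops as nonsynonymous
        for order in itertools.permutations(positions):
            current = codon_a
            sd = nd = 0
            for pos in order:
                nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
                if current in STOP_CODONS or nxt in STOP_CODONS or \
                        CODON_TO_AA.get(current) != CODON_TO_AA.get(nxt):
                    nd += 1
                else:
                    sd += 1
                current = nxt
            path_sums.append((sd, nd))
    sd = sum(p[0] for p in path_sums) / len(path_sums)
    nd = sum(p[1] for p in path_sums) / len(path_sums)
    return sd, nd


@lru_cache(maxsize=1)
def _diff_tables() -> tuple[np.ndarray, np.ndarray]:
    sd = np.zeros((N_CODONS, N_CODONS))
    nd = np.zeros((N_CODONS, N_CODONS))
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            if i < j:
                s, n = _pathway_diffs(a, b)
                sd[i, j] = sd[j, i] = s
                nd[i, j] = nd[j, i] = n
    return sd, nd


@dataclass
class PairwiseDistance:
    """NG86 result for one sequence pair."""

    ds: float
    dn: float
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons: int
    saturated_s: bool = False
    saturated_n: bool = False


def _jc_correct(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return float("inf"), True
    return -0.75 * np.log1p(-4.0 * p / 3.0), False


def nei_gojobori_ds(seq_a: np.ndarray, seq_b: np.ndarray) -> PairwiseDistance:
    """NG86 dS/dN between two codon-index sequences.

    Codons missing (-1) in either sequence are dropped pairwise. Sites are
    averaged over the two sequences; proportions are Jukes–Cantor
    corrected. pS >= 3/4 (or pN) makes the correction undefined and the
    distance is returned as flagged +inf.
    """
    a = np.asarray(seq_a)
    b = np.asarray(seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences differ in codon length")
    keep = (a >= 0) & (b >= 0)
    a, b = a[keep].astype(np.int64), b[keep].astype(np.int64)
    if a.size == 0:
        raise ValueError("no pairwise-complete codons")
    site = _site_counts()
    syn_sites = float((site[a].sum() + site[b].sum()) / 2.0)
    nonsyn_sites = float(3.0 * a.size - syn_sites)
    sd_t, nd_t = _diff_tables()
    syn_diffs = float(sd_t[a, b].sum())
    nonsyn_diffs = float(nd_t[a, b].sum())
    ps = syn_diffs / syn_sites if syn_sites > 0 else 0.0
    pn = nonsyn_diffs / nonsyn_sites if nonsyn_sites > 0 else 0.0
    ds, sat_s = _jc_correct(ps)
    dn, sat_n = _jc_correct(pn)
    return PairwiseDistance(ds, dn, syn_sites, nonsyn_sites,
                            syn_diffs, nonsyn_diffs, int(a.size), sat_s, sat_n)


@dataclass
class SynonymousDistanceMatrix:
    """Symmetric pairwise dS (and dN) matrix with a method tag."""

    taxa: list[str]
    ds: np.ndarray
    dn: np.ndarray
    method: str = "NG86+JC"

    def pair(self, a: str, b: str) -> float:
        return float(self.ds[self.taxa.index(a), self.taxa.index(b)])

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.taxa)]
        for i, t in enumerate(self.taxa):
            lines.append(t + "\t" + "\t".join(f"{v:.6f}" for v in self.ds[i]))
        lines.append(f"# method={self.method}")
        return "\n".join(lines) + "\n"


def pairwise_ds_matrix(alignment: CodonAlignment) -> SynonymousDistanceMatrix:
    """All-pairs NG86 distances on the alignment."""
    n = alignment.n_taxa
    ds = np.zeros((n, n))
    dn = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = nei_gojobori_ds(alignment.codons[i], alignment.codons[j])
            ds[i, j] = ds[j, i] = r.ds
            dn[i, j] = dn[j, i] = r.dn
    return SynonymousDistanceMatrix(list(alignment.taxa), ds, dn)


def node_mean_ds(tree: LabeledTree, ds: SynonymousDistanceMatrix) -> list[dict]:
    """Mean pairwise dS across all tip pairs whose MRCA is each node.

    Returns one record per internal node (preorder ids ``node1``...),
    with the children clades, the number of spanning pairs and their mean
    dS. Summed over nodes the pair counts partition all C(n, 2) tip pairs.
    """
    records = []
    node_no = 0
    for nd in tree.tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        node_no += 1
        child_leaves = [
            [leaf.taxon.label for leaf in child.leaf_iter()]
            for child in nd.child_nodes()
        ]
        pairs = []
        for ca, cb in itertools.combinations(child_leaves, 2):
            pairs.extend(itertools.product(ca, cb))
        if not pairs:
            raise RuntimeError("internal node with no spanning tip pair")
        vals = np.array([ds.pair(a, b) for a, b in pairs])
        records.append(
            {
                "node": f"node{node_no}",
                "clades": [sorted(c) for c in child_leaves],
                "n_pairs": len(pairs),
                "mean_ds": float(np.mean(vals)),
                "finite": bool(np.all(np.isfinite(vals))),
            }
        )
    return records


@dataclass
class NodeDating:
    """Strict-clock node ages derived from mean synonymous distances."""

    records: list[dict]
    mu: float
    generation_time: float

    def to_tsv(self) -> str:
        lines = ["node\tclade_a\tclade_b\tn_pairs\tmean_dS\tage_My"]
        for r in self.records:
            age = "NA" if r["age_my"] is None else f"{r['age_my']:.4f}"
            lines.append(
                f"{r['node']}\t{','.join(r['clades'][0])}\t{','.join(r['clades'][1])}"
                f"\t{r['n_pairs']}\t{r['mean_ds']:.6f}\t{age}"
            )
        lines.append(f"# age = dS/(2*mu) generations, mu={self.mu:g}/site/generation, "
                     f"generation_time={self.generation_time:g} yr")
        return "\n".join(lines) + "\n"


def date_nodes(
    node_ds: list[dict],
    mu: float = DEFAULT_MU,
    generation_time: float = 1.0,
) -> NodeDating:
    """Convert node mean dS to ages in million years.

    age_years = dS / (2 * mu) generations * generation_time. Nodes whose
    mean dS is saturated (infinite) are reported undated (age None).
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    records = []
    for r in node_ds:
        rec = dict(r)
        if np.isfinite(r["mean_ds"]):
            rec["age_my"] = r["mean_ds"] / (2.0 * mu) * generation_time / 1e6
        else:
            rec["age_my"] = None
        records.append(rec)
    return NodeDating(records, mu, generation_time)
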