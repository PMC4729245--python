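"""Codon-usage-bias statistics: Wright's effective number of codons (ENC),
column-bootstrap confidence intervals, and the social-vs-subsocial group
permutation test.

ENC summarises how evenly a species uses synonymous codons. It ranges from
20 (one codon per amino acid: extreme bias) to 61 (all synonymous codons
equally used: no bias) and is assembled from mean codon "homozygosities"
F_k per degeneracy class k:

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

Two F estimators are supported: the bias-corrected form
F = (n * sum(p^2) - 1) / (n - 1) (default) and the plain homozygosity
F = sum(p^2) (which realises the 20/61 endpoints analytically).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .genetic_code import ENC_CLASS_SIZES, ENC_FAMILIES, N_CODONS
from .seqio import SOCIAL, SUBSOCIAL, CodonAlignment

_ENDPOINT_EPS = 1e-9  # snap pure round-off onto the analytic 20/61 bounds

#: family -> (degeneracy class, member codon indices), fixed at import
_FAMILY_ITEMS = [(len(m), np.asarray(m)) for m in ENC_FAMILIES.values()]


def codon_counts(seq: np.ndarray) -> np.ndarray:
    """Counts over the 61 sense codons, ignoring missing (-1) entries."""
    seq = np.asarray(seq)
    return np.bincount(seq[seq >= 0].astype(np.int64), minlength=N_CODONS)


def enc_from_counts(counts: np.ndarray, estimator: str = "wright") -> float:
    """Wright's Nc from a 61-vector of codon counts.

    ``estimator`` selects the family homozygosity: "wright" for the
    bias-corrected (n*sum(p^2)-1)/(n-1) (families need n >= 2), "plain"
    for sum(p^2). Degeneracy classes with no usable family borrow the mean
    F of the observed classes; the result is clamped to [20, 61].
    """
    if estimator not in ("wright", "plain"):
        raise ValueError(f"unknown F estimator {estimator!r}")
    counts = np.asarray(counts, dtype=np.float64)
    if counts.sum() < 1:
        raise ValueError("no usable codons: empty sequence after filtering")

    by_class: dict[int, list[float]] = {k: [] for k in ENC_CLASS_SIZES}
    for k, members in _FAMILY_ITEMS:
        c = counts[members]
        n = c.sum()
        if n < (2 if estimator == "wright" else 1):
            continue
        sum_p2 = float(np.dot(c, c)) / (n * n)
        f = (n * sum_p2 - 1.0) / (n - 1.0) if estimator == "wright" else sum_p2
        by_class[k].append(f)

    mean_f = {k: (sum(v) / len(v)) for k, v in by_class.items() if v}
    if not mean_f:
        raise ValueError("no amino-acid family has enough codons for ENC")
    impute = sum(mean_f.values()) / len(mean_f)

    enc = 2.0  # Met + Trp
    for k, n_families in ENC_CLASS_SIZES.items():
        f = mean_f.get(k, impute)
        f = min(max(f, 1e-6), 1.0)
        enc += n_families / f
    if abs(enc - 61.0) < _ENDPOINT_EPS:
        enc = 61.0
    if abs(enc - 20.0) < _ENDPOINT_EPS:
        enc = 20.0
    return float(min(max(enc, 20.0), 61.0))


def enc(seq: np.ndarray, estimator: str = "wright") -> float:
    """ENC of a single-species codon-index sequence (missing = -1)."""
    return enc_from_counts(codon_counts(seq), estimator=estimator)


def enc_per_species(alignment: CodonAlignment, estimator: str = "wright") -> dict[str, float]:
    """Per-row ENC on the (concatenated) coding alignment."""
    return {t: enc(alignment.codons[i], estimator) for i, t in enumerate(alignment.taxa)}


def _group_members(labels: dict[str, str], taxa: list[str]) -> tuple[list[str], list[str]]:
    soc = [t for t in taxa if labels[t] == SOCIAL]
    sub = [t for t in taxa if labels[t] == SUBSOCIAL]
    if not soc or not sub:
        raise ValueError("need at least one species per mating-system group")
    return soc, sub


def bootstrap_group_ci(
    alignment: CodonAlignment,
    labels: dict[str, str],
    n_boot: int = 1000,
    seed: int = 0,
    estimator: str = "wright",
    alpha: float = 0.05,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap CI for the group-mean ENC.

    Codon columns are resampled with replacement to the original length;
    per replicate the social and subsocial mean ENC are recomputed; the
    (alpha/2, 1-alpha/2) percentiles per group are returned.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if alignment.n_codons < 2:
        import warnings

        warnings.warn("single-column alignment: bootstrap CI is degenerate")
    rng = np.random.default_rng(seed)
    soc, sub = _group_members(labels, alignment.taxa)
    soc_idx = [alignment.taxa.index(t) for t in soc]
    sub_idx = [alignment.taxa.index(t) for t in sub]
    n_cols = alignment.n_codons
    reps = {SOCIAL: np.empty(n_boot), SUBSOCIAL: np.empty(n_boot)}
    for b in range(n_boot):
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = alignment.codons[:, cols]
        for key, idx in ((SOCIAL, soc_idx), (SUBSOCIAL, sub_idx)):
            reps[key][b] = float(
                np.mean([enc(resampled[i], estimator) for i in idx])
            )
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    return {
        g: (float(np.percentile(v, lo)), float(np.percentile(v, hi)))
        for g, v in reps.items()
    }


def permutation_group_test(
    enc_values: dict[str, float],
    labels: dict[str, str],
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "auto",
) -> dict:
    """Permutation test of mean ENC difference (social minus subsocial).

    Species are repeatedly split at random into two groups matching the
    social/subsocial sizes; the statistic is mean(small-group sized like
    social) - mean(other group). The p-value is one-sided in the direction
    "social mean higher" (the reduced-selection expectation). With
    ``mode="auto"``, all C(n, n_social) splits are enumerated whenever
    their number is <= n_perm and the exact fraction is reported;
    otherwise splits are sampled and p carries the add-one correction
    p = (1 + #{null >= obs}) / (1 + n_perm). ``mode`` may force either
    behaviour.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    taxa = list(enc_values)
    soc, sub = _group_members(labels, taxa)
    values = np.asarray([enc_values[t] for t in taxa], dtype=float)
    k = len(soc)
    observed = float(np.mean([enc_values[t] for t in soc])
                     - np.mean([enc_values[t] for t in sub]))
    n = len(taxa)
    total = values.sum()

    def stat(idx_small: np.ndarray) -> float:
        small = values[idx_small].sum()
        return small / k - (total - small) / (n - k)

    if mode not in ("auto", "exhaustive", "sampled"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    exhaustive = (math.comb(n, k) <= n_perm) if mode == "auto" else mode == "exhaustive"
    if exhaustive:
        null = np.array([stat(np.asarray(c)) for c in combinations(range(n), k)])
        p = float(np.mean(null >= observed - 1e-12))
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for i in range(n_perm):
            null[i] = stat(rng.choice(n, size=k, replace=False))
        p = float((1 + np.sum(null >= observed - 1e-12)) / (1 + n_perm))
    return {
        "observed": observed,
        "p_value": p,
        "null": null,
        "mode": "exhaustive" if exhaustive else "sampled",
        "n_permutations": len(null),
        "seed": seed,
    }


@dataclass
class EncReport:
    """Bundle of the full codon-usage-bias analysis for one alignment."""

    per_species_enc: dict[str, float]
    group_means: dict[str, float]
    group_ci: dict[str, tuple[float, float]]
    permutation: dict
    estimator: str
    n_bootstrap: int
    seed: int
    rows: list[str] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["record\tname\tvalue\textra"]
        for sp, v in self.per_species_enc.items():
            lines.append(f"species_enc\t{sp}\t{v:.4f}\t")
        for g, m in self.group_means.items():
            lo, hi = self.group_ci[g]
            lines.append(f"group_mean\t{g}\t{m:.4f}\tCI95=({lo:.4f},{hi:.4f})")
        perm = self.permutation
        lines.append(
            "permutation_test\tsocial-subsocial\t"
            f"{perm['observed']:.4f}\tp={perm['p_value']:.4g},mode={perm['mode']},"
            f"seed={self.seed},estimator={self.estimator}"
        )
        return "\n".join(lines) + "\n"


def enc_report(
    alignment: CodonAlignment,
    labels: dict[str, str],
    n_boot: int = 1000,
    n_perm: int = 1000,
    seed: int = 0,
    estimator: str = "wright",
) -> EncReport:
    """Run the full ENC comparison: per-species values, group means with
    bootstrap CI, and the group permutation test."""
    values = enc_per_species(alignment, estimator)
    soc, sub = _group_members(labels, alignment.taxa)
    means = {
        SOCIAL: float(np.mean([values[t] for t in soc])),
        SUBSOCIAL: float(np.mean([values[t] for t in sub])),
    }
    ci = bootstrap_group_ci(alignment, labels, n_boot=n_boot, seed=seed,
                            estimator=estimator)
    perm = permutation_group_test(values, labels, n_perm=n_perm, seed=seed + 1)
    return EncReport(values, means, ci, perm, estimator, n_boot, seed)


def base_composition(alignment: CodonAlignment) -> dict[str, np.ndarray]:
    """Per-species nucleotide frequencies at each codon position.

    Returns species -> 3x4 array (rows: codon positions 1..3; columns:
    A, C, G, T), each row summing to 1 over non-missing codons. Missing
    codons drop all three of their positions.
    """
    from .genetic_code import SENSE_CODONS

    # position x base lookup per codon state
    base_order = "ACGT"
    lut = np.zeros((N_CODONS, 3, 4))
    for i, codon in enumerate(SENSE_CODONS):
        for pos, b in enumerate(codon):
            lut[i, pos, base_order.index(b)] = 1.0

    out: dict[str, np.ndarray] = {}
    for i, taxon in enumerate(alignment.taxa):
        row = alignment.codons[i]
        used = row[row >= 0].astype(np.int64)
        if used.size == 0:
            raise ValueError(f"taxon {taxon!r} has no non-missing codons")
        freq = lut[used].sum(axis=0)
        out[taxon] = freq / freq.sum(axis=1, keepdims=True)
    return out
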