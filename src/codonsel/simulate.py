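"""Synthetic codon alignments with known branch-class selection structure.

The generator evolves sense codons along a fixed rooted tree under the
same Goldman–Yang branch-class model the estimators fit: root states are
drawn from the stationary distribution and each branch applies the
transition matrix of its class' omega. The bundled study fixture mirrors
the design of the empirical comparison this package targets: 10 taxa
(3 social, 7 subsocial), each social tip sister to a subsocial tip on a
short terminal branch, 13 loci totalling 1583 codons (4749 coding bp),
and three-class omega defaults (internal 0.1674, external-social
0.2534, external-subsocial 0.1018).

The fixture topology is synthetic: it pairs each social tip with its
reported subsocial sister species but is otherwise a constructed
topology; a user-supplied Newick can replace it for accession-based
benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import yaml

from .codon_model import ReversibleEig, build_rate_matrix, _check_freqs
from .genetic_code import ENC_FAMILIES, N_CODONS
from .seqio import (
    SOCIAL,
    SUBSOCIAL,
    CodonAlignment,
    LabeledTree,
    write_mating_map,
)

#: Default omega per branch class (three-class model point estimates).
DEFAULT_OMEGAS = {
    "internal": 0.1674,
    "external_social": 0.2534,
    "external_subsocial": 0.1018,
}
DEFAULT_KAPPA = 2.0

#: Fixture design constants: 13 loci summing to 1583 codons (4749 nt).
FIXTURE_N_CODONS = 1583
FIXTURE_LOCUS_LENGTHS = [122] * 12 + [119]

#: Terminal social branches are ~1/4 the subsocial terminal length,
#: echoing the relative youth of the social lineages; overall depth
#: (~0.4 substitutions/codon root-to-tip) reflects the substantial
#: synonymous divergence a multi-million-year genus accumulates while
#: staying clear of saturation.
SOCIAL_TIP_LEN = 0.04
SUBSOCIAL_TIP_LEN = 0.16
INTERNAL_LEN = 0.08

FIXTURE_LABELS = {
    "S_dumicola": SOCIAL,
    "S_mimosarum": SOCIAL,
    "S_sarasinorum": SOCIAL,
    "S_lineatus": SUBSOCIAL,
    "S_tibialis": SUBSOCIAL,
    "S_africanus": SUBSOCIAL,
    "S_tentoriicola": SUBSOCIAL,
    "S_pacificus": SUBSOCIAL,
    "S_bicolor": SUBSOCIAL,
    "S_dufuori": SUBSOCIAL,
}

EXTRA_TAXON = "S_sp_undescribed"


def _fixture_newick(include_extra: bool = False) -> str:
    i, ss, st = INTERNAL_LEN, SUBSOCIAL_TIP_LEN, SOCIAL_TIP_LEN
    core = (
        f"((S_lineatus:{ss},S_tibialis:{ss}):{i},"
        f"((S_bicolor:{ss},S_dufuori:{ss}):{i},"
        f"(((S_dumicola:{st},S_tentoriicola:{ss}):{i},"
        f"(S_mimosarum:{st},S_africanus:{ss}):{i}):{i},"
        f"(S_sarasinorum:{st},S_pacificus:{ss}):{i}):{i}):{i});"
    )
    if include_extra:
        # graft the undescribed (assumed subsocial) taxon next to S_lineatus
        core = core.replace(
            f"S_lineatus:{ss}",
            f"(S_lineatus:{ss},{EXTRA_TAXON}:{ss}):{i}", 1,
        )
    return core


@dataclass
class SimulationSpec:
    """Everything needed to simulate one codon alignment."""

    tree: LabeledTree
    omega_by_class: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OMEGAS))
    kappa: float = DEFAULT_KAPPA
    codon_freqs: np.ndarray | None = None  # uniform over 61 if None
    n_codons: int = FIXTURE_N_CODONS
    locus_lengths: list[int] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.codon_freqs is None:
            self.codon_freqs = np.full(N_CODONS, 1.0 / N_CODONS)
        self.codon_freqs = _check_freqs(self.codon_freqs)
        if self.locus_lengths is not None and sum(self.locus_lengths) != self.n_codons:
            raise ValueError("locus lengths must sum to n_codons")
        if self.kappa <= 0 or any(w < 0 for w in self.omega_by_class.values()):
            raise ValueError("invalid rate parameters")


def simulate_codon_alignment(spec: SimulationSpec) -> tuple[CodonAlignment, dict]:
    """Evolve an alignment under the spec's branch-class codon model.

    Returns the alignment plus a truth record (parameters, seed, per-branch
    class and length) for parameter-recovery experiments. Seeded runs are
    bit-reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = spec.codon_freqs
    eigs = {
        cls: ReversibleEig(build_rate_matrix(spec.kappa, w, freqs), freqs)
        for cls, w in spec.omega_by_class.items()
    }
    tree = spec.tree.tree
    n = spec.n_codons

    root_state = rng.choice(N_CODONS, size=n, p=freqs)
    states = {id(tree.seed_node): root_state}
    branch_record = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        t = float(nd.edge.length or 0.0)
        if nd.is_leaf():
            cls = spec.tree.tip_class(nd.taxon.label)
            name = nd.taxon.label
        else:
            cls = "internal"
            name = f"internal_{id(nd) % 100000}"
        if cls not in eigs:
            raise ValueError(f"no omega supplied for branch class {cls!r}")
        parent = states[id(nd.parent_node)]
        if t == 0.0:
            child = parent.copy()
        else:
            pmat = eigs[cls].pmat(t)
            cum = np.cumsum(pmat, axis=1)
            cum[:, -1] = 1.0
            u = rng.random(n)
            child = np.empty(n, dtype=np.int16)
            for s in np.unique(parent):
                idx = parent == s
                child[idx] = np.searchsorted(cum[s], u[idx], side="right")
            np.clip(child, 0, N_CODONS - 1, out=child)
        states[id(nd)] = child
        branch_record[name] = {"class": cls, "length": t}

    taxa = spec.tree.taxa
    mat = np.vstack([states[id(leaf)] for leaf in tree.leaf_node_iter()]).astype(np.int16)
    partitions = []
    if spec.locus_lengths:
        pos = 0
        for k, ln in enumerate(spec.locus_lengths):
            partitions.append((f"locus{k + 1}", pos, pos + ln))
            pos += ln
    aln = CodonAlignment(list(taxa), mat, partitions)
    truth = {
        "kappa": spec.kappa,
        "omega_by_class": dict(spec.omega_by_class),
        "seed": spec.seed,
        "n_codons": n,
        "branches": branch_record,
    }
    return aln, truth


def make_study_fixture(
    seed: int = 0,
    n_codons: int = FIXTURE_N_CODONS,
    omega_by_class: dict[str, float] | None = None,
    kappa: float = DEFAULT_KAPPA,
    codon_freqs: np.ndarray | None = None,
    include_extra_taxon: bool = False,
    newick: str | None = None,
) -> tuple[CodonAlignment, LabeledTree, dict[str, str], dict]:
    """Simulate the 10-taxon study-design fixture.

    Three social tips sit on short terminal branches, each sister to a
    subsocial tip; 13 locus spans total ``n_codons`` codons. An optional
    11th (assumed subsocial) taxon emulates adding a newly discovered
    species. Returns (alignment, labeled tree, label map, truth record).
    """
    labels = dict(FIXTURE_LABELS)
    if include_extra_taxon:
        labels[EXTRA_TAXON] = SUBSOCIAL
    tree = LabeledTree.from_newick(newick or _fixture_newick(include_extra_taxon), labels)
    if n_codons == FIXTURE_N_CODONS:
        locus_lengths = list(FIXTURE_LOCUS_LENGTHS)
    else:
        base = n_codons // 13
        locus_lengths = [base] * 12 + [n_codons - 12 * base]
        locus_lengths = [x for x in locus_lengths if x > 0]
    spec = SimulationSpec(
        tree=tree,
        omega_by_class=dict(omega_by_class or DEFAULT_OMEGAS),
        kappa=kappa,
        codon_freqs=codon_freqs,
        n_codons=n_codons,
        locus_lengths=locus_lengths,
        seed=seed,
    )
    aln, truth = simulate_codon_alignment(spec)
    return aln, tree, labels, truth


def simulate_skewed_codon_usage(
    alignment: CodonAlignment,
    skew_strength: float,
    target_taxa: list[str],
    seed: int = 0,
) -> CodonAlignment:
    """Skew synonymous usage of the target taxa toward preferred codons.

    Each codon of a target taxon is replaced by its family's preferred
    codon (the family's first member) with probability ``skew_strength``;
    the amino-acid sequence is preserved exactly. skew 0 is the identity;
    skew 1 leaves one codon per amino acid (plain-F ENC of 20).
    """
    if not 0.0 <= skew_strength <= 1.0:
        raise ValueError("skew_strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    preferred = np.arange(N_CODONS, dtype=np.int16)
    for members in ENC_FAMILIES.values():
        for m in members:
            preferred[m] = members[0]
    out = alignment.codons.copy()
    for taxon in target_taxa:
        i = alignment.taxa.index(taxon)
        row = out[i]
        mask = (row >= 0) & (rng.random(row.shape) < skew_strength)
        row[mask] = preferred[row[mask].astype(np.int64)]
    return CodonAlignment(list(alignment.taxa), out, list(alignment.partitions))


def simulate_intron(n_bp: int = 589, n_taxa: int = 10, seed: int = 0,
                    names: list[str] | None = None) -> dict[str, str]:
    """Unconstrained (Jukes–Cantor-uniform) nucleotide sequences standing in
    for a non-coding partition; used only by partition-handling tests."""
    rng = np.random.default_rng(seed)
    names = names or [f"t{i}" for i in range(n_taxa)]
    bases = np.array(list("ACGT"))
    return {nm: "".join(rng.choice(bases, size=n_bp)) for nm in names}


def write_fixture(outdir, seed: int = 0, **kwargs) -> None:
    """Write FASTA + Newick + label map + truth YAML for one fixture."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln, tree, labels, truth = make_study_fixture(seed=seed, **kwargs)
    aln.to_fasta(outdir / "alignment.fasta")
    tree.to_newick(outdir / "tree.nwk")
    write_mating_map(labels, outdir / "labels.tsv")
    (outdir / "truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=False))
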