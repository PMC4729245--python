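"""Alignment and tree I/O with codon-aware validation.

Central containers:

* :class:`CodonAlignment` — taxa x codon-column matrix over the 61 sense
  codon states (``-1`` marks a gap/ambiguous codon, treated as missing data
  downstream).
* :class:`LabeledTree` — a rooted topology whose branches are classed as
  ``internal``, ``external_social`` or ``external_subsocial`` from a
  species -> mating-system map.

FASTA parsing goes through Bio.SeqIO and Newick through dendropy; the codon
framing, stop-codon policy and branch classing are enforced here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import (
    CODON_INDEX,
    SENSE_CODONS,
    STOP_CODONS,
)

SOCIAL = "social"
SUBSOCIAL = "subsocial"

INTERNAL = "internal"
EXTERNAL_SOCIAL = "external_social"
EXTERNAL_SUBSOCIAL = "external_subsocial"


class FramingError(ValueError):
    """Sequence length incompatible with a codon reading frame."""


class StopCodonError(ValueError):
    """In-frame stop codon found in a coding alignment."""


class InputError(ValueError):
    """Malformed or inconsistent user input (taxa, labels, topology)."""


@dataclass
class CodonAlignment:
    """In-frame codon alignment over the 61 sense-codon states.

    ``codons`` holds one row per taxon; entries are indices into
    ``genetic_code.SENSE_CODONS`` or ``-1`` for a missing/ambiguous codon.
    ``partitions`` records locus spans as ``(name, start, end)`` half-open
    codon-column intervals (0-based internally; reports are 1-based).
    """

    taxa: list[str]
    codons: np.ndarray
    partitions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codons = np.asarray(self.codons, dtype=np.int16)
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise InputError("codon matrix shape does not match taxa list")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise InputError(f"duplicate taxon names: {', '.join(dupes)}")
        if self.partitions:
            total = sum(e - s for _, s, e in self.partitions)
            if total != self.n_codons:
                raise InputError("partition spans do not cover the alignment")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return int(self.codons.shape[1])

    def row(self, taxon: str) -> np.ndarray:
        return self.codons[self.taxa.index(taxon)]

    def subset_columns(self, cols: np.ndarray) -> "CodonAlignment":
        """New alignment from the given codon columns (partitions dropped)."""
        return CodonAlignment(list(self.taxa), self.codons[:, cols])

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq("".join("---" if c < 0 else SENSE_CODONS[c] for c in row)),
                      id=name, description="")
            for name, row in zip(self.taxa, self.codons)
        ]
        SeqIO.write(records, str(path), "fasta")


def read_codon_alignment(
    path: str | Path | io.TextIOBase,
    frame_offset: int = 0,
    mask_stops: bool = False,
) -> CodonAlignment:
    """Read an in-frame coding FASTA alignment.

    ``frame_offset`` trims that many leading nucleotides from every sequence
    before framing. In-frame stop codons raise :class:`StopCodonError`
    naming the taxon and 1-based codon column, unless ``mask_stops`` is set,
    in which case they become missing data.
    """
    handle = str(path) if isinstance(path, (str, Path)) else path
    records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise InputError("no sequences found in FASTA input")
    names = [r.id for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise InputError(f"duplicate taxon names in FASTA: {', '.join(dupes)}")
    seqs = [str(r.seq)[frame_offset:].upper() for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise InputError(f"sequences have unequal lengths: {sorted(lengths)}")
    (length,) = lengths
    if length % 3:
        raise FramingError(f"alignment length {length} is not a multiple of 3")

    n_codons = length // 3
    mat = np.empty((len(names), n_codons), dtype=np.int16)
    for i, (name, seq) in enumerate(zip(names, seqs)):
        for k in range(n_codons):
            codon = seq[3 * k : 3 * k + 3]
            idx = CODON_INDEX.get(codon)
            if idx is None:
                if codon in STOP_CODONS:
                    if not mask_stops:
                        raise StopCodonError(
                            f"in-frame stop codon {codon} in taxon {name!r} "
                            f"at codon column {k + 1}"
                        )
                    idx = -1
                else:
                    idx = -1
            mat[i, k] = idx
    return CodonAlignment(names, mat)


def concatenate_loci(alignments: list[CodonAlignment],
                     names: list[str] | None = None) -> CodonAlignment:
    """Concatenate per-locus alignments column-wise, recording locus spans.

    All loci must share the same taxa set; rows of later loci are reordered
    to the first locus' taxon order.
    """
    if not alignments:
        raise InputError("no alignments to concatenate")
    ref = alignments[0]
    ref_set = set(ref.taxa)
    if names is None:
        names = [f"locus{i + 1}" for i in range(len(alignments))]
    blocks, partitions, pos = [], [], 0
    for name, aln in zip(names, alignments):
        if set(aln.taxa) != ref_set:
            missing = sorted(ref_set ^ set(aln.taxa))
            raise InputError(f"taxa mismatch between loci: {', '.join(missing)}")
        order = [aln.taxa.index(t) for t in ref.taxa]
        blocks.append(aln.codons[order])
        partitions.append((name, pos, pos + aln.n_codons))
        pos += aln.n_codons
    return CodonAlignment(list(ref.taxa), np.hstack(blocks), partitions)


def split_partitions(alignment: CodonAlignment) -> dict[str, CodonAlignment]:
    """Split a concatenated alignment back into its recorded locus spans."""
    if not alignment.partitions:
        raise InputError("alignment carries no partition records")
    out = {}
    for name, start, end in alignment.partitions:
        out[name] = CodonAlignment(list(alignment.taxa),
                                   alignment.codons[:, start:end])
    return out


def read_mating_map(path: str | Path | io.TextIOBase) -> dict[str, str]:
    """Read a two-column TAB file: species <TAB> social|subsocial."""
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
    else:
        text = path.read()
    labels: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2 or parts[1] not in (SOCIAL, SUBSOCIAL):
            raise InputError(f"bad label-map line {lineno}: {line!r}")
        labels[parts[0]] = parts[1]
    return labels


def write_mating_map(labels: dict[str, str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{k}\t{v}\n" for k, v in labels.items()))


@dataclass
class LabeledTree:
    """Rooted bifurcating topology with mating-system branch classes.

    Branch lengths (when present) are expected substitutions per codon
    site. Terminal branches take the class of their tip's label; all other
    branches are ``internal``. Branch counting follows the unrooted view of
    the topology (the two root-adjacent edges count as one), so an n-tip
    bifurcating tree has 2n-3 branches.
    """

    tree: dendropy.Tree
    labels: dict[str, str]

    def __post_init__(self) -> None:
        tips = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        unlabeled = sorted(tips - set(self.labels))
        if unlabeled:
            raise InputError(f"tips missing from label map: {', '.join(unlabeled)}")
        bad = sorted(v for v in set(self.labels.values()) if v not in (SOCIAL, SUBSOCIAL))
        if bad:
            raise InputError(f"unknown mating-system labels: {bad}")

    # -- construction --------------------------------------------------

    @classmethod
    def from_newick(
        cls,
        source: str | Path,
        labels: dict[str, str],
        resolve_polytomies: bool = False,
    ) -> "LabeledTree":
        """Parse a rooted Newick tree and class its branches.

        Polytomies are rejected unless ``resolve_polytomies`` is set, in
        which case they are arbitrarily resolved with zero-length branches.
        """
        kw = dict(schema="newick", preserve_underscores=True)
        if isinstance(source, Path) or (isinstance(source, str) and Path(source).exists()):
            tree = dendropy.Tree.get(path=str(source), **kw)
        else:
            tree = dendropy.Tree.get(data=source, **kw)
        tree.is_rooted = True
        # a trifurcating seed node is the conventional unrooted
        # representation, not a polytomy
        poly = [
            nd for nd in tree.preorder_node_iter()
            if len(nd.child_nodes()) > (3 if nd.parent_node is None else 2)
        ]
        if poly:
            if not resolve_polytomies:
                raise InputError(
                    f"tree contains {len(poly)} polytomy(ies); "
                    "pass resolve_polytomies=True to resolve arbitrarily"
                )
            tree.resolve_polytomies()
            for nd in tree.preorder_node_iter():
                if nd.edge.length is None and nd.parent_node is not None:
                    nd.edge.length = 0.0
        return cls(tree, dict(labels))

    # -- basic views ---------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def tip_class(self, name: str) -> str:
        return EXTERNAL_SOCIAL if self.labels[name] == SOCIAL else EXTERNAL_SUBSOCIAL

    def branch_classes(self) -> dict[str, int]:
        """Count branches per class in the unrooted view of the topology.

        With a bifurcating root, the two root-adjacent edges collapse into
        one unrooted branch; it is external (classed by the tip) if either
        end is a tip, internal otherwise.
        """
        counts = {INTERNAL: 0, EXTERNAL_SOCIAL: 0, EXTERNAL_SUBSOCIAL: 0}
        root = self.tree.seed_node
        root_children = root.child_nodes()
        merged = set(root_children) if len(root_children) == 2 else set()
        for nd in self.tree.preorder_node_iter():
            if nd is root or nd in merged:
                continue
            if nd.is_leaf():
                counts[self.tip_class(nd.taxon.label)] += 1
            else:
                counts[INTERNAL] += 1
        if merged:
            leaf_ends = [nd for nd in merged if nd.is_leaf()]
            if leaf_ends:
                counts[self.tip_class(leaf_ends[0].taxon.label)] += 1
            else:
                counts[INTERNAL] += 1
        return counts

    def internal_nodes(self) -> list[dendropy.Node]:
        return [nd for nd in self.tree.preorder_node_iter() if not nd.is_leaf()]

    def to_newick(self, path: str | Path | None = None) -> str:
        s = self.tree.as_string(schema="newick", suppress_rooting=True,
                                unquoted_underscores=True)
        if path is not None:
            Path(path).write_text(s)
        return s


def read_labeled_tree(
    path: str | Path,
    labels: dict[str, str],
    resolve_polytomies: bool = False,
) -> LabeledTree:
    """Convenience wrapper mirroring :meth:`LabeledTree.from_newick`."""
    return LabeledTree.from_newick(path, labels, resolve_polytomies=resolve_polytomies)
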