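"""Universal genetic code tables shared across the package.

Everything here is a module-level constant derived once at import time.
Spider nuclear genes use the standard code, so no alternative code tables
are exposed.
"""

from __future__ import annotations

import itertools

import numpy as np

BASES = "TCAG"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Standard-code amino acid for each of the 64 codons in TCAG order.
_CODE = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)

ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
CODON_TO_AA = dict(zip(ALL_CODONS, _CODE))
STOP_CODONS = frozenset(c for c, aa in CODON_TO_AA.items() if aa == "*")

#: The 61 sense codons, in TCAG enumeration order; index order is the
#: state order used by every rate matrix / likelihood routine.
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61

SENSE_AA = [CODON_TO_AA[c] for c in SENSE_CODONS]

#: Synonymous families keyed by amino acid letter (sense codons only).
AA_FAMILIES: dict[str, list[int]] = {}
for _i, _aa in enumerate(SENSE_AA):
    AA_FAMILIES.setdefault(_aa, []).append(_i)

#: Wright-style degeneracy classes for ENC: Met/Trp (1-fold) excluded,
#: Ile is the only 3-fold family, Leu/Ser/Arg kept whole as 6-fold.
DEGENERACY_OF_AA = {aa: len(members) for aa, members in AA_FAMILIES.items()}
ENC_FAMILIES = {aa: members for aa, members in AA_FAMILIES.items() if len(members) > 1}
ENC_CLASS_SIZES = {2: 9, 3: 1, 4: 5, 6: 3}

_PURINES = {"A", "G"}


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a<->b is a transition."""
    return a != b and ((a in _PURINES) == (b in _PURINES))


def _single_step_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean 61x61 tables: single-nt neighbour, transition, nonsynonymous."""
    n = N_CODONS
    nb = np.zeros((n, n), dtype=bool)
    ts = np.zeros((n, n), dtype=bool)
    ns = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            nb[i, j] = True
            ts[i, j] = is_transition(*diffs[0])
            ns[i, j] = SENSE_AA[i] != SENSE_AA[j]
    return nb, ts, ns


SINGLE_STEP, IS_TRANSITION_STEP, IS_NONSYN_STEP = _single_step_tables()


def codons_to_indices(seq: str) -> np.ndarray:
    """Encode an in-frame nucleotide string as sense-codon indices.

    Codons containing any non-ACGT character map to -1 (missing).
    Stop codons raise ValueError; callers decide masking policy upstream.
    """
    if len(seq) % 3:
        raise ValueError("sequence length is not a multiple of 3")
    out = np.empty(len(seq) // 3, dtype=np.int16)
    for k in range(0, len(seq), 3):
        codon = seq[k : k + 3].upper()
        idx = CODON_INDEX.get(codon)
        if idx is None:
            if codon in STOP_CODONS:
                raise ValueError(f"in-frame stop codon {codon} at codon column {k // 3 + 1}")
            idx = -1
        out[k // 3] = idx
    return out


def indices_to_codons(idx: np.ndarray, missing: str = "NNN") -> str:
    """Decode sense-codon indices back to a nucleotide string."""
    return "".join(missing if i < 0 else SENSE_CODONS[int(i)] for i in idx)
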