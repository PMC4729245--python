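"""Maximum-likelihood codon substitution models on a fixed topology.

The generator is Goldman–Yang-style: instantaneous rate i->j is nonzero
only for single-nucleotide changes and equals

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

scaled so one unit of branch length is one expected substitution per codon
at stationarity. Branch-class models share kappa, frequencies and branch
lengths but give each branch class its own omega:

* ``A`` — a single omega for every branch;
* ``B`` — internal vs external;
* ``C`` — internal vs external-social vs external-subsocial;
* ``D`` — internal plus one omega per external branch.

Site models M7 (omega ~ Beta(p, q) discretised into equal-probability
categories) and M8 (beta plus one extra class with omega > 1) treat omega
as varying over columns instead of branches; the M7-vs-M8 likelihood-ratio
test screens for positively selected sites.

Likelihoods come from Felsenstein pruning over the 61 sense-codon states
with per-node rescaling; fits alternate bounded quasi-Newton steps on the
global parameters (kappa, omegas / beta shape) with branch-length steps
that use an analytic gradient from a single outside-likelihood pass.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

from .genetic_code import (
    IS_NONSYN_STEP,
    IS_TRANSITION_STEP,
    N_CODONS,
    SENSE_CODONS,
    SINGLE_STEP,
)
from .seqio import (
    EXTERNAL_SOCIAL,
    EXTERNAL_SUBSOCIAL,
    INTERNAL,
    CodonAlignment,
    InputError,
    LabeledTree,
)

_FREQ_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# codon frequencies and the rate matrix
# ---------------------------------------------------------------------------

def empirical_codon_freqs(alignment: CodonAlignment, method: str = "f3x4") -> np.ndarray:
    """Stationary codon frequencies from the data.

    ``f3x4`` multiplies the per-codon-position nucleotide frequencies
    (PAML's common default); ``f61`` uses raw codon proportions. Both are
    floored at 1e-6 and renormalised over the 61 sense codons.
    """
    used = alignment.codons[alignment.codons >= 0].astype(np.int64)
    if used.size == 0:
        raise InputError("alignment has no non-missing codons")
    if method == "f61":
        freqs = np.bincount(used, minlength=N_CODONS).astype(float)
    elif method == "f3x4":
        base_order = "ACGT"
        pos_freq = np.zeros((3, 4))
        for i, codon in enumerate(SENSE_CODONS):
            cnt = np.count_nonzero(used == i)
            for pos, b in enumerate(codon):
                pos_freq[pos, base_order.index(b)] += cnt
        pos_freq /= pos_freq.sum(axis=1, keepdims=True)
        freqs = np.array(
            [
                pos_freq[0, base_order.index(c[0])]
                * pos_freq[1, base_order.index(c[1])]
                * pos_freq[2, base_order.index(c[2])]
                for c in SENSE_CODONS
            ]
        )
    else:
        raise ValueError(f"unknown frequency method {method!r}")
    freqs = np.maximum(freqs, _FREQ_FLOOR)
    return freqs / freqs.sum()


def _check_freqs(freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (N_CODONS,) or np.any(freqs <= 0) or not np.isfinite(freqs).all():
        raise ValueError("codon frequencies must be 61 positive finite numbers")
    if abs(freqs.sum() - 1.0) > 1e-8:
        raise ValueError("codon frequencies must sum to 1")
    return freqs


def unscaled_rate_matrix(kappa: float, omega: float, freqs: np.ndarray) -> tuple[np.ndarray, float]:
    """Generator before rate scaling, plus its expected substitution rate."""
    if not (np.isfinite(kappa) and kappa > 0):
        raise ValueError("kappa must be positive and finite")
    if not (np.isfinite(omega) and omega >= 0):
        raise ValueError("omega must be non-negative and finite")
    freqs = _check_freqs(freqs)
    q = np.where(SINGLE_STEP, freqs[None, :], 0.0)
    q = q * np.where(IS_TRANSITION_STEP, kappa, 1.0)
    q = q * np.where(IS_NONSYN_STEP, omega, 1.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = float(-np.dot(freqs, np.diag(q)))
    return q, rate


def build_rate_matrix(kappa: float, omega: float, freqs: np.ndarray) -> np.ndarray:
    """Scaled generator: one expected substitution per codon per unit time."""
    q, rate = unscaled_rate_matrix(kappa, omega, freqs)
    if rate <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return q / rate


class ReversibleEig:
    """Eigendecomposition of a reversible generator for fast P(t).

    Symmetrises S = D Q D^-1 with D = diag(sqrt(pi)), so P(t) =
    D^-1 U exp(L t) U^T D from one symmetric eigendecomposition. Falls
    back to scipy's scaling-and-squaring expm if the decomposition looks
    ill-conditioned.
    """

    def __init__(self, q: np.ndarray, freqs: np.ndarray):
        self.q = q
        self.freqs = freqs
        d = np.sqrt(freqs)
        s = (q * d[:, None]) / d[None, :]
        s = (s + s.T) / 2.0
        lam, u = np.linalg.eigh(s)
        self.lam = lam
        self.left = u / d[:, None]
        self.right = u.T * d[None, :]
        # sanity: reconstruct Q; if symmetrisation failed badly use expm
        self._ok = np.allclose((self.left * lam) @ self.right, q, atol=1e-8)

    def pmat(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be non-negative")
        if not self._ok:
            from scipy.linalg import expm

            p = expm(self.q * t)
        else:
            p = (self.left * np.exp(self.lam * t)) @ self.right
        # floor instead of clipping to exact zero: eigen-reconstruction noise
        # (~1e-15) on near-zero multi-step entries must not zero out whole
        # site likelihoods at short branch lengths
        np.maximum(p, 1e-16, out=p)
        return p


# ---------------------------------------------------------------------------
# tree compilation and the pruning engine
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    idx: int
    children: list[int]
    parent: int | None
    length: float | None
    name: str
    branch_class: str | None  # class of the edge above; None for root
    tip_row: int  # row in the alignment, -1 for internal


def _compile_tree(ltree: LabeledTree, taxa: list[str]) -> list[_Node]:
    """Deroot (merge a bifurcating root's two edges) and flatten to arrays."""
    tree = ltree.tree.clone(depth=1)
    root = tree.seed_node
    kids = root.child_nodes()
    if len(kids) == 2:
        c1, c2 = kids
        if c1.is_leaf() and not c2.is_leaf():
            c1, c2 = c2, c1
        merged = (c1.edge.length or 0.0) + (c2.edge.length or 0.0)
        root.remove_child(c1)
        root.remove_child(c2)
        c1.add_child(c2)
        c2.edge.length = merged
        tree.seed_node = c1
        c1.edge.length = None
        root = c1

    nodes: list[_Node] = []

    def classify(nd) -> str:
        if nd.is_leaf():
            return ltree.tip_class(nd.taxon.label)
        return INTERNAL

    def visit(nd, parent_idx: int | None) -> int:
        child_ids = []
        my_idx_holder = len(nodes)  # filled after children (postorder)
        for child in nd.child_nodes():
            child_ids.append(visit(child, None))
        idx = len(nodes)
        name = nd.taxon.label if nd.is_leaf() else f"internal_{idx}"
        nodes.append(
            _Node(
                idx=idx,
                children=child_ids,
                parent=None,
                length=None if nd is root else float(nd.edge.length if nd.edge.length is not None else 0.0),
                name=name,
                branch_class=None if nd is root else classify(nd),
                tip_row=taxa.index(nd.taxon.label) if nd.is_leaf() else -1,
            )
        )
        for c in child_ids:
            nodes[c].parent = idx
        return idx

    visit(root, None)
    return nodes


class PruningEngine:
    """Felsenstein pruning over compressed column patterns.

    Compiled once per (tree, alignment); evaluations take per-branch
    transition matrices. ``branch_ratios`` returns dL/dt divided by the
    per-pattern likelihood, the building block of analytic branch-length
    gradients for both plain and mixture (site-model) likelihoods.
    """

    def __init__(self, ltree: LabeledTree, alignment: CodonAlignment):
        tip_set = set(ltree.taxa)
        if tip_set != set(alignment.taxa):
            raise InputError("tree tips and alignment taxa differ")
        self.alignment = alignment
        self.nodes = _compile_tree(ltree, alignment.taxa)
        self.root = len(self.nodes) - 1
        self.branch_nodes = [n.idx for n in self.nodes if n.parent is not None]
        self.branch_names = [self.nodes[i].name for i in self.branch_nodes]
        self.branch_class = [self.nodes[i].branch_class for i in self.branch_nodes]
        self.init_lengths = np.array(
            [self.nodes[i].length if self.nodes[i].length is not None else np.nan
             for i in self.branch_nodes]
        )

        cols = alignment.codons.T  # (n_cols, n_taxa)
        patterns, inverse, counts = np.unique(
            cols, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns.T  # (n_taxa, n_pat)
        self.pattern_inverse = inverse
        self.weights = counts.astype(float)
        self.n_patterns = patterns.shape[0]

        eye = np.eye(N_CODONS)
        self._tip_partial: dict[int, np.ndarray] = {}
        for node in self.nodes:
            if node.tip_row >= 0:
                v = self.patterns[node.tip_row]
                out = np.ones((self.n_patterns, N_CODONS))
                mask = v >= 0
                out[mask] = eye[v[mask].astype(np.int64)]
                self._tip_partial[node.idx] = out

    # -- core passes ---------------------------------------------------

    def _down(self, pmats: dict[int, np.ndarray]):
        """Postorder partials. Returns (partials, M, logscale)."""
        n_pat = self.n_patterns
        partial: dict[int, np.ndarray] = {}
        m: dict[int, np.ndarray] = {}
        logscale = np.zeros(n_pat)
        for node in self.nodes:  # already postorder
            if node.children:
                prod = None
                for c in node.children:
                    mc = partial[c] @ pmats[c].T
                    m[c] = mc
                    prod = mc if prod is None else prod * mc
                if node.tip_row >= 0:
                    prod = prod * self._tip_partial[node.idx]
                scale = prod.max(axis=1)
                bad = scale <= 0
                if np.any(bad):
                    scale = np.where(bad, 1.0, scale)
                prod = prod / scale[:, None]
                logscale += np.log(scale)
                partial[node.idx] = prod
            else:
                partial[node.idx] = self._tip_partial[node.idx]
        return partial, m, logscale

    def site_loglik(self, pmats: dict[int, np.ndarray], freqs: np.ndarray,
                    return_cache: bool = False):
        """Per-pattern log-likelihood (and pruning cache if requested)."""
        partial, m, logscale = self._down(pmats)
        site_l = partial[self.root] @ freqs
        if np.any(~np.isfinite(site_l)) or np.any(site_l <= 0):
            bad = int(np.argmax(~np.isfinite(site_l) | (site_l <= 0)))
            col = int(np.argmax(self.pattern_inverse == bad)) + 1
            raise FloatingPointError(f"non-finite likelihood at codon column {col}")
        ll = np.log(site_l) + logscale
        if return_cache:
            return ll, (partial, m)
        return ll

    def loglik(self, pmats: dict[int, np.ndarray], freqs: np.ndarray) -> float:
        return float(np.dot(self.weights, self.site_loglik(pmats, freqs)))

    def branch_ratios(
        self,
        pmats: dict[int, np.ndarray],
        qpmats: dict[int, np.ndarray],
        freqs: np.ndarray,
        cache,
    ) -> np.ndarray:
        """(n_branches, n_pat) array of (dL/dt_b) / L per pattern."""
        partial, m = cache
        n_pat = self.n_patterns
        ratios = np.empty((len(self.branch_nodes), n_pat))
        pos = {b: k for k, b in enumerate(self.branch_nodes)}
        h: dict[int, np.ndarray] = {}

        for node in reversed(self.nodes):  # preorder
            if not node.children:
                continue
            if node.parent is None:
                base = np.broadcast_to(freqs, (n_pat, N_CODONS)).copy()
                if node.tip_row >= 0:
                    base = base * self._tip_partial[node.idx]
            else:
                base = h[node.idx] @ pmats[node.idx]
                sc = base.max(axis=1)
                sc = np.where(sc <= 0, 1.0, sc)
                base = base / sc[:, None]
                if node.tip_row >= 0:
                    base = base * self._tip_partial[node.idx]
            for c in node.children:
                hc = base
                for s in node.children:
                    if s != c:
                        hc = hc * m[s]
                h[c] = hc
                denom = np.einsum("pk,pk->p", hc, m[c])
                denom = np.where(denom <= 0, np.finfo(float).tiny, denom)
                dnum = np.einsum("pk,pk->p", hc, partial[c] @ qpmats[c].T)
                ratios[pos[c]] = dnum / denom
        return ratios


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class CodonModelParams:
    kappa: float
    omega_by_class: dict[str, float]
    codon_freqs: np.ndarray
    branch_lengths: dict[str, float]

    def __post_init__(self):
        self.codon_freqs = _check_freqs(self.codon_freqs)
        if not (np.isfinite(self.kappa) and self.kappa > 0):
            raise ValueError("kappa must be positive")
        for k, w in self.omega_by_class.items():
            if not (np.isfinite(w) and w >= 0):
                raise ValueError(f"omega for class {k!r} must be non-negative")


@dataclass
class SiteModelParams:
    model: str  # "M7" | "M8"
    beta_p: float
    beta_q: float
    p0: float = 1.0
    omega_s: float = 2.0
    n_categories: int = 10

    def categories(self) -> tuple[np.ndarray, np.ndarray]:
        """Discretised (omega, weight) categories; weights sum to 1."""
        k = self.n_categories
        quantiles = (2 * np.arange(k) + 1) / (2 * k)
        omegas = stats.beta.ppf(quantiles, self.beta_p, self.beta_q)
        if self.model == "M7":
            return omegas, np.full(k, 1.0 / k)
        if self.model == "M8":
            w = np.append(np.full(k, self.p0 / k), 1.0 - self.p0)
            return np.append(omegas, self.omega_s), w
        raise ValueError(f"unknown site model {self.model!r}")


@dataclass
class CodonModelFit:
    model: str
    params: object
    log_likelihood: float
    n_free_params: int
    converged: bool
    optimizer_trace: list = field(default_factory=list)
    details: dict = field(default_factory=dict)


@dataclass
class LrtResult:
    statistic: float
    df: int
    p_value: float
    null_model: str
    alt_model: str


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    max_rounds: int = 30
    tol: float = 1e-6
    n_starts: int = 1
    jitter: float = 0.3
    global_maxiter: int = 60
    bl_maxiter: int = 60
    seed: int = 0
    min_branch: float = 1e-7
    max_branch: float = 20.0
    freqs_method: str = "f3x4"


_NT_DIFFS = None


def _codon_nt_diff_table() -> np.ndarray:
    global _NT_DIFFS
    if _NT_DIFFS is None:
        t = np.zeros((N_CODONS, N_CODONS), dtype=np.int8)
        for i, a in enumerate(SENSE_CODONS):
            for j, b in enumerate(SENSE_CODONS):
                t[i, j] = sum(x != y for x, y in zip(a, b))
        _NT_DIFFS = t
    return _NT_DIFFS


def _pairwise_codon_distances(alignment: CodonAlignment) -> np.ndarray:
    """Rough JC-corrected substitutions per codon for branch-length init."""
    tbl = _codon_nt_diff_table()
    n = alignment.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = alignment.codons[i], alignment.codons[j]
            keep = (a >= 0) & (b >= 0)
            if not keep.any():
                d[i, j] = d[j, i] = 0.3
                continue
            p = tbl[a[keep].astype(np.int64), b[keep].astype(np.int64)].sum() / (3.0 * keep.sum())
            p = min(p, 0.70)
            d[i, j] = d[j, i] = 3.0 * (-0.75 * np.log1p(-4.0 * p / 3.0))
    return d


def _init_branch_lengths(engine: PruningEngine, alignment: CodonAlignment,
                         cfg: FitConfig) -> np.ndarray:
    """Non-negative least-squares branch lengths from pairwise distances."""
    nodes = engine.nodes
    below: dict[int, set[int]] = {}
    for node in nodes:
        if node.tip_row >= 0 and not node.children:
            below[node.idx] = {node.tip_row}
        else:
            s = set().union(*(below[c] for c in node.children)) if node.children else set()
            if node.tip_row >= 0:
                s.add(node.tip_row)
            below[node.idx] = s
    n = alignment.n_taxa
    pairs = list(itertools.combinations(range(n), 2))
    a = np.zeros((len(pairs), len(engine.branch_nodes)))
    for k, b in enumerate(engine.branch_nodes):
        sub = below[b]
        for r, (i, j) in enumerate(pairs):
            if (i in sub) != (j in sub):
                a[r, k] = 1.0
    d = _pairwise_codon_distances(alignment)
    y = np.array([d[i, j] for i, j in pairs])
    try:
        x, _ = optimize.nnls(a, y)
    except Exception:
        x = np.full(a.shape[1], 0.05)
    return np.clip(x, cfg.min_branch * 10, cfg.max_branch)


def branch_classes_for_model(engine: PruningEngine, model: str) -> tuple[list[str], list[int]]:
    """Class names and per-branch class index for a branch-model tag."""
    classes = engine.branch_class
    if model == "A":
        names = ["all"]
        idx = [0] * len(classes)
    elif model == "B":
        names = ["internal", "external"]
        idx = [0 if c == INTERNAL else 1 for c in classes]
    elif model == "C":
        names = ["internal", "external_social", "external_subsocial"]
        lut = {INTERNAL: 0, EXTERNAL_SOCIAL: 1, EXTERNAL_SUBSOCIAL: 2}
        idx = [lut[c] for c in classes]
    elif model == "D":
        names = ["internal"]
        idx = []
        for c, name in zip(classes, engine.branch_names):
            if c == INTERNAL:
                idx.append(0)
            else:
                names.append(name)
                idx.append(len(names) - 1)
    else:
        raise ValueError(f"unknown branch model tag {model!r}")
    present = sorted(set(idx))
    if len(present) < len(names):  # drop classes with no branch (small trees)
        remap = {old: new for new, old in enumerate(present)}
        names = [names[old] for old in present]
        idx = [remap[i] for i in idx]
    return names, idx


def _branch_pmats(engine, eigs_by_class, class_idx, lengths,
                  with_qp=False):
    pmats, qpmats = {}, {}
    for k, b in enumerate(engine.branch_nodes):
        eig = eigs_by_class[class_idx[k]]
        p = eig.pmat(lengths[k])
        pmats[b] = p
        if with_qp:
            qpmats[b] = eig.q @ p
    return (pmats, qpmats) if with_qp else pmats


def _optimize_branch_model(engine, alignment, class_names, class_idx, cfg,
                           freqs, init_kappa=2.0, init_omegas=None,
                           init_lengths=None):
    n_classes = len(class_names)
    if init_omegas is None:
        init_omegas = np.full(n_classes, 0.2)
    if init_lengths is None:
        if np.all(np.isfinite(engine.init_lengths)) and engine.init_lengths.sum() > 0:
            init_lengths = np.clip(engine.init_lengths, cfg.min_branch * 10, cfg.max_branch)
        else:
            init_lengths = _init_branch_lengths(engine, alignment, cfg)

    kappa = float(init_kappa)
    omegas = np.asarray(init_omegas, dtype=float)
    lengths = np.asarray(init_lengths, dtype=float)
    trace: list[tuple[int, float]] = []

    def eigs_for(kp, oms):
        return [ReversibleEig(build_rate_matrix(kp, w, freqs), freqs) for w in oms]

    def neg_ll_global(x):
        kp = np.exp(x[0])
        oms = np.exp(x[1:])
        pm = _branch_pmats(engine, eigs_for(kp, oms), class_idx, lengths)
        return -engine.loglik(pm, freqs)

    def neg_ll_branches(x, eigs):
        t = np.exp(x)
        pm, qp = _branch_pmats(engine, eigs, class_idx, t, with_qp=True)
        ll_pat, cache = engine.site_loglik(pm, freqs, return_cache=True)
        ratios = engine.branch_ratios(pm, qp, freqs, cache)
        grad_t = ratios @ engine.weights
        ll = float(np.dot(engine.weights, ll_pat))
        return -ll, -(grad_t * t)  # chain rule for log-lengths

    last = -np.inf
    converged = False
    bounds_global = [(np.log(0.01), np.log(100.0))] + \
                    [(np.log(1e-4), np.log(49.0))] * n_classes
    bounds_bl = [(np.log(cfg.min_branch), np.log(cfg.max_branch))] * len(lengths)
    for rnd in range(cfg.max_rounds):
        res = optimize.minimize(
            neg_ll_global,
            np.log(np.concatenate([[kappa], omegas])),
            method="L-BFGS-B",
            bounds=bounds_global,
            options={"maxiter": cfg.global_maxiter, "ftol": 1e-10},
        )
        kappa = float(np.exp(res.x[0]))
        omegas = np.exp(res.x[1:])

        eigs = eigs_for(kappa, omegas)  # fixed during the branch-length phase
        res = optimize.minimize(
            neg_ll_branches,
            np.log(np.maximum(lengths, cfg.min_branch)),
            args=(eigs,),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds_bl,
            options={"maxiter": cfg.bl_maxiter, "ftol": 1e-10},
        )
        lengths = np.exp(res.x)
        ll = -float(res.fun)
        trace.append((rnd, ll))
        if ll - last < cfg.tol and rnd > 0:
            converged = True
            break
        last = ll

    return kappa, omegas, lengths, ll, converged, trace


def fit_branch_model(
    tree: LabeledTree,
    alignment: CodonAlignment,
    model: str = "A",
    config: FitConfig | None = None,
    custom_classes: tuple[list[str], list[int]] | None = None,
    init: dict | None = None,
    freqs: np.ndarray | None = None,
) -> CodonModelFit:
    """ML fit of a branch-class dN/dS model on the fixed topology.

    ``model`` is one of A/B/C/D (see module docstring) or any tag when
    ``custom_classes`` supplies an explicit (class names, per-branch class
    index) partition. ``init`` may carry ``kappa``, ``omegas`` and
    ``lengths`` warm starts (e.g. from a nested fit).
    """
    cfg = config or FitConfig()
    engine = init.pop("engine") if init and "engine" in init else PruningEngine(tree, alignment)
    if custom_classes is not None:
        class_names, class_idx = custom_classes
    else:
        class_names, class_idx = branch_classes_for_model(engine, model)
    if freqs is None:
        freqs = empirical_codon_freqs(alignment, cfg.freqs_method)
    init = init or {}

    rng = np.random.default_rng(cfg.seed)
    best = None
    for start in range(max(1, cfg.n_starts)):
        kw = dict(
            init_kappa=init.get("kappa", 2.0),
            init_omegas=init.get("omegas"),
            init_lengths=init.get("lengths"),
        )
        if start > 0:
            kw["init_kappa"] = kw["init_kappa"] * np.exp(rng.normal(0, cfg.jitter))
            base = kw["init_omegas"] if kw["init_omegas"] is not None else np.full(len(class_names), 0.2)
            kw["init_omegas"] = np.asarray(base) * np.exp(rng.normal(0, cfg.jitter, len(class_names)))
        out = _optimize_branch_model(engine, alignment, class_names, class_idx,
                                     cfg, freqs, **kw)
        if best is None or out[3] > best[3]:
            best = out
    kappa, omegas, lengths, ll, converged, trace = best
    if not converged:
        import warnings

        warnings.warn(f"branch model {model}: optimizer hit max_rounds without "
                      f"meeting tol={cfg.tol}")

    params = CodonModelParams(
        kappa=kappa,
        omega_by_class=dict(zip(class_names, map(float, omegas))),
        codon_freqs=freqs,
        branch_lengths=dict(zip(engine.branch_names, map(float, lengths))),
    )
    n_free = 1 + len(class_names) + len(lengths)
    return CodonModelFit(
        model=model,
        params=params,
        log_likelihood=ll,
        n_free_params=n_free,
        converged=converged,
        optimizer_trace=trace,
        details={
            "class_of_branch": dict(zip(engine.branch_names,
                                        [class_names[i] for i in class_idx])),
            "freqs_method": cfg.freqs_method,
            "engine": engine,
        },
    )


# -- site models ------------------------------------------------------------

def _site_model_loglik(engine, freqs, kappa, sparams: SiteModelParams,
                       lengths, want_grad=False):
    omegas, wts = sparams.categories()
    keep = wts > 0
    omegas, wts = omegas[keep], wts[keep]
    qs, rates = zip(*(unscaled_rate_matrix(kappa, w, freqs) for w in omegas))
    rho = float(np.dot(wts, rates))
    eigs = [ReversibleEig(q / rho, freqs) for q in qs]

    per_cat_ll = []
    per_cat_ratio = []
    for eig in eigs:
        pm = {b: eig.pmat(lengths[k]) for k, b in enumerate(engine.branch_nodes)}
        if want_grad:
            qp = {b: eig.q @ pm[b] for b in engine.branch_nodes}
            ll_pat, cache = engine.site_loglik(pm, freqs, return_cache=True)
            per_cat_ratio.append(engine.branch_ratios(pm, qp, freqs, cache))
        else:
            ll_pat = engine.site_loglik(pm, freqs)
        per_cat_ll.append(ll_pat)
    ll_mat = np.stack(per_cat_ll)  # (n_cat, n_pat)
    logw = np.log(wts)[:, None]
    ll_pat = logsumexp(ll_mat + logw, axis=0)
    ll = float(np.dot(engine.weights, ll_pat))
    if not want_grad:
        return ll
    post = np.exp(ll_mat + logw - ll_pat[None, :])  # category responsibilities
    ratio = np.einsum("kp,kbp->bp", post, np.stack(per_cat_ratio))
    grad_t = ratio @ engine.weights
    return ll, grad_t


def fit_site_model(
    tree: LabeledTree,
    alignment: CodonAlignment,
    model: str = "M7",
    n_categories: int = 10,
    config: FitConfig | None = None,
    fix: dict | None = None,
    init: dict | None = None,
    freqs: np.ndarray | None = None,
) -> CodonModelFit:
    """ML fit of the M7 or M8 site-mixture model.

    The omega distribution is discretised into ``n_categories``
    equal-probability beta categories (quantile midpoints); M8 appends the
    (1 - p0, omega_s > 1) class. ``fix`` pins named parameters (e.g.
    ``{"p0": 1.0}`` turns M8 into M7 for nesting checks).
    """
    if model not in ("M7", "M8"):
        raise ValueError(f"unknown site model {model!r}")
    if n_categories < 2:
        raise ValueError("n_categories must be >= 2")
    cfg = config or FitConfig()
    fix = fix or {}
    init = init or {}
    engine = init.pop("engine", None) or PruningEngine(tree, alignment)
    if freqs is None:
        freqs = empirical_codon_freqs(alignment, cfg.freqs_method)
    lengths = init.get("lengths")
    if lengths is None:
        lengths = _init_branch_lengths(engine, alignment, cfg)
    lengths = np.asarray(lengths, dtype=float)
    kappa = float(init.get("kappa", 2.0))

    # global parameter vector layout (log/logit transforms)
    names = ["kappa", "beta_p", "beta_q"]
    if model == "M8":
        names += ["p0", "omega_s"]
    defaults = {"kappa": kappa, "beta_p": init.get("beta_p", 0.8),
                "beta_q": init.get("beta_q", 2.0),
                "p0": init.get("p0", 0.9), "omega_s": init.get("omega_s", 2.0)}

    def pack() -> tuple[np.ndarray, list[str]]:
        free = [n for n in names if n not in fix]
        x = []
        for n in free:
            v = defaults[n]
            if n == "p0":
                v = min(max(v, 1e-4), 1 - 1e-4)
                x.append(np.log(v / (1 - v)))
            elif n == "omega_s":
                x.append(np.log(max(v - 1.0, 1e-4)))
            else:
                x.append(np.log(v))
        return np.array(x), free

    def unpack(x, free) -> dict:
        vals = dict(defaults)
        vals.update(fix)
        for n, xi in zip(free, x):
            if n == "p0":
                vals[n] = 1.0 / (1.0 + np.exp(-xi))
            elif n == "omega_s":
                vals[n] = 1.0 + np.exp(xi)
            else:
                vals[n] = np.exp(xi)
        return vals

    def sparams_from(vals) -> SiteModelParams:
        return SiteModelParams(model, vals["beta_p"], vals["beta_q"],
                               vals.get("p0", 1.0), vals.get("omega_s", 2.0),
                               n_categories)

    bounds_of = {"kappa": (np.log(0.01), np.log(100.0)),
                 "beta_p": (np.log(0.005), np.log(99.0)),
                 "beta_q": (np.log(0.005), np.log(99.0)),
                 "p0": (-12.0, 12.0),
                 "omega_s": (np.log(1e-3), np.log(49.0))}

    trace, last, converged = [], -np.inf, False
    ll = -np.inf
    for rnd in range(cfg.max_rounds):
        x0, free = pack()

        # one extra tree-length scale decouples the mixture-average rate
        # normalisation from the shape parameters: changing the omega
        # distribution rescales every category's generator, which at fixed
        # branch lengths would otherwise mask genuine improvements
        def neg_global(x):
            vals = unpack(x[:-1], free)
            scale = np.exp(x[-1])
            return -_site_model_loglik(engine, freqs, vals["kappa"],
                                       sparams_from(vals), lengths * scale)

        res = optimize.minimize(neg_global, np.append(x0, 0.0), method="L-BFGS-B",
                                bounds=[bounds_of[n] for n in free] + [(-4.0, 4.0)],
                                options={"maxiter": cfg.global_maxiter, "ftol": 1e-10})
        vals = unpack(res.x[:-1], free)
        lengths = lengths * np.exp(res.x[-1])
        defaults.update({k: vals[k] for k in names})
        sp = sparams_from(vals)

        def neg_bl(x):
            t = np.exp(x)
            ll_, grad = _site_model_loglik(engine, freqs, vals["kappa"], sp, t,
                                           want_grad=True)
            return -ll_, -(grad * t)

        res = optimize.minimize(
            neg_bl, np.log(np.maximum(lengths, cfg.min_branch)), jac=True,
            method="L-BFGS-B",
            bounds=[(np.log(cfg.min_branch), np.log(cfg.max_branch))] * len(lengths),
            options={"maxiter": cfg.bl_maxiter, "ftol": 1e-10},
        )
        lengths = np.exp(res.x)
        ll = -float(res.fun)
        trace.append((rnd, ll))
        if ll - last < cfg.tol and rnd > 0:
            converged = True
            break
        last = ll

    sp = sparams_from({**defaults, **fix})
    n_free = 1 + len(lengths) + (2 if model == "M7" else 4) - len(fix)
    return CodonModelFit(
        model=model,
        params=sp,
        log_likelihood=ll,
        n_free_params=n_free,
        converged=converged,
        optimizer_trace=trace,
        details={"kappa": defaults["kappa"],
                 "branch_lengths": dict(zip(engine.branch_names, map(float, lengths))),
                 "freqs_method": cfg.freqs_method,
                 "engine": engine},
    )


# -- LRT and regrouping -----------------------------------------------------

_NESTED = {("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"),
           ("C", "D"), ("M7", "M8")}


def likelihood_ratio_test(fit_null: CodonModelFit, fit_alt: CodonModelFit) -> LrtResult:
    """Chi-squared LRT of two nested fits.

    Statistic -2(lnL0 - lnL1) clamped at zero; df is the free-parameter
    difference. Boundary cases (M7 vs M8) are tested against chi2(2), the
    conventional, mildly conservative choice.
    """
    pair = (fit_null.model, fit_alt.model)
    nested = pair in _NESTED or fit_alt.model.startswith("regroup")
    if not nested:
        raise ValueError(f"models {pair} are not a recognised nested pair")
    df = fit_alt.n_free_params - fit_null.n_free_params
    if df <= 0:
        raise ValueError("alternative model must have more free parameters")
    stat = max(0.0, 2.0 * (fit_alt.log_likelihood - fit_null.log_likelihood))
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return LrtResult(stat, df, p, fit_null.model, fit_alt.model)


def regroup_branch_test(
    tree: LabeledTree,
    alignment: CodonAlignment,
    focal_species: str,
    partner_sets: list[list[str]],
    config: FitConfig | None = None,
    fit_single: CodonModelFit | None = None,
) -> list[dict]:
    """Refit the 3-class branch model with the focal tip regrouped.

    For each partner set the external branches of ``focal_species`` and its
    partners form one omega class, all other external branches a second,
    and internal branches the third; each refit is compared to the
    single-omega model by LRT. An empty partner set falls back to the
    mating-system (model C) classing.
    """
    cfg = config or FitConfig()
    engine = PruningEngine(tree, alignment)
    if focal_species not in engine.branch_names:
        raise InputError(f"focal species {focal_species!r} is not a tip of the tree")
    if fit_single is None:
        fit_single = fit_branch_model(tree, alignment, "A", config=cfg,
                                      init={"engine": engine})
    warm = {
        "kappa": fit_single.params.kappa,
        "lengths": np.array([fit_single.params.branch_lengths[n]
                             for n in engine.branch_names]),
    }
    rows = []
    for partners in partner_sets:
        missing = [p for p in partners if p not in engine.branch_names]
        if missing:
            raise InputError(f"partner tips not in tree: {', '.join(missing)}")
        if not partners:
            names, idx = branch_classes_for_model(engine, "C")
            tag = "regroup:C"
        else:
            group = {focal_species, *partners}
            names = ["internal", "focal_group", "other_external"]
            idx = []
            for c, nm in zip(engine.branch_class, engine.branch_names):
                if c == INTERNAL:
                    idx.append(0)
                elif nm in group:
                    idx.append(1)
                else:
                    idx.append(2)
            tag = "regroup:" + "+".join(sorted(group))
        fit = fit_branch_model(tree, alignment, tag, config=cfg,
                               custom_classes=(names, idx),
                               init={"engine": engine, **warm})
        lrt = likelihood_ratio_test(fit_single, fit)
        rows.append({
            "partners": list(partners),
            "fit": fit,
            "omega": fit.params.omega_by_class,
            "lnL": fit.log_likelihood,
            "lrt_vs_single": lrt,
        })
    return rows
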