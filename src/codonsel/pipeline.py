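"""End-to-end analysis pipeline and report rendering.

Runs, in a fixed order mirroring the underlying study design: input
validation, the ENC codon-usage comparison (bootstrap CI + permutation
test), the M7-vs-M8 positive-selection screen, branch-class dN/dS models
A-D with likelihood-ratio tests, an optional regrouping robustness check
for a focal taxon, and NG86 synonymous distances with strict-clock node
dating. Every stage's outputs land in the run directory as TSV plus one
machine-readable JSON bundle; re-running with the same config and seed
reproduces the reports byte for byte (timings go only to the log).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .codon_model import (
    CodonModelFit,
    FitConfig,
    LrtResult,
    fit_branch_model,
    fit_site_model,
    likelihood_ratio_test,
    regroup_branch_test,
)
from .codon_usage import enc_report
from .divergence import DEFAULT_MU, date_nodes, node_mean_ds, pairwise_ds_matrix
from .seqio import (
    SOCIAL,
    CodonAlignment,
    LabeledTree,
    read_codon_alignment,
    read_labeled_tree,
    read_mating_map,
)

log = logging.getLogger("codonsel")


@dataclass
class RunConfig:
    """Paths, estimator choices and resampling sizes for one full run."""

    alignment: str
    tree: str
    labels: str
    out_dir: str = "codonsel_run"
    seed: int = 0
    n_boot: int = 1000
    n_perm: int = 1000
    enc_estimator: str = "wright"
    freqs_method: str = "f3x4"
    n_categories: int = 10
    mu: float = DEFAULT_MU
    generation_time: float = 1.0
    focal_species: str | None = None  # default: first social species
    regroup_partner_sets: list = field(default_factory=lambda: [[]])
    mask_stops: bool = False
    resolve_polytomies: bool = False
    fit: dict = field(default_factory=dict)  # FitConfig overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def validate(self) -> None:
        for p in (self.alignment, self.tree, self.labels):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.n_boot < 1 or self.n_perm < 1:
            raise ValueError("resampling sizes must be >= 1")


def _fit_row(fit: CodonModelFit) -> dict:
    return {
        "model": fit.model,
        "lnL": fit.log_likelihood,
        "omega": dict(fit.params.omega_by_class),
        "kappa": fit.params.kappa,
        "n_free_params": fit.n_free_params,
        "converged": fit.converged,
    }


def _stars(p: float) -> str:
    return "**" if p < 0.01 else "*" if p < 0.05 else "NS"


def render_table1(fits: dict[str, CodonModelFit],
                  lrts: dict[tuple[str, str], LrtResult]) -> str:
    """Model-comparison table: -lnL to 6 decimals, omega to 4, LRT column.

    Significance stars use unadjusted chi-squared p-values at 0.05/0.01,
    with no multiple-testing correction (noted in the footer).
    """
    lines = ["Model\t-lnL\tdN/dS ratio\t-2dlnL"]
    for tag in ("A", "B", "C", "D"):
        fit = fits.get(tag)
        if fit is None:
            lines.append(f"{tag}\tNA\tNA\t(fit missing)")
            continue
        omega = " ".join(
            f"{v:.4f} ({k})" for k, v in fit.params.omega_by_class.items()
        )
        tests = " ".join(
            f"{a} vs. {b}: {r.statistic:.2f} {_stars(r.p_value)}"
            for (a, b), r in sorted(lrts.items())
            if b == tag
        )
        lines.append(f"{tag}\t{-fit.log_likelihood:.6f}\t{omega}\t{tests}")
    lines.append("# LRT stars: * p<0.05, ** p<0.01 (chi-squared, unadjusted; "
                 "no multiple-testing correction)")
    return "\n".join(lines) + "\n"


def _annotated_newick(tree: LabeledTree, fit_d: CodonModelFit,
                      dating) -> str:
    """Newick with per-branch omega comments (model D) and node ages."""
    import dendropy

    # fresh taxon namespace: annotation must not rename the caller's taxa
    t = dendropy.Tree.get(data=tree.to_newick(), schema="newick",
                          preserve_underscores=True)
    omegas = fit_d.params.omega_by_class
    for leaf in t.leaf_node_iter():
        name = leaf.taxon.label
        if name in omegas:
            leaf.taxon.label = f"{name}[&omega={omegas[name]:.4f}]"
    age_by_node = {r["node"]: r["age_my"] for r in dating.records}
    k = 0
    for nd in t.preorder_node_iter():
        if not nd.is_leaf():
            k += 1
            age = age_by_node.get(f"node{k}")
            if age is not None:
                nd.label = f"age_My={age:.3f}"
    return t.as_string(schema="newick", suppress_rooting=True,
                       unquoted_underscores=True)


def load_inputs(config: RunConfig) -> tuple[CodonAlignment, LabeledTree, dict]:
    labels = read_mating_map(config.labels)
    alignment = read_codon_alignment(config.alignment, mask_stops=config.mask_stops)
    tree = read_labeled_tree(config.tree, labels,
                             resolve_polytomies=config.resolve_polytomies)
    if set(tree.taxa) != set(alignment.taxa):
        raise ValueError("tree tips and alignment taxa differ")
    return alignment, tree, labels


def run_full_analysis(
    config: RunConfig,
    alignment: CodonAlignment | None = None,
    tree: LabeledTree | None = None,
    labels: dict | None = None,
) -> dict:
    """Execute every stage and write the report bundle.

    In-memory inputs may be passed directly (bypassing the config paths),
    which is how the simulate subcommand and the test-suite drive the
    pipeline. Returns the machine-readable result bundle (also written as
    ``run.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    bundle: dict = {"config": {k: v for k, v in asdict(config).items()},
                    "version": __version__, "seed": config.seed}
    t_start = time.time()
    try:
        # stage 1: inputs
        if alignment is None or tree is None or labels is None:
            config.validate()
            alignment, tree, labels = load_inputs(config)
        log.info("inputs: %d taxa x %d codons", alignment.n_taxa, alignment.n_codons)

        fitcfg = FitConfig(seed=config.seed, freqs_method=config.freqs_method,
                           **config.fit)

        # stage 2: codon usage bias
        t0 = time.time()
        enc = enc_report(alignment, labels, n_boot=config.n_boot,
                         n_perm=config.n_perm, seed=config.seed,
                         estimator=config.enc_estimator)
        (out / "enc_report.tsv").write_text(enc.to_tsv())
        bundle["enc"] = {
            "per_species": enc.per_species_enc,
            "group_means": enc.group_means,
            "group_ci": enc.group_ci,
            "permutation_p": enc.permutation["p_value"],
            "permutation_mode": enc.permutation["mode"],
            "observed_difference": enc.permutation["observed"],
        }
        log.info("ENC stage done in %.1fs (perm p=%.4g)",
                 time.time() - t0, enc.permutation["p_value"])

        # stage 3: site-model screen (before branch models)
        t0 = time.time()
        m7 = fit_site_model(tree, alignment, "M7", config.n_categories, config=fitcfg)
        m8 = fit_site_model(
            tree, alignment, "M8", config.n_categories, config=fitcfg,
            init={"beta_p": m7.params.beta_p, "beta_q": m7.params.beta_q,
                  "kappa": m7.details["kappa"],
                  "lengths": np.array(list(m7.details["branch_lengths"].values()))},
        )
        screen = likelihood_ratio_test(m7, m8)
        site_tsv = (
            "model\tlnL\tparams\n"
            f"M7\t{m7.log_likelihood:.6f}\tp={m7.params.beta_p:.4f},q={m7.params.beta_q:.4f}\n"
            f"M8\t{m8.log_likelihood:.6f}\tp={m8.params.beta_p:.4f},q={m8.params.beta_q:.4f},"
            f"p0={m8.params.p0:.4f},omega_s={m8.params.omega_s:.4f}\n"
            f"LRT\t{screen.statistic:.4f}\tdf={screen.df},p={screen.p_value:.4g}\n"
        )
        (out / "site_models.tsv").write_text(site_tsv)
        bundle["site_screen"] = {"m7_lnL": m7.log_likelihood,
                                 "m8_lnL": m8.log_likelihood,
                                 "statistic": screen.statistic,
                                 "df": screen.df, "p_value": screen.p_value}
        if screen.p_value < 0.05:
            log.warning("site screen: M8 preferred (p=%.3g) — possible "
                        "positively selected sites; branch-model omegas "
                        "may mix selection regimes", screen.p_value)
        log.info("site screen done in %.1fs", time.time() - t0)

        # stage 4: branch models A-D + LRTs
        t0 = time.time()
        fits: dict[str, CodonModelFit] = {}
        engine = None
        warm: dict = {}
        for tag in ("A", "B", "C", "D"):
            init = dict(warm)
            if engine is not None:
                init["engine"] = engine
            fits[tag] = fit_branch_model(tree, alignment, tag, config=fitcfg,
                                         init=init or None)
            engine = fits[tag].details["engine"]
            f = fits[tag]
            warm = {"kappa": f.params.kappa,
                    "lengths": np.array([f.params.branch_lengths[n]
                                         for n in engine.branch_names])}
        lrts = {}
        for null, alt in (("A", "B"), ("A", "C"), ("A", "D"),
                          ("B", "C"), ("B", "D"), ("C", "D")):
            lrts[(null, alt)] = likelihood_ratio_test(fits[null], fits[alt])
        (out / "branch_models.tsv").write_text(render_table1(fits, lrts))
        bundle["branch_models"] = {tag: _fit_row(f) for tag, f in fits.items()}
        bundle["lrt"] = {
            f"{a}_vs_{b}": {"statistic": r.statistic, "df": r.df, "p_value": r.p_value}
            for (a, b), r in lrts.items()
        }
        log.info("branch models done in %.1fs", time.time() - t0)

        # stage 5: regrouping robustness check
        t0 = time.time()
        focal = config.focal_species
        if focal is None:
            social = [t for t in alignment.taxa if labels[t] == SOCIAL]
            focal = social[0] if social else None
        regroup_rows = []
        if focal is not None:
            rows = regroup_branch_test(tree, alignment, focal,
                                       config.regroup_partner_sets,
                                       config=fitcfg, fit_single=fits["A"])
            lines = ["focal\tpartners\tlnL\tomega\tLRT_vs_single"]
            for r in rows:
                lrt = r["lrt_vs_single"]
                lines.append(
                    f"{focal}\t{','.join(r['partners']) or '-'}\t{r['lnL']:.6f}\t"
                    + ";".join(f"{k}={v:.4f}" for k, v in r["omega"].items())
                    + f"\t{lrt.statistic:.2f} (df={lrt.df}) {_stars(lrt.p_value)}"
                )
                regroup_rows.append({"partners": r["partners"], "lnL": r["lnL"],
                                     "omega": r["omega"],
                                     "lrt": {"statistic": lrt.statistic,
                                             "df": lrt.df, "p_value": lrt.p_value}})
            (out / "regroup.tsv").write_text("\n".join(lines) + "\n")
        else:
            (out / "regroup.tsv").write_text("# no social species: stage skipped\n")
        bundle["regroup"] = {"focal": focal, "rows": regroup_rows}
        log.info("regroup stage done in %.1fs", time.time() - t0)

        # stage 6: synonymous distances + dating
        t0 = time.time()
        ds = pairwise_ds_matrix(alignment)
        (out / "distances.tsv").write_text(ds.to_tsv())
        node_ds = node_mean_ds(tree, ds)
        dating = date_nodes(node_ds, mu=config.mu,
                            generation_time=config.generation_time)
        (out / "dating.tsv").write_text(dating.to_tsv())
        (out / "annotated.nwk").write_text(
            _annotated_newick(tree, fits["D"], dating))
        def _finite(mat):  # saturated distances serialise as null
            return [[v if np.isfinite(v) else None for v in row] for row in mat]

        bundle["distances"] = {"taxa": ds.taxa, "ds": _finite(ds.ds),
                               "dn": _finite(ds.dn), "method": ds.method}
        bundle["dating"] = {
            "mu": config.mu,
            "generation_time": config.generation_time,
            "nodes": [{k: (None if isinstance(v, float) and not np.isfinite(v) else v)
                       for k, v in r.items() if k != "clades"}
                      for r in dating.records],
        }
        log.info("dating stage done in %.1fs", time.time() - t0)

        (out / "run.json").write_text(json.dumps(bundle, indent=1, sort_keys=True,
                                                 default=float))
        log.info("run complete in %.1fs", time.time() - t_start)
        return bundle
    except Exception:
        log.exception("pipeline stage failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
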