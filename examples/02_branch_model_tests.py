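"""Branch-class dN/dS models and their likelihood-ratio tests.

Simulates an alignment in which external social branches evolve with a
higher dN/dS (omega = 0.2534) than external subsocial branches (0.1018),
then fits the nested model ladder: A (single omega), B (internal vs
external), C (adds the social/subsocial split), D (one omega per external
branch). If model C beats A and B by chi-squared LRT, the data support
class-specific selection pressure; the fitted omegas estimate its size.
"""

import numpy as np

from codonsel import FitConfig, fit_branch_model, likelihood_ratio_test, make_study_fixture
from codonsel.pipeline import render_table1

alignment, tree, _, truth = make_study_fixture(seed=2, n_codons=600)
print("true omegas:", truth["omega_by_class"])

fits, warm, engine = {}, {}, None
for tag in ("A", "B", "C", "D"):
    init = dict(warm, engine=engine) if engine else None
    fits[tag] = fit_branch_model(tree, alignment, tag, config=FitConfig(), init=init)
    engine = fits[tag].details["engine"]
    warm = {"kappa": fits[tag].params.kappa,
            "lengths": np.array([fits[tag].params.branch_lengths[n]
                                 for n in engine.branch_names])}

lrts = {}
for null, alt in (("A", "B"), ("A", "C"), ("A", "D"),
                  ("B", "C"), ("B", "D"), ("C", "D")):
    lrts[(null, alt)] = likelihood_ratio_test(fits[null], fits[alt])

print(render_table1(fits, lrts))
c = fits["C"].params.omega_by_class
print(f"model C: social omega {c['external_social']:.4f} vs "
      f"subsocial {c['external_subsocial']:.4f} — a higher social value is "
      "the reduced-selection-effectiveness signature")
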