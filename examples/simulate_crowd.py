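"""Generate a synthetic crowdsourcing dataset and summarise the annotators.

200 items are sampled uniformly on [0, 2pi] x [-1, 1] with a sinusoidal
class boundary (z = 0 iff sin(x1) < x2); ten annotators with condition-
specific drift/diffusion parameters drawn from the experiment-1 priors label
every item by drift-diffusion path simulation (dt = 0.01 s).
"""

import numpy as np

from ddmcrowd import annotator_sensitivity_specificity, experiment_preset, make_dataset

cfg = experiment_preset(1, seed=0)
ds, annotators = make_dataset(cfg)

print(f"{ds.n_items} items, {ds.n_annotators} annotators, "
      f"{int(ds.z.sum())} items in class 1")
print(f"{'j':>2} {'mu0':>5} {'sig0':>5} {'mu1':>5} {'sig1':>5} "
      f"{'sens%':>6} {'spec%':>6} {'emp.acc%':>8} {'mean RT (s)':>11}")
for j, a in enumerate(annotators):
    sens, spec = annotator_sensitivity_specificity(a)
    emp = 100 * np.mean(ds.y[:, j] == ds.z)
    print(f"{j:>2} {a.mu0:5.2f} {a.sigma0:5.2f} {a.mu1:5.2f} {a.sigma1:5.2f} "
          f"{100*sens:6.1f} {100*spec:6.1f} {emp:8.1f} {ds.rt[:, j].mean():11.2f}")
print("Analytic sensitivity/specificity are S(2 mu / sigma^2) per condition;")
print("empirical accuracy tracks them to binomial noise over 200 items.")
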