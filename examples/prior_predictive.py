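"""Prior-predictive comparison of the default and informative latent-trait priors.

Draws from both priors and reports the extremeness index — the share of
individual-level prior mass within 0.1 of 0 or 1 — for source guessing g and
source memory d, plus the implied response-rate spread for P("A" | source A).
A large index means the prior expects participants who essentially always or
never engage the process, the pathology that motivates informative priors.
"""

import numpy as np

import ordtree as ot

model = ot.build_2htsm()
n_draws = 50_000

for name, prior in [
    ("matzke_klauer (TreeBUGS default)", ot.matzke_klauer_preset(model)),
    ("informative", ot.informative_preset(model)),
]:
    draws = ot.draw_prior(prior, model, n_participants=1, n_draws=n_draws, seed=1)
    print(f"\n{name}:")
    for p in ("g", "d"):
        idx = ot.extremeness_index(draws, p)
        print(f"  extremeness index {p}: {idx.value:.3f} (MC se {idx.se:.4f})")
    rate = ot.response_probability_draws(draws, model, "source_A", "A")
    lo, hi = np.quantile(rate, [0.05, 0.95])
    print(f"  P('A'|source A) individual-level 90% prior interval: [{lo:.3f}, {hi:.3f}]")

print(
    "\nThe default priors put roughly two-thirds of individual-level mass near the\n"
    "0/1 extremes (a mixture of extreme sub-populations); the informative priors\n"
    "spread mass over the interior, matching the expectation that guessing sits\n"
    "near chance and source memory is neither absent nor perfect."
)
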