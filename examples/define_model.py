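"""Define a source-monitoring MPT model and evaluate its category probabilities.

Builds the four-parameter 2HTSM (item memory D, source memory d, item
guessing b, source guessing g), shows the EQN text form, and evaluates the
response-category probabilities at a mid-range parameter point.
"""

import ordtree as ot

model = ot.build_2htsm()
print("free parameters:", model.parameters)
print()
print("EQN representation:")
print(ot.write_eqn(model))

theta = dict(D=0.5, d=0.5, b=0.5, g=0.5)
probs = ot.category_probabilities(model, theta)
for tree in model.trees:
    labelled = {c: round(float(p), 3) for c, p in zip(tree.categories, probs[tree.name])}
    print(f"{tree.name:10s} -> {labelled}")
print()
print(
    "Each row is the predicted response distribution for one item type; e.g. with\n"
    "all processes at .5, an item from source A is called 'A' with probability .5\n"
    "(.25 via remembered source + .125 via source guessing after detection +\n"
    ".125 via guessing old then guessing A)."
)

bell = ot.build_2htsm_bell(("pleasant", "disgusting"))
print(f"\nBell-style two-condition variant: {len(bell.parameters)} free parameters,")
print("derived distractor detection:", {k: str(v) for k, v in bell.derived.items()})
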