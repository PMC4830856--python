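"""Simulate ordinal questionnaire data and estimate its partial-correlation network.

Builds a chain-structured latent network, draws 500 respondents of 8 ordinal
items from it, estimates the polychoric correlation matrix, and selects the
sparse Gaussian Graphical Model by EBIC-tuned graphical lasso.
"""


from qolnet import polychoric_matrix, select_network
from qolnet.synthetic import SyntheticSpec, make_precision, sample_ordinal, thresholds_for

spec = SyntheticSpec(p=8, structure="chain", seed=1)
theta_true, support = make_precision(spec)
data = sample_ordinal(theta_true, thresholds_for(spec.category_counts()), 500, seed=2)

r = polychoric_matrix(data)
net = select_network(r, gamma=0.5)

print(f"polychoric matrix: p = {r.p}, n = {r.n}, method = {r.method}")
print(f"selected penalty lambda = {net.lam:.4f} (EBIC = {net.ebic:.1f})")
print(f"edges selected: {net.edge_count} (true chain has {support.sum() // 2})")
print("edge list (partial correlations, controlling for all other items):")
for a, b, w in net.edge_list():
    print(f"  {a} -- {b}: {w:+.3f}")
# Each weight is the conditional association of two items given the rest;
# at n = 500 the chain's neighbouring links dominate the selected network.
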