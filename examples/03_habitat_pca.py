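"""The vegetation-cover habitat axis.

Builds a per-taxon habitat table (three collinear environmental
variables driven by one latent vegetation factor, plus latitude,
rainfall and temperature), extracts the first principal component on the
covariance matrix, and reports how much variance it explains and how it
correlates with climate: denser vegetation should track latitude and
rainfall but not temperature.
"""

from plumavis import correlate, pca_covariance
from plumavis.synthetic import gen_habitat

taxa = [f"sp{i:02d}" for i in range(1, 25)]
habitat = gen_habitat(taxa, seed=7)
print(habitat.head(3).round(2).to_string())

pc = pca_covariance(habitat)  # centered, covariance (not correlation) PCA
print(f"\nPC1 explains {pc.pc1_explained:.1%} of environmental variance")
print("loadings:\n", pc.loadings["PC1"].round(3).to_string())

for var in ("latitude", "rainfall", "temperature"):
    res = correlate(pc.scores.to_numpy(), habitat[var].to_numpy())
    print(f"PC1 vs {var:12s}: r2 = {res['r2']:.2f}, p = {res['p']:.3g} (n = {res['n']})")
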