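"""Measure emergent root morphology and summarise it with a PCA.

Two contrasting root habits — a wide shallow forager and a steep deep
avoider — are each grown alone a few times; the seven whole-root-system
measures are computed per plant and decomposed with a PCA on the
standardised table.  (The length-per-biomass column is constant under the
fixed-radius segment cost model, so the PCA drops it.)
"""

import warnings

import rhizosim as rz

habits = {
    "wide-forager": rz.Genotype(rotang=0.9, branchang=1.45, gravitrop=0.05,
                                basezonelength=30, basezonep=0.1, maxorder=8,
                                orderweightings=1.3, kshoot1=-1.8, kshoot2=0.006),
    "deep-avoider": rz.Genotype(rotang=0.9, branchang=0.6, gravitrop=0.25,
                                basezonelength=30, basezonep=0.08, maxorder=4,
                                orderweightings=0.9, kshoot1=-1.8, kshoot2=0.006),
}

records, labels = [], []
for label, genotype in habits.items():
    for rep in range(4):
        result = rz.run_simulation(rz.Scenario(n_neighbours=0, duration=150),
                                   [genotype], seed=100 + rep)
        records.append(rz.morphology(result.plants[0]))
        labels.append(label)

table = rz.records_frame(records, habit=labels)
print(table.groupby("habit")[["root_depth", "max_horizontal_length",
                              "root_biomass", "fractal_dimension"]].mean().round(3))

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # the constant column is expected
    pca = rz.morphology_pca(table)
print("\nPC1 explains {:.0%} of variance; loadings:".format(pca.explained_variance_ratio[0]))
print(pca.loadings.iloc[0].round(3).to_string())
print("(reach and biomass load together, against depth: the forager/avoider axis)")
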