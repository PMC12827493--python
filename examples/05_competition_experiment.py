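"""A miniature factorial competition experiment.

Two synthetic "species" pools — a high-growth-potential wide forager and a
competition-avoiding deep one — are crossed as target and neighbour with 0
and 4 neighbours.  The summary table and the effect/response indices show
the trade-off: the forager grows far larger alone and suppresses harder,
while the avoider keeps most of its solo growth under crowding.
"""

import rhizosim as rz

forager = rz.Genotype(rotang=0.9, branchang=1.45, gravitrop=0.05, basezonelength=30,
                      basezonep=0.1, maxorder=8, orderweightings=1.3,
                      kshoot1=-1.8, kshoot2=0.006)
avoider = rz.Genotype(rotang=0.9, branchang=0.6, gravitrop=0.25, basezonelength=30,
                      basezonep=0.08, maxorder=4, orderweightings=0.9,
                      kshoot1=-1.8, kshoot2=0.006)

pools = {"forager": [forager], "avoider": [avoider]}
design = rz.build_design(["avoider", "forager"], replicates=3, base_seed=1,
                         neighbour_counts=(4,))
records = rz.run_experiments(design, pools, duration=150)
summary = rz.summarize(records)
print(summary.round(4).to_string(index=False))

indices = rz.competition_indices(summary)
print("\nper-species indices (response = fraction of solo growth kept under")
print("4 neighbours; effect = mean relative suppression exerted):")
print(indices.round(3).to_string(index=False))
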