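"""Competition for soil water among clonal neighbours.

A vigorous wide-foraging genotype is grown alone and surrounded by four
clones 50 mm away.  Neighbouring root systems deplete shared voxels, and
the per-voxel proportional rationing splits what is left — so the target
ends much smaller in the crowd.  The printed ratio is its competitive
response to conspecifics.
"""

import numpy as np

import rhizosim as rz

genotype = rz.Genotype(rotang=0.9, branchang=1.45, gravitrop=0.05, basezonelength=30,
                       basezonep=0.1, maxorder=8, orderweightings=1.3,
                       kshoot1=-1.8, kshoot2=0.006)

solo = rz.run_simulation(rz.Scenario(n_neighbours=0, duration=150), [genotype], seed=7)
crowd = rz.run_simulation(rz.Scenario(n_neighbours=4, duration=150), [genotype] * 5, seed=7)

print(f"alone:            target shoot {solo.target_final_shoot:8.4f} g")
print(f"four neighbours:  target shoot {crowd.target_final_shoot:8.4f} g")
ratio = crowd.target_final_shoot / solo.target_final_shoot
print(f"fraction of solo growth retained under competition: {ratio:.3f}")
print("(neighbour shoot biomasses:",
      np.round(crowd.shoot[1:, -1], 4).tolist(), ")")
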