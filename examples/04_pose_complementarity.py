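"""Score ligand poses by hydrophobic and electrostatic complementarity.

An elongated cavity can hold a ligand in two head-to-tail orientations.
Surface complementarity discriminates them: the planted pose and its
180-degree "reverted" flip are scored against the same environment.
"""

import ligandpath as lp
from ligandpath import synthetic as syn
from ligandpath.complementarity import flip_pose

lig, env = syn.make_complementarity_case("perfect_electrostatic")
print(f"electrostatic complementarity, matched charge cage : "
      f"{lp.electrostatic_complementarity(lig, env):+.3f}")
lig_a, env_a = syn.make_complementarity_case("anti_electrostatic")
print(f"electrostatic complementarity, conjugated cage     : "
      f"{lp.electrostatic_complementarity(lig_a, env_a):+.3f}")

lm, em = syn.make_complementarity_case("hydrophobic_match")
table = lp.rank_poses([("md-pose", lm),
                       ("reverted", flip_pose(lm, (0, 0, 1)))], em)
print("\npose ranking against the matched environment:")
print(table.to_string(index=False))
print("+1 means hydrophobic patches face hydrophobic surroundings and the "
      "environment's potential mirrors the ligand's with opposite sign; the "
      "flipped pose loses on both metrics, identifying the bound "
      "orientation.")
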