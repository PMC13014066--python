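"""Per-complex pharmacophore perception and consensus merging.

First perceives a model from a planted complex (showing the geometry
-> feature pipeline), then merges the three reference per-complex
inventories (NDGA, zileuton, BW B70C) into the consensus model:
features present in all three complexes become required, those in two
become optional, the rest are dropped, and excluded volumes survive
only where all three models overlap.
"""

import loxpharm as lp
from loxpharm.datasets import reference_feature_sets
from loxpharm.synth import make_planted_complex

complex_model, _truth = make_planted_complex(
    [{"ftype": "METAL", "distance": 2.2},
     {"ftype": "HBD", "distance": 2.9, "angle": 160.0},
     {"ftype": "HYD", "distance": 4.0}])
perceived = lp.perceive(complex_model, ligand=("L", 900, ""), metal="FE")
print("perceived from planted complex:",
      [(f.label, f.ftype) for f in perceived.features])

models = list(reference_feature_sets().values())
for m in models:
    print(f"{m.complex_id:9s}: {len(m.features):2d} features, "
          f"{len(m.volumes)} excluded volumes")

corr = lp.correspond(models, match_radius=2.0)
rules = lp.ConsensusRules(n_models=3, required_if_present_in=3,
                          optional_if_present_in=2)
consensus = lp.build_consensus(corr, rules)
consensus.volumes = lp.merge_excluded_volumes(models)

print(f"consensus: {len(consensus.features)} features, "
      f"{sum(f.optional for f in consensus.features)} optional, "
      f"{len(consensus.volumes)} excluded volumes")
for f in consensus.features:
    flag = "optional" if f.optional else "required"
    print(f"  {f.label:4s} {f.ftype:5s} {flag:8s} tolerance {f.tolerance:.2f} A")
print("acceptor features appear in one complex only and are dropped;")
print("the NI warhead and second hydrophobic appear in two -> optional")
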