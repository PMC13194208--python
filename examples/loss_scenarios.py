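"""How the *same* amount of habitat loss can fragment or de-fragment.

Applies each loss scenario to one synthetic landscape, removing 10% of
its habitat, and prints the change in the four metrics.  Patch removal
drops whole patches (fewer patches, less edge: de-fragmentation);
dissection and perforation cut and puncture (more patches or edge:
fragmentation).
"""

from forestfrag import (
    LossScenario,
    apply_loss,
    compute_metrics,
    gen_fractal_landscape,
)
from forestfrag.synthetic import SCENARIO_KINDS

t0 = gen_fractal_landscape(n=64, cell_size=30.0, p=0.5, roughness=2.0, seed=3)
m0 = compute_metrics(t0)
print(f"before loss: p={m0.p_habitat:.3f}  patches={m0.n_patches}  "
      f"ED={m0.edge_density:.1f} m/ha  MPS={m0.mean_patch_size:.2f} ha\n")

print(f"{'scenario':<14}{'removed':>8}{'d_patches':>10}{'d_ED':>9}{'d_MPS':>9}")
for kind in SCENARIO_KINDS:
    t1, realized = apply_loss(t0, LossScenario(kind, target_fraction=0.10, seed=3))
    m1 = compute_metrics(t1)
    print(f"{kind:<14}{realized:8.3f}{m1.n_patches - m0.n_patches:10d}"
          f"{m1.edge_density - m0.edge_density:9.1f}"
          f"{m1.mean_patch_size - m0.mean_patch_size:9.2f}")

print("\nPositive d_patches / d_ED and negative d_MPS mean the landscape "
      "became MORE fragmented; the opposite signs mean LESS fragmented.")
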