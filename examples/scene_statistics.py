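"""Contrast statistics of a sparse vs a cluttered scene.

Generates two dead-leaves textures — one with a single object, one with
200 fragments — and prints their contrast energy (CE), spatial
coherence (SC) and fitted Weibull parameters.  CE tracks the overall
amount of edge contrast (the Weibull scale beta); SC tracks how evenly
contrast is spread across the scene (the Weibull shape gamma).  Both
rise with clutter.
"""

from scenecomplex.scenestats import SceneStatsConfig, scene_statistics
from scenecomplex.synthetic import gen_texture

cfg = SceneStatsConfig(fit_weibull=True)
for name, k in (("sparse (1 object)", 1), ("cluttered (200 fragments)", 200)):
    st = scene_statistics(gen_texture(k, seed=7), cfg, image_id=name)
    wb = st.weibull
    print(
        f"{name:26s}  CE = {st.ce:.4f}  SC = {st.sc:.3f}  "
        f"beta = {wb.beta:.4f}  gamma = {wb.gamma:.3f}  "
        f"(n = {wb.n}, zeros discarded = {wb.n_zeros_discarded})"
    )
print(
    "\nHigher CE/SC for the cluttered scene: many fragments mean more "
    "edges (CE up) spread homogeneously across the image (SC up)."
)
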