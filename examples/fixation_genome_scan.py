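"""Scan the genome for hot and cold spots of ohnolog fixation.

Simulates a four-genome pillar table whose fixation rate gamma is elevated
in a contiguous 10% block of pillars, fits the full loss model, and computes
the per-pillar probability of at least one fixation event
(1 - p_nonfix, with p_nonfix = prod_i (1 - p_fix^i)) averaged over a
sliding window of 2% of the pillars — the fixation genome scan.
"""

from pathlib import Path
import tempfile

import numpy as np

from rediploid import (
    LossModelSpec,
    ModelFlavor,
    fit_model,
    fixation_scan,
    read_newick,
    read_pillar_table,
    scenario,
)

with tempfile.TemporaryDirectory() as tmp:
    bundle = scenario("fixation_hotspot", Path(tmp) / "hot", seed=3, n_pillars=1200)
    table = read_pillar_table(bundle / "pillars.tsv")
    tree = read_newick(bundle / "tree.nwk")
    manifest = dict(
        line.split("=", 1) for line in (bundle / "manifest.txt").read_text().splitlines()
    )

spec = LossModelSpec(ModelFlavor.WGD_bf)
fit = fit_model(table, tree, spec, seed=0, n_restarts=2)
scan = fixation_scan(fit.tree, spec, fit.params, table, window_frac=0.02)

start, length = int(manifest["hot_start"]), int(manifest["hot_len"])
inside = scan.window_means[start : start + length].mean()
outside = np.concatenate(
    [scan.window_means[: max(0, start - 30)], scan.window_means[start + length + 30 :]]
).mean()

print(f"fitted gamma (genome-wide): {fit.params.gamma:.3f}")
print(f"windowed P(at least one fixation): "
      f"{inside:.3f} inside the planted hot spot, {outside:.3f} elsewhere")
print(f"scaled positions span [{scan.positions[0]:.2f}, {scan.positions[-1]:.2f}]")
print(
    "\nThe elevated window mean inside the block is the 'hot spot' signature: "
    "fixation probability is spatially structured along the ancestral gene order."
)
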