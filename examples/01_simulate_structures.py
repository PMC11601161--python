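"""Generate synthetic protein backbones and inspect their geometry.

Builds a mixed helix/coil/strand chain plus a noisy homolog and prints the
Cα-Cα bond statistics and the RMSD between the pair over the ground-truth
residue correspondence.
"""

import numpy as np

import factalign as fa

params = fa.SimParams(seed=42)
chain = fa.synth_chain(params, id="demo")
steps = np.linalg.norm(np.diff(chain.coords, axis=0), axis=1)
print(f"chain '{chain.id}': {len(chain)} residues")
print(f"consecutive Ca-Ca distance: {steps.mean():.2f} +- {steps.std():.2f} A"
      f" (virtual bond ~3.8 A)")

homolog, true_cols = fa.derive_homolog(chain, fa.SimParams(seed=43))
qi = [a for a, _ in true_cols]
ti = [b for _, b in true_cols]
rmsd = np.sqrt(np.mean(np.sum(
    (chain.coords[qi] - homolog.coords[ti]) ** 2, axis=1)))
print(f"homolog: {len(homolog)} residues, "
      f"{len(true_cols)} true aligned pairs, "
      f"RMSD over truth {rmsd:.2f} A")
print("the RMSD reflects the 1.0 A coordinate jitter used to emulate "
      "structural divergence between homologs")
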