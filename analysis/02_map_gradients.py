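"""Map connectivity gradients of the phantom and score axis recovery.

Simulates one scan (T=400, AR(1) noise sd 0.5), cleans it (within-mask
smoothing at 4 mm FWHM, Marchenko-Pastur denoising, z-scoring), builds
eta-squared fingerprint similarity, sparsifies at the minimal connected
epsilon and extracts three Laplacian-eigenmap gradients.  Reports the
Spearman correlation of each gradient with the planted axes.
Outputs under results/gradients/.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

import wmgrad as w
from wmgrad import preprocess as pp
from wmgrad.regions import save_volume

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "gradients"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    scene = w.make_scene(n_wm_voxels=1500, n_parcels=40, seed=SEED)
    gm, wm = w.simulate_bold(scene, t_frames=400, noise_sd=0.5, ar1=0.3,
                             seed=SEED + 1)
    gm = pp.preprocess_run(gm, fwhm=0.0, wishart=True)
    wm = pp.preprocess_run(wm, fwhm=4.0, wishart=True)

    fp = w.fingerprints(wm, w.gm_pca_basis(gm))
    graph = w.sparsify_connected(w.similarity_matrix(fp))
    gset = w.laplacian_eigenmaps(graph, k=3, region=scene.wm_region)
    gset = w.align_gradient_signs(gset, scene.axis_positions[:, :3])

    rows = []
    for j in range(3):
        rho = [stats.spearmanr(gset.gradients[:, j],
                               scene.axis_positions[:, a]).statistic
               for a in range(3)]
        rows.append({"gradient": j + 1,
                     "eigenvalue": gset.eigenvalues[j],
                     "variance_explained": gset.variance_explained[j],
                     "spearman_u1": rho[0], "spearman_u2": rho[1],
                     "spearman_u3": rho[2]})
        save_volume(OUT / f"gradient_{j + 1}.nii.gz",
                    scene.wm_region.embed(gset.gradients[:, j]),
                    scene.wm_region.affine)
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "gradient_summary.tsv", sep="\t", index=False)
    np.savetxt(OUT / "gradient_values.tsv", gset.gradients, delimiter="\t",
               header="g1\tg2\tg3", comments="")

    print(f"minimal connected epsilon: {graph.epsilon:.4f}")
    print(table.round(3).to_string(index=False))
    print("principal gradient tracks the posterior-anterior axis "
          f"(|rho| = {abs(table.loc[0, 'spearman_u1']):.3f}); "
          "second gradient tracks dorsal-ventral "
          f"(|rho| = {abs(table.loc[1, 'spearman_u2']):.3f})")


if __name__ == "__main__":
    main()
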