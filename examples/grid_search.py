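"""Two-step parameter selection on a small synthetic dataset.

Step 1 fixes the state-space wavelet and model order by an exhaustive grid
on the dual-model features alone; step 2 freezes that pair and searches the
wavelet and level of the energy block over the fused features.  Every cell
is a 5-fold cross-validated accuracy.
"""

import imbef

em = imbef.generate_stage_epochs(imbef.default_profiles()[:3],
                                 n_per_stage=20, te=4.0, fs=128.0, seed=21)

step1 = imbef.search_dssm_params(em, wavelets=["db1", "db2"], orders=[5, 6],
                                 classifier="bagged_trees", k=5, seed=0)
print("step 1 (model block): accuracy grid, orders x wavelets")
print((step1.accuracy_matrix(3, index="order_dssm", columns="wavelet_dssm")
       * 100).round(2))
best1 = step1.best[3]
frozen = (best1["wavelet_dssm"], int(best1["order_dssm"]))
print(f"selected: wavelet={frozen[0]}, order={frozen[1]} "
      f"({best1['accuracy'] * 100:.2f}%)\n")

step2 = imbef.search_le_params(em, wavelets=["db1", "db4"], levels=[3, 4, 5],
                               frozen_dssm=frozen, classifier="bagged_trees",
                               k=5, seed=0)
print("step 2 (energy block): accuracy grid, levels x wavelets")
print((step2.accuracy_matrix(3, index="level_le", columns="wavelet_le")
       * 100).round(2))
best2 = step2.best[3]
print(f"selected: wavelet={best2['wavelet_le']}, "
      f"level={int(best2['level_le'])} ({best2['accuracy'] * 100:.2f}%)")
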