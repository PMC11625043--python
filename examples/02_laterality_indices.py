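"""From one subject's time series to laterality indices.

Pipeline: Pearson FC -> Fisher z -> per-vertex intra/heterotopic strength
sums -> per-pair LI = (L-R)/|L+R| -> network means. The generating plan gives
the cingulo-opercular network (CON) stronger right-hemisphere intra coupling,
so its network LI_intra should come out negative.
"""

from hemilat import compute_fc, mean_global_fc, network_li, pair_li, strength_sums
from hemilat.synthetic import build_covariance, make_atlas, simulate_timeseries, young_plan

atlas = make_atlas({n: 30 for n in ("SMN", "AUD", "LAN", "DAN", "CON", "FPN", "DMN")}, seed=2)
cov = build_covariance(atlas, young_plan())
ts = simulate_timeseries(cov, n_timepoints=750, seed=3, subject_id="demo")

fc = compute_fc(ts)
sums = strength_sums(fc, atlas)
limap = pair_li(sums, atlas)
table = network_li(limap, atlas)

print(f"mean global FC (z): {mean_global_fc(fc):.4f}")
print(f"valid pairs: intra {int(limap.valid('intra').sum())}/{atlas.n_pairs}, "
      f"he {int(limap.valid('he').sum())}/{atlas.n_pairs}")
print("\nnetwork LI (positive = left-lateralized):")
print(table.round(4).to_string(index=False))
print("\nCON li_intra < 0 reflects the planted right-hemisphere intra coupling and")
print("LAN li_intra > 0 its planted left asymmetry; li_he carries no planted")
print("asymmetry and hovers near zero. Single-subject values are noisy -- group")
print("means (examples 03/06) show the planted structure cleanly.")
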