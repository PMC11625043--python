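"""Generate a small synthetic resting-state cohort and write it to disk.

Three groups with planted lateralization differences: young non-musicians
(YNM, asymmetric couplings), older musicians (OM, asymmetries ~preserved) and
older non-musicians (ONM, asymmetries shrunk toward symmetry).
"""

from hemilat.synthetic import make_atlas, make_cohort, write_dataset

atlas = make_atlas({n: 20 for n in ("SMN", "AUD", "LAN", "DAN", "CON", "FPN", "DMN")} | {"NONE": 8}, seed=1)
data = make_cohort(
    group_sizes={"YNM": 8, "OM": 7, "ONM": 7},
    atlas=atlas,
    n_timepoints=300,
    seed=1,
)
write_dataset(data, "scratch/example_cohort")

t = data.cohort.table
print(f"atlas: {atlas.n_vertices} vertices, {atlas.n_pairs} homotopic pairs")
print(f"subjects: {len(t)}  groups: {dict(t['group'].value_counts())}")
print("\nper-group covariate means (age / education / hearing):")
print(t.groupby('group')[['age', 'education', 'hearing']].mean().round(2))
print("\nEach subject also has a vertex x time BOLD-like matrix and an FD trace")
print("under scratch/example_cohort/; covariate means track the generating")
print("group conditions, and mfd / mean_global_fc are realized values.")
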