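"""Generate a synthetic neuromast rosette and inspect its ground truth.

Builds one 16-cell organ with known hair-cell (HC) / support-cell (SC)
identities, marker expression and probability maps, then prints the
per-type placement statistics the downstream analysis relies on.
"""

from neuroshape import SynthConfig, generate_neuromast
from neuroshape.io import save_ground_truth

config = SynthConfig(
    n_cells=16, organ_radius_um=16.0, voxel_size_um=(0.4, 0.2, 0.2), seed=1
)
gt = generate_neuromast(config)

t = gt.truth_table
print(f"organ with {len(t)} cells in a "
      f"{gt.cell_labels.labels.shape} voxel volume")
print(t.groupby("type")["d_true"].agg(["count", "mean"]))
print("\nsubtypes:", t["subtype"].value_counts().to_dict())
print("concave (QC-exercising) cells:", int(t['concave'].sum()))

out = save_ground_truth(gt, "scratch/example_rosette")
print(f"\nvolumes, truth table and provenance written to {out}/")
# The mean normalized distance d of HC-like cells is well below that of
# SC-like cells: hair cells sit at the organ centre, support cells ring it.
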