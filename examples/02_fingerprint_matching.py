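"""Blind test of the quantitative threshold-table method on synthetic maps.

Simulates three raster maps per tissue class (three synthetic patients with
slightly different recorded wavenumber ranges), builds per-patient reference
tables from 80% of each map's spectra, classifies the held-out 20% averages,
and prints the confusion matrix.  Rows are the actual tissue, columns the
prediction.
"""

import ramantissue as rt

cfg = rt.SimulationConfig(n_rows=12, n_cols=12, seed=5)
maps, manifest = rt.simulate_dataset(n_maps_per_class=3, cfg=cfg)
print(f"simulated {len(maps)} maps "
      f"({maps[0].n_rows}x{maps[0].n_cols} spots each):")
print(manifest.to_string(index=False))

cm = rt.qm_blind_test(maps, train_fraction=0.8, seed=7)
print("\nblind-test confusion matrix (rows = actual):")
print("            " + "  ".join(f"{c.value:>6}" for c in cm.classes))
for c, row in zip(cm.classes, cm.counts):
    print(f"{c.value:>10}  " + "  ".join(f"{v:6d}" for v in row))
print(f"\noverall accuracy: {cm.accuracy():.3f} "
      "(fraction of held-out area averages classified correctly)")
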