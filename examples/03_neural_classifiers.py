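"""Train the two neural classifiers on per-spot synthetic spectra.

The 1D network sees only the ordered peak intensities; the 2D network sees
(wavenumber, intensity) pairs, which makes it robust to session-to-session
differences in the recorded wavenumber range.  Prints held-out accuracy for
both after a stratified 70/30 split.
"""

import ramantissue as rt
from ramantissue import neural
from ramantissue.preprocess import preprocess_ml_batch

cfg = rt.SimulationConfig(n_rows=10, n_cols=10, seed=5)
maps, _ = rt.simulate_dataset(n_maps_per_class=1, cfg=cfg)

for arch, epochs in (("ann1d", 50), ("cnn2d", 6)):
    spec = neural.NetworkSpec(arch)
    feats, labels = [], []
    for m in maps:
        fs = preprocess_ml_batch(m.grid, m.flat_intensities(), mode=spec.kind_mode())
        feats.extend(fs)
        labels.extend([m.meta.tissue_class] * len(fs))
    cm = neural.evaluate_split(
        feats, labels, spec, train_fraction=0.7, seed=11,
        train_config=neural.TrainConfig(epochs=epochs, seed=11))
    print(f"{arch}: trained on {len(feats)} spectra ({epochs} epochs), "
          f"held-out accuracy {cm.accuracy():.3f}")
print("\nBoth architectures separate the four tissue classes on the "
      "synthetic study conditions.")
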