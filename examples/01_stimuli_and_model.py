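"""Render the six checkerboard stimuli and build the V1 model RDM.

The experiment's stimuli are polar checkerboards at three spatial
frequencies, confined to the left or right visual hemifield, counter-phasing
at 15 Hz.  The model observer is the HMAX S1 layer: Gabor filters at four
orientations and sixteen sizes, emulating V1 simple cells.  Its
representational dissimilarity matrix (RDM) over the six stimuli is what
the EEG RDMs are later compared against.
"""

import numpy as np

import snyq

# --- the stimulus set ------------------------------------------------------
specs = snyq.stimulus_set()
for spec in specs:
    print(f"condition {spec.condition}: {spec.hemifield:>5s} hemifield, "
          f"{spec.sf_name:>6s} SF (radial {spec.radial_sf} c/deg, "
          f"angular {spec.angular_sf} c/deg)")

# render one stimulus at the default analysis resolution and inspect it
ppd = 128.0 / 56.0  # pixels per degree: 128 px across the 56 deg canvas
img = snyq.render_checkerboard(specs[2], ppd)         # left hemifield, high SF
rev = snyq.render_checkerboard(specs[2], ppd, phase=1)  # its reversal phase
print(f"\nrendered {img.shape} px; values "
      f"{sorted(float(v) for v in np.unique(img.pixels))}")
print(f"reversal exchanges black and white: "
      f"{np.array_equal((img.pixels == 1.0), (rev.pixels == 0.0))}")

# --- S1 responses and the model RDM ---------------------------------------
model = snyq.build_model_rdm(ppd)
print("\nmodel RDM (Euclidean distances between S1 feature vectors):")
for i, row_label in enumerate(model.labels):
    row = " ".join(f"{model.matrix[i, j]:7.1f}" for j in range(6))
    print(f"  {row_label:>8s} {row}")

# the orderings the analyses rely on: dissimilarity grows with
# spatial-frequency separation, and high-SF stimuli are the most
# discriminable across hemifields
print(f"\nd(LVF-med, LVF-high) = {model.entry('LVF-med', 'LVF-high'):.1f} > "
      f"d(LVF-low, LVF-med) = {model.entry('LVF-low', 'LVF-med'):.1f}")
print(f"d(LVF-high, RVF-high) = {model.entry('LVF-high', 'RVF-high'):.1f} > "
      f"d(LVF-low, RVF-low) = {model.entry('LVF-low', 'RVF-low'):.1f}")

# --- a 2-D view of the model geometry --------------------------------------
coords = snyq.mds_embed(model, dims=2)
print("\nclassical MDS embedding (2-D):")
for label, (x, y) in zip(model.labels, coords):
    print(f"  {label:>8s}: ({x:7.1f}, {y:7.1f})")
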