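"""Round-trip a recording through EDF+ and the native session container.

`write_edf` stores a session as a standard EDF+ file with the trial
triggers on a Status channel; `import_bdf` reads it back (via MNE) and
re-epochs around the triggers, optionally translating acquisition event
codes to condition labels with an event map.  `save_session`/`load_session`
provide a faster text+npz native container with a JSON sidecar.
"""

import tempfile
from pathlib import Path

import numpy as np

import snyq

# simulate a short session to have something to export
cfg = snyq.SimulationConfig(seed=5, n_trials_per_condition=2, n_blocks=2)
layout = snyq.make_layout(seed=cfg.seed)
session = snyq.simulate_session(cfg, layout, subject_id=0)
print(f"session: {session.data.shape} at {session.fs_hz:g} Hz")

work = Path(tempfile.mkdtemp())

# --- EDF+ round trip -------------------------------------------------------
edf_path = work / "subject00.edf"
snyq.write_edf(session, edf_path)
print(f"wrote {edf_path.name}: {edf_path.stat().st_size / 1e6:.1f} MB")

back = snyq.import_bdf(edf_path, layout, pre_s=0.5, post_s=1.5)
err = np.max(np.abs(back.data - session.data))
print(f"EDF round trip: labels match = "
      f"{np.array_equal(back.labels, session.labels)}, "
      f"max amplitude error {err:.2e} uV (16-bit quantization)")

# acquisition systems often use offset trigger codes; remap on import
session.labels = session.labels + 100
snyq.write_edf(session, work / "coded.edf")
remapped = snyq.import_bdf(work / "coded.edf", layout,
                           event_map={100 + c: c for c in range(1, 7)})
print(f"event remap 101..106 -> 1..6: "
      f"{sorted(int(v) for v in np.unique(remapped.labels))}")
session.labels = session.labels - 100

# --- native container ------------------------------------------------------
sidecar = snyq.save_session(session, work, subject_id=0, config_hash="demo")
back2 = snyq.load_session(sidecar)
print(f"native container ({sidecar.name}): exact = "
      f"{np.array_equal(back2.data, session.data)}")
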