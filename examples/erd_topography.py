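"""Map ERD/ERS over the 27-channel sensorimotor montage.

Generates a three-class multichannel session (feet, left hand, right hand;
somatotopic modulation at post-training depth), applies the nearest-neighbour
Laplacian, and quantifies the mu-band ERD at each MI's representation area,
plus the full topography table for the feet condition.
"""

import numpy as np

import mibci as m

montage = m.default_montage()
protocol = m.SessionProtocol(n_trials=30, classes=m.io.MI_CLASSES, seed=2)
rec, trials = m.generate_session(protocol, m.SubjectModel.trained(), montage, seed=2)
lap = m.laplacian(rec, montage)
print(f"{rec.n_channels}-channel session, {len(trials)} trials; "
      f"Laplacian over 27 electrodes ({len(lap.partial_channels)} edge "
      f"channels with <4 neighbours)")

plateau = lambda c: c.erd_percent[(c.times >= 5.5) & (c.times < 10.0)].mean()
for condition, channel, band, name in [
        ("feet", "Cz", (8, 13), "mu"), ("feet", "Cz", (25, 35), "beta"),
        ("left_hand", "C4", (8, 13), "mu"), ("right_hand", "C3", (8, 13), "mu")]:
    tf = m.time_freq(lap, trials, condition, channel)
    curve = m.band_curve(m.erd_ers(tf), band)
    print(f"  {condition:<10} {name}-band at {channel}: {plateau(curve):+6.1f} %")
print("negative = ERD (power loss during MI), positive = ERS; feet MI "
      "suppresses mu but enhances beta at the vertex.")

# topography: feet-condition mu ERD across all 27 electrodes
curves = {}
for ch in (l for l in montage.labels if not l.endswith("'")):
    tf = m.time_freq(lap, trials, "feet", ch)
    curves[ch] = m.band_curve(m.erd_ers(tf), (8, 13))
table = m.topography_export(curves, montage)
extreme = table.loc[table["value"].idxmin()]
print(f"strongest feet-MI mu ERD at {extreme['channel']} "
      f"({extreme['value']:.1f} %) out of {len(table)} electrodes")
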