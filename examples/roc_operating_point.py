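"""Sample-wise ROC analysis of the feet detector.

Every output sample is labelled event (inside an MI window) or non-event
(rest); sweeping the detection threshold over all observed bar values yields
TPR = N_TP/(N_TP+N_FN) and FPR = N_FP/(N_TN+N_FP) per threshold, the AUC, and
the balanced operating point closest to TPR = 1 - FPR.
"""

import numpy as np

import mibci as m

montage = m.montage_subset(m.default_montage(),
                           ("Cz", "C4", "C3", "Cz'", "C4'", "C3'"))
protocol = m.SessionProtocol(n_trials=30, classes=("feet", "left_hand"), seed=3)
rec, trials = m.generate_session(protocol, m.SubjectModel.trained(), montage, seed=3)
streams = m.feature_stream(rec, montage=montage)

times = np.arange(rec.n_samples) / rec.sample_rate
feet_trials = trials.select("feet")
mask = m.mi_window_mask(times, feet_trials)
roc = m.sample_roc(streams["beta_Cz"].values, mask)
op = m.best_threshold(roc)

print(f"{mask.sum()} event samples, {(~mask).sum()} non-event samples, "
      f"{len(roc.thresholds)} candidate thresholds")
print(f"AUC: {roc.auc:.3f}  (0.5 = chance, 1.0 = complete separation)")
print(f"balanced operating point: threshold {op.threshold:.3f} log uV^2, "
      f"TPR {op.tpr:.3f}, FPR {op.fpr:.3f}")
print("the beta-ERS of feet MI raises the Cz bar during events, so the "
      "balanced point detects feet imagery above chance.")
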