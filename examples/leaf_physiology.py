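"""Leaf physiology indices: relative water content and water-loss curves."""

from memtype import rwc, water_loss_curve

# RWC% = (fresh - dry) / (turgid - dry) * 100
value, in_range = rwc(fresh_weight=2.0, dry_weight=0.5, turgid_weight=2.5)
print(f"RWC of a leaf at 2.0 g fresh / 0.5 g dry / 2.5 g turgid: {value:.1f}%"
      f" (weights consistent: {in_range})")

# detached-leaf weights measured every 30 minutes
times = [0, 30, 60, 90, 120]
weights = [1.20, 1.08, 0.99, 0.92, 0.87]
curve = water_loss_curve(times, weights)
print("\nwater loss as a fraction of initial fresh weight:")
for row in curve.itertuples():
    print(f"  t = {row.time:5.0f} min: loss = {row.loss_fraction:.3f}")
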