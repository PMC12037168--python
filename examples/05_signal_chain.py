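"""The real-time joystick signal chain, step by step.

Raw 10-bit ADC codes (0-1023 over 0-5 V, resting near mid-scale) are
calibrated to millimeters, smoothed with the controller's 20 ms trailing
average, re-baselined against drift, and checked for the >3 mm
anteroposterior threshold crossing that registers a choice.
"""

import numpy as np

from pushpull import signal_io

cal = signal_io.Calibration(box_id="box1", slope_x=0.05, slope_y=0.05)
print(f"code 0 -> {signal_io.code_to_volts(0, cal):.1f} V, "
      f"code 1023 -> {signal_io.code_to_volts(1023, cal):.1f} V")
dv = (signal_io.code_to_volts(514, cal) - signal_io.code_to_volts(512, cal)) * 1000
print(f"a 2-count wiggle is {dv:.1f} mV")

# a synthetic raw stream: drifting baseline plus a push past threshold
rng = np.random.default_rng(3)
t = np.arange(1500)
codes_x = 512 + 6 + (t // 400)  # slow drift in counts
codes_x = codes_x + np.where((t > 900) & (t < 1100), ((t - 900) * 0.9).astype(int), 0)
codes_x = np.clip(codes_x + rng.integers(-1, 2, len(t)), 0, 1023)
codes_y = np.clip(512 + rng.integers(-1, 2, len(t)), 0, 1023)
samples = [
    signal_io.AdcSample(int(tt), int(xc), int(yc))
    for tt, xc, yc in zip(t, codes_x, codes_y)
]

trace = signal_io.adc_to_mm(samples, cal)
smoothed = signal_io.moving_average(trace, 20.0)
rebased = signal_io.rebaseline(smoothed, 50.0)
choice = signal_io.detect_choice(rebased, 3.0)

print(f"baseline removed: {rebased.baseline_x:+.2f} mm on x")
print(f"choice: {choice.direction} at t = {choice.t_cross:.0f} ms "
      f"(peak {rebased.x.max():.2f} mm)")
# The crossing time is the first sample strictly beyond 3 mm of the
# re-read baseline — the same rule the behavior box applies in real time.
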