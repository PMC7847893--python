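"""Parse stimulus command strings and build an acoustic battery.

Command strings drive the rig: letter-prefixed fields give transducer
amplitude (a), tone frequency (f), duration (d), delays (D) and LED
level (b).
"""

import numpy as np

from zfplate import parse_event_string
from zfplate.synth import acoustic_battery

cmd = parse_event_string("2a0.3f1000d20D100D280b250")
print(f"command id {cmd.command_id}: amplitude {cmd.amplitude_a}, "
      f"{cmd.frequency_f:.0f} Hz, {cmd.duration_d:.0f} ms, "
      f"delays {cmd.delays_D} ms, light {cmd.light_b}")
# The two delays mark a prepulse-inhibition pair: weak prepulse at
# 100 ms, strong stimulus at 280 ms, under baseline light b250.

battery = acoustic_battery(n_repeats=2, interval_s=120.0,
                           rng=np.random.default_rng(0))
amps = sorted({e.amplitude_a for e in battery})
print(f"\nbattery: {len(battery)} stimuli at {len(amps)} intensities, "
      f"2-min spacing, randomized order")
print("amplitudes:", amps)
# Twelve log-spaced amplitudes from a0.0005 to a1 - the standard
# dose-response ladder for the arousal-threshold assay.
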