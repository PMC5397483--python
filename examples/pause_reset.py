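"""Pause-induced reset toward integration.

Compares a 10-triplet control against 7 context triplets + a 300 or 600 ms
pause + 3 test triplets, with identical frozen noise, and prints the
difference in proportion segregated at the final triplet.  The pause lets
the fast A1 adaptation recover, so post-pause inputs again favor the
integration unit: the difference scores are negative (a partial reset) at
every DF.
"""

import streamseg as ss
from streamseg.battery import buildup_for_timeline

a1 = ss.A1Params()
net = ss.NetworkParams()
bank = ss.NoiseBank(n_trials=500, master_seed=0)

print("delta = p(test) - p(control) at the final triplet; negative = reset\n")
for df in (4.0, 7.0, 10.0):
    control = ss.make_triplet_sequence(10, df)
    buf_control, _ = buildup_for_timeline(control, a1, net, bank)
    for pause_ms in (300, 600):
        tl = ss.apply_pause(control, pause_ms, after_triplet=7)
        buf, _ = buildup_for_timeline(tl, a1, net, bank)
        delta = ss.difference_score(buf, buf_control)
        print(f"DF={df:>4g}  pause {pause_ms} ms: delta = {delta:+.3f}")
    print()
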