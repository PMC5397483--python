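"""Build-up of stream segregation: static vs adapting A1 inputs.

Simulates 500-trial frozen-noise ensembles of 10-triplet ABA_ sequences at
DF = 4, 7, 10 semitones and prints the time-binned proportion of trials
hearing two streams.  With static (pre-adapted) inputs the proportion is
flat from the first triplet; with adapting inputs the first bin is biased
toward the integrated percept and the proportion builds up over seconds to
the static level, faster and higher for larger DF.
"""

from dataclasses import replace

import streamseg as ss

a1 = ss.A1Params()
net = ss.NetworkParams()
bank = ss.NoiseBank(n_trials=500, master_seed=0)

for df in (4.0, 7.0, 10.0):
    tl = ss.make_triplet_sequence(10, df)
    for label, params in (("adapting", a1), ("static  ", replace(a1, adapting=False))):
        trace = ss.compute_input_trace(tl, params, net.dt)
        ens = ss.run_ensemble(trace, net, bank)
        buf = ss.build_up(ens)
        curve = " ".join(f"{p:.2f}" for p in buf.proportion_segregated)
        print(f"DF={df:>4g} {label}: {curve}")
    print()

print("Each number is the proportion segregated in one 400 ms triplet bin")
print("(n = 500 trials; binomial s.e.m. ~ 0.02). Adapting rows start near 0")
print("and climb to the static rows' level; final values order DF 4 < 7 < 10.")
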