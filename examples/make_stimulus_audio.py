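"""Build a psychoacoustic trial table and render one stimulus as audio.

Enumerates the pause experiment's factorial design (3 DF x 5 length/pause
cells x 20 repetitions = 300 trials) with per-trial roved base frequencies,
writes it as CSV, then synthesizes one 6-triplet ABA_ sequence (100 ms pure
tones, 10 ms linear ramps) as a WAV file you can listen to.
"""

from pathlib import Path

import streamseg as ss

out = Path("example_output")
out.mkdir(exist_ok=True)

table = ss.pause_experiment_design(repetitions=20)
table.to_csv(out / "pause_design.csv", master_seed=0)
print(f"wrote {out / 'pause_design.csv'} with {len(table)} trials")

base = ss.rove_base_frequency(0)
tl = ss.make_triplet_sequence(6, df_st=7.0, base_freq_hz=base)
wav = ss.synthesize_waveform(tl, sample_rate=44100)
ss.write_wav(out / "aba_df7.wav", wav, 44100, fmt="pcm16")
print(f"wrote {out / 'aba_df7.wav'}: 6 ABA_ triplets, A = {base:.1f} Hz, "
      f"B = {tl.freq_b:.1f} Hz (DF = 7 st), 2.4 s")
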