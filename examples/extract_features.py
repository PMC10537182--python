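"""Build a segment x feature matrix from one subband of one transform.

Every channel of every segment contributes 27 statistical and nonlinear
features per subband; with 14 channels that is the reference 378-column
layout.  Here a smaller 4-channel set keeps the printout readable.
"""

from eegstates import MDWTParams, SimConfig, extract_subband_features, generate_dataset

cfg = SimConfig(minutes_per_state=1.5, channels=4, master_seed=1)
segs = generate_dataset(cfg)

fm = extract_subband_features(segs, "mdwt", MDWTParams(), subband_index=1)
print(f"feature matrix: {fm.n_segments} segments x {fm.n_columns} columns "
      f"({segs.n_channels} channels x 27 features)")
print("labels:", ", ".join(sorted(set(fm.labels))))

print("\nchannel-0 columns for the first segment:")
ch0 = fm.column_meta["channel"] == 0
for name, value in zip(fm.column_meta.loc[ch0, "feature"], fm.values[0, ch0.to_numpy()]):
    print(f"  {name:<20} {value:12.4f}")

print("\nEnergy-type features (average_energy, abs_energy) differ strongly "
      "between states in the gamma/beta subband, which is what makes SB-1 "
      "informative for the classifier.")
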