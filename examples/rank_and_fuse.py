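"""Rank feature types with mRMR and fuse the top-k across transforms.

Ranks the 27 feature types of each transform's informative subband by
minimum-redundancy / maximum-relevance mutual information, then
concatenates the top-4 types (all channels) across the three transforms.
"""

from eegstates import (
    FIXED_BEST_SUBBANDS,
    DEFAULT_TRANSFORMS,
    SimConfig,
    extract_subband_features,
    fuse,
    generate_dataset,
    rank_features,
)

cfg = SimConfig(minutes_per_state=5.0, channels=4, master_seed=2)
segs = generate_dataset(cfg)

pairs = []
for tr, params in DEFAULT_TRANSFORMS.items():
    sb = FIXED_BEST_SUBBANDS[tr]
    fm = extract_subband_features(segs, tr, params, sb)
    ranking = rank_features(fm)
    pairs.append((fm, ranking))
    top = ", ".join(
        f"{name} ({ranking.scores[name]:.3f} bits)" for name in ranking.order[:4]
    )
    print(f"{tr} SB-{sb}: {top}")

fused = fuse(pairs, k=4)
print(f"\nfused matrix: {fused.n_segments} segments x {fused.n_columns} columns "
      f"(3 transforms x 4 feature types x {segs.n_channels} channels)")
print("The first-ranked score is the relevance I(feature; state) in bits; "
      "later scores subtract the mean redundancy with already-chosen features.")
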