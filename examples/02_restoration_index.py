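"""Compute the restoration index and its group-level time course.

Preprocesses raw voltage to baseline-z-scored high-gamma epochs, selects
electrodes that discriminate the two original words, computes RI per
electrode/frame/percept and the FDR-corrected group |dRI| statistics.
"""

import numpy as np

from phonrestore.config import PipelineConfig, SynthSection
from phonrestore.pipeline import bistable_split, simulate_dataset
from phonrestore.preprocess import (
    common_average_reference, epoch_and_zscore, extract_high_gamma,
    reject_channels)
from phonrestore.restoration import (
    aggregate_ri, restoration_index, select_electrodes)

cfg = PipelineConfig(
    seed=1,
    synth=SynthSection(n_electrodes=36, grid_shape=(6, 6),
                       n_trials_per_condition=40, n_word_pairs=1,
                       n_contrast_electrodes=12, restoration_gain=0.8),
)
rec, trials, electrodes, triplets, fm, _ = simulate_dataset(cfg)
rec = reject_channels(rec)
rec = common_average_reference(rec, electrodes)
rec = extract_high_gamma(rec)
ep = epoch_and_zscore(rec, trials, window=(-0.5, 1.1))

sel = select_electrodes(ep, trials, "wp0", zscore_threshold=1.5)
print(f"{len(sel.selected)} electrodes discriminate the originals "
      f"(max |z| difference {sel.max_abs_diff.max():.1f})")

ri = restoration_index(ep, trials, sel)
bi, maj = bistable_split(trials, "wp0")
group = aggregate_ri([ri], [bi], [maj])
onset = group.earliest_sig_time()
print(f"bistable pair: {bi}; significant |dRI| frames: {int(group.sig.sum())}")
print(f"earliest significant frame: {onset * 1000:.0f} ms after critical-phoneme "
      f"onset (the planted restoration latency is 150 ms)")
print(f"peak baseline-referenced mean |dRI|: {np.nanmax(group.mean):.2f} "
      f"(0 = percept-independent, up to 2 = each percept at its own original)")
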