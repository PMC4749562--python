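"""Compare switch-timing synchrony of nearby vs distant cell pairs.

For every cell pair, all switch pairs are classified by direction (both up
or both down vs opposite) and by distance (within or beyond 30 um).  In a
coupled tissue, same-direction switches of nearby cells should occur at
markedly smaller time intervals; opposite-direction switches should not.
"""

import dataclasses

from switchtissue import ProfileSet, TissueConfig, simulate_tissue, switch_synchrony

cfg = dataclasses.replace(TissueConfig(), n_cells=150, field_size=(375.0, 375.0))
tracks, truth = simulate_tissue(cfg, rng=7)
cells = [
    ProfileSet(cell_id=cid, profiles=[dataclasses.replace(p, weight=1.0)])
    for cid, p in zip(tracks.cell_ids, truth.profiles)
]
res = switch_synchrony(cells, truth.positions, threshold_um=30.0, rng=8, n_resample=1)
for name, ks in res.ks_tests.items():
    print(f"{name}: median |dt| {ks['median_close']:.1f} h (<=30 um, n={ks['n_close']}) "
          f"vs {ks['median_far']:.1f} h (>30 um); KS p = {ks['pvalue']:.2e}")
# Expected: a clearly significant left-shift (p << 0.01) for same-direction
# pairs within 30 um, and no significant shift for opposite-direction pairs.
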