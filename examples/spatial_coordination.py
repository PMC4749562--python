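"""Detect the spatial range of transcriptional coordination.

Simulates a coupled tissue (pulse propagation within 30 um) and an
uncoupled control, bins cell-pair trace correlations by distance, and
tests each bin against a trace-permutation null.  The significant range
should recover the generative 30 um radius in the coupled tissue and be
empty in the control.
"""

import dataclasses

from switchtissue import TissueConfig, make_distance_bins, permutation_null, simulate_tissue

bins = make_distance_bins(60.0)

for label, coupling in (("coupled", "default"), ("uncoupled", None)):
    cfg = TissueConfig() if coupling else dataclasses.replace(TissueConfig(), coupling=None)
    tracks, _ = simulate_tissue(cfg, rng=100)
    # n_perm must exceed 1/alpha for the p < 0.001 call to be attainable
    res = permutation_null(tracks, bins, n_perm=1999, rng=0)
    print(f"{label}: significant range endpoint = {res.significant_range_um} um")
    for row in res.table.itertuples():
        if row.n_pairs:
            print(f"  [{row.lo_um:>4.0f},{row.hi_um:>4.0f}) um  n={row.n_pairs:<4d} "
                  f"median r={row.median:+.3f}  p_perm={row.p_perm:.4f}")
# Coupled tissue: bins below ~30 um beat the permutation null (p < 0.001)
# and the endpoint sits at the coupling radius; the control shows no
# structure at any distance.
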