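"""Derive single-differential and simulated-bipolar montages from a
monopolar GM recording.

The single-differential montage subtracts consecutive rows within each
column (64 monopolar electrodes -> 59 valid SD channels once the missing
corner is accounted for); the simulated bipolar channel averages two 3x3
electrode groups and takes their difference, mimicking a classic pair of
large electrodes.
"""

from coactmap import (
    ActivationField,
    Direction,
    Effort,
    Knee,
    Muscle,
    TrialMeta,
    TrialSpec,
    generate_trial,
    monopolar_to_single_differential,
    simulate_bipolar,
)

meta = TrialMeta("S01", Muscle.GM, Knee.FLEXED_90, Effort.SUBMAX_30,
                 Direction.DORSIFLEXION)
rec, _ = generate_trial(TrialSpec(
    meta=meta,
    field=ActivationField(base_uv=60.0, blobs=((6.0, 2.0, 2.0, 1.2, 100.0),)),
    noise_uv=1.0,
    seed=3,
))
print(f"monopolar: {rec.grid.n_rows}x{rec.grid.n_cols} lattice, "
      f"{rec.n_valid_channels} valid channels")

sd = monopolar_to_single_differential(rec)
print(f"single-differential: {sd.grid.n_rows}x{sd.grid.n_cols} lattice, "
      f"{sd.n_valid_channels} valid channels")

bip = simulate_bipolar(rec)
print(f"bipolar: 1 channel, virtual electrodes centred at "
      f"{bip.extra['bipolar_center_a']} and {bip.extra['bipolar_center_b']}")
# The SD montage drops one row (12x5 = 60 positions) and invalidates the one
# channel touching the missing corner electrode, leaving 59 usable signals.
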