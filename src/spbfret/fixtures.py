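"""Named default simulation fixtures.

Each fixture encodes one experimental condition as a fully specified
simulation configuration:

* ``spc42_cnm67`` — the reference interacting pair at the SPB core
  (apparent efficiency 14%).
* ``tandem_bfa1`` — donor and acceptor fused in tandem on the same protein,
  the maximal-FRET control (apparent efficiency 26%, pairing fraction 1).
* ``donor_only`` — donor fluorophore with no acceptor (efficiency 0): the
  null control.
* ``kar9_misaligned_frap`` — dynamic SPB pool during spindle misalignment,
  half-recovery time 11 s.
* ``spc72_misaligned_frap`` — the same pool with 6-fold slower exchange
  (half-recovery time 66 s), observed over a longer window.
* ``spc72_aligned_spindle`` — correctly aligned spindles that complete
  anaphase: mean duration 23 min (sd 4), onset around 10 min.
"""

from __future__ import annotations

import dataclasses
import math

from .config import FrapSimConfig, SimConfig, SpindleSimConfig

FIXTURES = {
    "spc42_cnm67": SimConfig(apparent_efficiency_pct=14.0),
    "tandem_bfa1": SimConfig(apparent_efficiency_pct=26.0,
                             pairing_fraction=1.0),
    "donor_only": SimConfig(apparent_efficiency_pct=0.0),
    "kar9_misaligned_frap": FrapSimConfig(
        off_rate_per_s=math.log(2) / 11.0, immobile_fraction=0.0,
        bleach_depth=0.8, pre_bleach_frames=10, post_bleach_frames=90,
        frame_interval_s=1.0, noise_sd=0.1),
    "spc72_misaligned_frap": FrapSimConfig(
        off_rate_per_s=math.log(2) / 66.0, immobile_fraction=0.0,
        bleach_depth=0.8, pre_bleach_frames=10, post_bleach_frames=240,
        frame_interval_s=1.0, noise_sd=0.1),
    "spc72_aligned_spindle": SpindleSimConfig(
        n_cells=30, onset_time_mean_min=10.0, onset_time_sd_min=2.0,
        anaphase_duration_mean_min=23.0, anaphase_duration_sd_min=4.0,
        sampling_interval_min=1.0),
}


def get_fixture(name: str, seed: int | None = None, **overrides):
    """Fetch a fixture config by name, optionally reseeded / overridden."""
    try:
        cfg = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"available: {sorted(FIXTURES)}") from None
    if seed is not None:
        overrides["seed"] = int(seed)
    return dataclasses.replace(cfg, **overrides) if overrides else cfg
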