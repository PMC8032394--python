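"""Innate odor preference from synthetic odor-port sessions.

Simulates the standard layout (four 5-min air epochs, then four 5-min odor
epochs) for one attractive-odor group and one aversive-odor group, and scores
each session with the preference index
PI = 100·(TOdor1 + TOdor2 − 2·TAir) / (4·TAve.Air).
"""

import numpy as np

from olfquant import (
    GeneratorConfig,
    epoch_durations,
    gen_investigation_session,
    preference_index,
    preference_schedule,
)

schedule = preference_schedule(odor_id="PB")
for valence in ("attractive", "aversive"):
    pis = []
    for seed in range(12):
        cfg = GeneratorConfig(seed=seed, schedule=schedule, valence_class=valence)
        stream = gen_investigation_session(cfg, subject_id=f"m{seed}")
        summary = epoch_durations(stream, schedule)
        pis.append(preference_index(summary).pi)
    pis = np.asarray(pis)
    print(f"{valence:>10}: PI = {pis.mean():7.1f} ± {pis.std(ddof=1)/np.sqrt(len(pis)):.1f} "
          f"(n = {len(pis)} sessions)")

# Positive PI: the odor drew more port investigation than habituated air
# (attraction); negative PI: investigation fell below the air baseline once
# novelty wore off (aversion).
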