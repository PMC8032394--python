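"""Success rates for the two-alternative-choice and Go/No-Go tasks.

Simulates trial tables for a trained (oracle) agent and an untrained
(random) agent and scores them with the two task-specific success-rate
formulas.
"""

from olfquant import gen_choice_trials, success_rate_go_nogo, success_rate_two_choice

for policy in ("oracle", "random"):
    tc = gen_choice_trials(policy, "two_choice", n_trials=10_000, seed=1)
    gng = gen_choice_trials(policy, "go_nogo", n_trials=10_000, seed=2)
    print(f"{policy:>6}: two-choice SR = {success_rate_two_choice(tc):6.2f}%   "
          f"Go/No-Go SR = {success_rate_go_nogo(gng):6.2f}%")

# A trained animal approaches 100%; an agent guessing at random sits at the
# 50% chance level in both tasks (learning criteria in practice: 80% for
# two-choice, 90% for Go/No-Go).
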