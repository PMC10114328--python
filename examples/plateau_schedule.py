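"""The reduce-on-plateau learning-rate schedule.

Whenever the monitored validation loss fails to improve for two consecutive
epochs, the rate is halved: lr' = lr * factor with lr0 = 0.01 and
factor = 0.5. Under a sustained plateau it decays geometrically toward the
1e-11 scale while staying strictly positive.
"""

import fundusdr as f

state = f.ScheduleState(lr=0.01, factor=0.5, patience=2)
f.step_on_plateau(state, 1.0)  # first epoch establishes the best loss

print("epoch  lr (metric never improves again)")
for epoch in range(2, 66):
    f.step_on_plateau(state, 1.0)
    if epoch % 8 == 0:
        print(f"{epoch:>5}  {state.lr:.3e}")
print(f"\nafter 64 stagnant epochs the rate is {state.lr:.2e} <= 1e-11,")
print("one halving per two epochs, never below the configured floor "
      f"({state.floor:g}).")
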