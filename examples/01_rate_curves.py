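"""Evaluate a Briere development-rate curve and find its optimum temperature.

Uses the published Briere-1 parameters of open-pollinated variety VE 201:
rate constant a, base temperature Tb (development stops below it) and
ceiling temperature Tm (development stops above it).
"""

import numpy as np

from maizephen import RateParams, briere1_rate, optimum_temperature

params = RateParams(a=0.0003, tb=8.9826, tm=40.1123)

for T in (8.0, 15.0, 25.0, 33.0, 40.5):
    r = briere1_rate(T, params)
    print(f"T = {T:5.1f} °C  ->  r = {r:.4f} per day")

to = optimum_temperature("briere1", params)
print(f"\noptimum temperature To = {to:.2f} °C (rate peaks here; Tb < To < Tm)")
print("zero rates at 8.0 and 40.5 °C: outside the thermal window no development occurs")
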