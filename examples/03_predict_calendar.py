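"""Predict a sowing-to-maturity calendar from daily weather.

Builds a year of sinusoidal seasonal weather, then accumulates the daily
Briere-1 development rate: 7 days sowing-to-emergence, a vegetative phase
(emergence to flowering) and a reproductive phase (flowering to maturity),
each completing when cumulative development reaches 1.
"""

from maizephen import RateParams, generate_weather, predict_cycle

weather = generate_weather(mean=23.0, amplitude=3.0, n_days=365, seed=7)
params = RateParams(a=2e-5, tb=9.0, tm=40.0)

cyc = predict_cycle(weather, "briere1", params, sowing_day=0, emergence_offset=7)
print(f"sowing     {cyc.sowing}")
print(f"emergence  {cyc.emergence}")
print(f"flowering  {cyc.flowering}   (vegetative phase {cyc.vp_days:.1f} d)")
print(f"maturity   {cyc.maturity}   (reproductive phase {cyc.rp_days:.1f} d)")
print(f"length of growing period: {cyc.total_days:.1f} days "
      "(= offset + vegetative + reproductive)")
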