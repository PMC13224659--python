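"""Closing a day and moving to pivot (ilr) coordinates.

A child's day is a composition: minutes in sleep, sedentary time,
light-intensity activities and games (LIAG), and energetic play, closed to
1440 min. Pivot coordinates map it to 3 unconstrained values; the first one
contrasts the chosen dominant behaviour against the geometric mean of the
rest.
"""

import coda24 as c

# the cohort-centre day (closed geometric means, min/day)
day = c.close({"sleep": 692.3, "sedentary": 326.3,
               "light_games": 379.0, "energetic": 42.4})
print("closed day (min):", {k: round(v, 1) for k, v in day.parts.items()})
print("as % of day:     ", {k: round(100 * v / 1440, 1)
                            for k, v in day.parts.items()})

basis = c.pivot_basis(c.BEHAVIOURS_4, dominant="sleep")
coords = c.ilr_transform(day, basis)
print("pivot coords (sleep dominant):", coords.coords.round(4))
# coords[0] > 0: this day has relatively more sleep than the geometric mean
# of the waking behaviours

back = c.ilr_inverse(coords)
print("round-trip back to minutes:", back.values.round(1))
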