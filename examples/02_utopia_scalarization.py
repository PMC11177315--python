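"""Score observations against an unreachable utopia point.

Two objectives (conversion %, target-isomer selectivity %) collapse to one
number: the Euclidean distance to a point beyond the attainable square.
Smaller distance (larger inverse distance) is better; Pareto-dominant
observations are always closer.
"""

from upbo import ObjectivePair, UtopiaPoint, pareto_front, utopia_distance

u = UtopiaPoint()  # (selectivity 110, conversion 110), equal weights
observations = {
    "high-sel, high-conv": ObjectivePair(conversion=95, selectivity=99),
    "high-sel, low-conv": ObjectivePair(conversion=63, selectivity=98),
    "low-sel, high-conv": ObjectivePair(conversion=98, selectivity=70),
    "mediocre": ObjectivePair(conversion=59, selectivity=8),
}
for name, obj in observations.items():
    s = utopia_distance(obj, u)
    print(f"{name:22s} dist={s.distance:7.3f}  1/dist={s.inverse_distance:.5f}")

pts = [(o.selectivity, o.conversion) for o in observations.values()]
front = pareto_front(pts)
names = list(observations)
print("Pareto front (nondominated trade-offs):", [names[i] for i in front])
# The dominant observation has the smallest distance; the dominated
# "mediocre" point is excluded from the front.
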