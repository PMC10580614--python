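"""Time-stratified referent selection.

For any case day, the referent (control) days are every other day in
the same calendar month and year sharing the case day's day of week —
always 3 or 4 of them.
"""

from collections import Counter
import datetime as dt

from lagcrossover import referent_days

case = dt.date(2019, 7, 15)  # a Monday
print(f"case day {case} ({case:%A}) -> referents:")
for r in referent_days(case):
    print(f"  {r} ({r:%A})")

sizes = Counter()
d = dt.date(2004, 1, 1)
while d <= dt.date(2019, 12, 31):
    sizes[len(referent_days(d))] += 1
    d += dt.timedelta(days=1)
print(f"referent-count distribution over 2004-2019: {dict(sizes)}")
# every stratum therefore holds one case day and 3-4 same-weekday
# controls, which absorbs weekday, seasonal and long-term-trend effects
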